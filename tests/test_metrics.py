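"""Interface metrics against brute-force and analytic oracles."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from capriq.metrics import (
    NotAssessable,
    clash_count,
    compute_metrics,
    fnat,
    irms,
    lrms,
    native_contacts,
    order_pair,
    srms,
    superpose,
)
from capriq.structure_io import build_correspondence
from capriq.synthetic import DecoySpec, ToyComplexSpec, make_decoy, make_toy_complex

from helpers import allpairs_clashes, allpairs_contacts, grid_superpose_rmsd, mini_structure


def _translated(structure, t, chain="B"):
    return structure.transformed(np.eye(3), np.asarray(t, float), chain_ids=[chain])


class TestContacts:
    def test_single_contact_pair(self):
        # one CB-CB pair at 4.0 A, everything else beyond 6 A
        st = mini_structure({
            "A": [("ALA", [("CA", (0, 0, 0)), ("CB", (1.5, 0, 0))]),
                  ("ALA", [("CA", (0, 0, 8)), ("CB", (1.5, 0, 8))])],
            "B": [("ALA", [("CA", (7.0, 0, 0)), ("CB", (5.5, 0, 0))]),
                  ("ALA", [("CA", (7.0, 0, 8)), ("CB", (7.0, 1.5, 8))])],
        })
        iface = native_contacts(st, "A", "B", threshold=5.0)
        assert len(iface.native_contacts) == 1
        assert iface.native_contacts == frozenset({(("A", "1"), ("B", "1"))})

    def test_separated_chains_not_assessable(self, c2_dimer):
        apart = _translated(c2_dimer, (50, 0, 0))
        iface = native_contacts(apart, "A", "B")
        assert not iface.assessable

    def test_threshold_monotonicity(self, c2_dimer):
        at5 = native_contacts(c2_dimer, "A", "B", threshold=5.0)
        at10 = native_contacts(c2_dimer, "A", "B", threshold=10.0)
        assert at5.native_contacts <= at10.native_contacts

    @pytest.mark.parametrize("spec", [
        ToyComplexSpec(),
        ToyComplexSpec(n_chains=3, chain_lengths=(20,) * 3, symmetry="C3"),
        ToyComplexSpec(n_chains=2, chain_lengths=(24, 18), symmetry="none", hetero=True),
    ], ids=["C2", "C3", "hetero"])
    def test_contacts_match_allpairs_oracle(self, spec):
        st = make_toy_complex(spec)
        a, b = st.chain_ids[0], st.chain_ids[1]
        iface = native_contacts(st, a, b)
        assert iface.native_contacts == frozenset(allpairs_contacts(st, a, b, 5.0))
        # interface residues follow the 10 A rule
        pairs10 = allpairs_contacts(st, a, b, 10.0)
        expected = {r for r, _ in pairs10} | {l for _, l in pairs10}
        assert iface.interface_residues == frozenset(expected)


class TestFnat:
    def test_identity_is_one(self, c2_dimer, identity_corr):
        iface = native_contacts(c2_dimer, "A", "B")
        assert fnat(c2_dimer, identity_corr, iface) == 1.0

    def test_displaced_ligand_is_zero(self, c2_dimer, identity_corr):
        iface = native_contacts(c2_dimer, "A", "B")
        apart = _translated(c2_dimer, (50, 0, 0))
        assert fnat(apart, identity_corr, iface) == 0.0

    def test_partial_recall_matches_construction(self):
        # 4 native contacts; the model moves two ligand residues away
        def lig(y3, y4):
            return [("ALA", [("CA", (4.0, 0, 0))]),
                    ("ALA", [("CA", (4.0, 0, 4))]),
                    ("ALA", [("CA", (4.0, y3, 8))]),
                    ("ALA", [("CA", (4.0, y4, 12))])]

        target = mini_structure({
            "A": [("ALA", [("CA", (0, 0, z))]) for z in (0, 4, 8, 12)],
            "B": lig(0, 0),
        })
        model = mini_structure({
            "A": [("ALA", [("CA", (0, 0, z))]) for z in (0, 4, 8, 12)],
            "B": lig(30.0, 30.0),
        })
        iface = native_contacts(target, "A", "B")
        assert len(iface.native_contacts) == 4
        corr = build_correspondence(model, target, {"A": "A", "B": "B"})
        assert fnat(model, corr, iface) == 0.5

    def test_missing_residues_count_as_missed(self, c2_dimer):
        from collections import OrderedDict
        from capriq.structure_io import AssemblyStructure

        iface = native_contacts(c2_dimer, "A", "B")
        contact_b = sorted({l for _, l in iface.native_contacts})
        drop = {contact_b[0][1]}
        chains = OrderedDict(
            (cid, [r for r in rs if not (cid == "B" and r.seq_id in drop)])
            for cid, rs in c2_dimer.chains.items()
        )
        model = AssemblyStructure(chains)
        corr = build_correspondence(model, c2_dimer, {"A": "A", "B": "B"})
        lost = {p for p in iface.native_contacts if p[1][1] in drop}
        expected = (len(iface.native_contacts) - len(lost)) / len(iface.native_contacts)
        assert fnat(model, corr, iface) == pytest.approx(expected)


class TestClashes:
    def test_reference_is_clash_free(self, c2_dimer):
        assert clash_count(c2_dimer, "A", "B") == 0

    def test_single_constructed_clash(self):
        st = mini_structure({
            "A": [("ALA", [("CA", (0, 0, 0))])],
            "B": [("ALA", [("CA", (2.5, 0, 0))])],
        })
        assert clash_count(st, "A", "B") == 1

    def test_overlapping_chains_match_oracle(self, c2_dimer):
        onto_a = (c2_dimer.chain_coords("A").mean(axis=0)
                  - c2_dimer.chain_coords("B").mean(axis=0))
        overlapped = _translated(c2_dimer, onto_a)  # B onto A
        assert clash_count(overlapped, "A", "B") == allpairs_clashes(
            overlapped, "A", "B", 3.0
        )
        assert clash_count(overlapped, "A", "B") > 0


class TestSuperpose:
    def test_identity(self):
        pts = np.random.default_rng(0).normal(size=(10, 3))
        fit = superpose(pts, pts)
        assert fit.rmsd == pytest.approx(0.0, abs=1e-10)

    def test_rigid_invariance(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(12, 3))
        R = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        moved = pts @ R.T + np.array([5.0, -2.0, 3.0])
        fit = superpose(pts, moved)
        assert fit.rmsd < 1e-8
        assert np.linalg.det(fit.rotation) == pytest.approx(1.0)

    def test_beats_rotation_grid_oracle(self):
        rng = np.random.default_rng(42)
        for trial in range(25):
            a = rng.normal(size=(10, 3)) * 3.0
            b = rng.normal(size=(10, 3)) * 3.0
            fit = superpose(a, b)
            grid_best = grid_superpose_rmsd(a, b, n_rotations=2000, seed=trial)
            assert fit.rmsd <= grid_best + 1e-9

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            superpose(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]], float)
        with pytest.raises(ValueError, match="degenerate"):
            superpose(line, line)


class TestRmsds:
    def test_identity_zero_everywhere(self, c2_dimer, identity_corr):
        iface = native_contacts(c2_dimer, "A", "B")
        assert lrms(c2_dimer, c2_dimer, identity_corr, iface) == pytest.approx(0, abs=1e-9)
        assert irms(c2_dimer, c2_dimer, identity_corr, iface) == pytest.approx(0, abs=1e-9)
        assert srms(c2_dimer, c2_dimer, identity_corr, iface) == pytest.approx(0, abs=1e-9)

    def test_pure_translation_lrms_is_exact(self, c2_dimer, identity_corr):
        iface = native_contacts(c2_dimer, "A", "B")
        for t in ((3, 0, 0), (0, 2.5, 0), (1, 1, 1)):
            model = _translated(c2_dimer, t)
            assert lrms(model, c2_dimer, identity_corr, iface) == pytest.approx(
                np.linalg.norm(t), abs=1e-9
            )

    def test_ligand_rotation_matches_direct_formula(self, c2_dimer, identity_corr):
        iface = native_contacts(c2_dimer, "A", "B")
        R = Rotation.from_euler("y", 17, degrees=True).as_matrix()
        centroid = c2_dimer.chain_coords("B").mean(axis=0)
        model = c2_dimer.transformed(R, centroid - R @ centroid, chain_ids=["B"])
        # direct per-atom deviation of the ligand backbone (receptor fit
        # is the identity since the receptor is untouched)
        bb = np.vstack([
            [a.position for a in r.backbone_atoms] for r in c2_dimer.chains["B"]
        ])
        moved = bb @ R.T + (centroid - R @ centroid)
        expected = np.sqrt(np.mean(np.sum((moved - bb) ** 2, axis=1)))
        assert lrms(model, c2_dimer, identity_corr, iface) == pytest.approx(
            expected, abs=1e-9
        )

    def test_global_rigid_transform_leaves_metrics_unchanged(self, c2_dimer, identity_corr):
        iface = native_contacts(c2_dimer, "A", "B")
        spec = DecoySpec(ligand_translation=(1.2, 0.8, -0.5), rotation_angle_deg=4.0)
        model, target, _ = make_decoy(spec)
        corr = build_correspondence(model, target, {"A": "A", "B": "B"})
        base = compute_metrics(model, target, corr, iface)
        R = Rotation.from_euler("zyx", [33, -21, 57], degrees=True).as_matrix()
        moved = model.transformed(R, np.array([10.0, -7.0, 4.0]))
        after = compute_metrics(moved, target, corr, iface)
        assert after.fnat == base.fnat
        assert after.clashes == base.clashes
        assert after.lrms == pytest.approx(base.lrms, abs=1e-6)
        assert after.irms == pytest.approx(base.irms, abs=1e-6)
        assert after.srms == pytest.approx(base.srms, abs=1e-6)

    def test_irms_between_zero_and_translation(self, c2_dimer, identity_corr):
        iface = native_contacts(c2_dimer, "A", "B")
        model = _translated(c2_dimer, (2.0, 0, 0))
        v = irms(model, c2_dimer, identity_corr, iface)
        assert 0.0 < v < 2.0

    def test_fnat_monotone_in_separation(self, c2_dimer, identity_corr):
        iface = native_contacts(c2_dimer, "A", "B")
        direction = (c2_dimer.chain_coords("B").mean(axis=0)
                     - c2_dimer.chain_coords("A").mean(axis=0))
        direction /= np.linalg.norm(direction)
        values = []
        for mag in (0.0, 1.0, 2.0, 4.0, 6.0, 10.0):
            model = _translated(c2_dimer, mag * direction)
            values.append(fnat(model, identity_corr, iface))
        assert values == sorted(values, reverse=True)
        assert values[0] == 1.0 and values[-1] == 0.0


class TestSrms:
    def test_all_glycine_interface_undefined(self):
        st = make_toy_complex(ToyComplexSpec(all_glycine=True))
        corr = build_correspondence(st, st, {"A": "A", "B": "B"})
        iface = native_contacts(st, "A", "B")
        assert srms(st, st, corr, iface) is None

    def test_gaussian_jitter_recovers_sigma(self):
        # side-chain jitter sigma per coordinate -> RMSD ~= sigma*sqrt(3)
        sigma = 0.4
        base = ToyComplexSpec(chain_lengths=(40, 40))
        spec = DecoySpec(base=base, sidechain_sigma=sigma, seed=7)
        model, target, _ = make_decoy(spec)
        corr = build_correspondence(model, target, {"A": "A", "B": "B"})
        iface = native_contacts(target, "A", "B")
        value = srms(model, target, corr, iface)
        n_atoms = sum(
            len(target.residue(k).sidechain_atoms)
            for k in iface.interface_residues
        )
        se = sigma * np.sqrt(3) / np.sqrt(2 * 3 * n_atoms)
        assert value == pytest.approx(sigma * np.sqrt(3), abs=3 * se)


def test_receptor_convention_larger_chain_first(hetero_dimer):
    # chain A has 24 residues, chain B 18
    assert order_pair(hetero_dimer, "A", "B") == ("A", "B")
    assert order_pair(hetero_dimer, "B", "A") == ("A", "B")


def test_insufficient_common_atoms_not_assessable(c2_dimer, identity_corr):
    from collections import OrderedDict
    from capriq.structure_io import AssemblyStructure

    iface = native_contacts(c2_dimer, "A", "B")
    stub = AssemblyStructure(OrderedDict(A=c2_dimer.chains["A"]))
    corr = build_correspondence(stub, c2_dimer, {"A": "A"})
    with pytest.raises(NotAssessable):
        lrms(stub, c2_dimer, corr, iface)
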