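"""Assembly-level evaluation: interface enumeration, chain mapping,
grouping, and assessment-unit aggregation."""

import itertools
from collections import OrderedDict

import numpy as np
import pytest

from capriq.assembly import (
    AUDefinition,
    best_chain_mapping,
    dockq_au,
    enumerate_interfaces,
    evaluate_model,
    group_similar_interfaces,
    score_au,
)
from capriq.quality import Category, QualityLabel
from capriq.structure_io import AssemblyStructure, ChainMappingError
from capriq.synthetic import ToyComplexSpec, make_toy_complex, load_target_table

from helpers import allpairs_contacts


@pytest.fixture(scope="module")
def c6_ring():
    return make_toy_complex(
        ToyComplexSpec(n_chains=6, chain_lengths=(20,) * 6, symmetry="C6")
    )


class TestEnumerateInterfaces:
    def test_two_chain_fixture_has_one(self, c2_dimer):
        assert len(enumerate_interfaces(c2_dimer)) == 1

    def test_c3_trimer_has_three(self, c3_trimer):
        assert len(enumerate_interfaces(c3_trimer)) == 3

    def test_hexamer_ring_neighbours_only(self, c6_ring):
        ifaces = enumerate_interfaces(c6_ring)
        assert len(ifaces) == 6
        # matches the all-pairs chain-pair oracle
        expected = set()
        for a, b in itertools.combinations(c6_ring.chain_ids, 2):
            if allpairs_contacts(c6_ring, a, b, 5.0):
                expected.add(frozenset((a, b)))
        got = {frozenset((i.receptor_chain, i.ligand_chain)) for i in ifaces}
        assert got == expected

    def test_single_chain_rejected(self, c2_dimer):
        lone = AssemblyStructure(OrderedDict(A=c2_dimer.chains["A"]))
        with pytest.raises(ValueError):
            enumerate_interfaces(lone)


class TestGrouping:
    def test_c3_symmetric_interfaces_form_one_group(self, c3_trimer):
        ifaces = enumerate_interfaces(c3_trimer)
        au = group_similar_interfaces(ifaces, c3_trimer)
        assert au.K == 1
        assert au.n_member_interfaces == 3

    def test_distinct_interfaces_stay_apart(self, hetero_dimer):
        # hetero trimer in a row: A-B and B-C are different chain classes
        tri = make_toy_complex(
            ToyComplexSpec(n_chains=3, chain_lengths=(24, 20, 16),
                           symmetry="none", hetero=True)
        )
        ifaces = enumerate_interfaces(tri)
        au = group_similar_interfaces(ifaces, tri)
        assert au.K == len(ifaces)

    def test_curated_au219_groups_nine_members_into_three(self):
        _, aus = load_target_table()
        au219 = next(a for a in aus if a.au_id == "AU219")
        assert au219.K == 3
        assert au219.n_member_interfaces == 9


class TestChainMapping:
    def test_swapped_homodimer_labels_recover_identity_metrics(self, c2_dimer):
        swapped = AssemblyStructure(OrderedDict(
            A=[r.__class__("A", r.seq_id, r.res_name, r.atoms)
               for r in c2_dimer.chains["B"]],
            B=[r.__class__("B", r.seq_id, r.res_name, r.atoms)
               for r in c2_dimer.chains["A"]],
        ))
        mapping, results = evaluate_model(swapped, c2_dimer)
        for res in results.values():
            assert res.metrics.fnat == 1.0
            assert res.metrics.lrms == pytest.approx(0.0, abs=1e-6)

    def test_heterodimer_single_admissible_mapping(self, hetero_dimer):
        mapping, results = evaluate_model(hetero_dimer, hetero_dimer)
        assert mapping.assignment == {"A": "A", "B": "B"}
        assert all(r.metrics.fnat == 1.0 for r in results.values())

    def test_rotated_trimer_labels_recovered(self, c3_trimer):
        # relabel chains A->B->C->A; exhaustive 3! search must undo it
        rot = {"A": "B", "B": "C", "C": "A"}
        chains = OrderedDict()
        for new in ("A", "B", "C"):
            old = next(k for k, v in rot.items() if v == new)
            chains[new] = [
                r.__class__(new, r.seq_id, r.res_name, r.atoms)
                for r in c3_trimer.chains[old]
            ]
        model = AssemblyStructure(chains)
        _, results = evaluate_model(model, c3_trimer)
        assert len(results) == 3
        for res in results.values():
            assert res.metrics.fnat == 1.0

    def test_relabeling_invariance_within_class(self, c3_trimer):
        ifaces = enumerate_interfaces(c3_trimer)
        base_map, base = best_chain_mapping(c3_trimer, c3_trimer, ifaces)
        for perm in itertools.permutations("ABC"):
            chains = OrderedDict()
            for new, old in zip("ABC", perm):
                chains[new] = [
                    r.__class__(new, r.seq_id, r.res_name, r.atoms)
                    for r in c3_trimer.chains[old]
                ]
            model = AssemblyStructure(chains)
            _, results = best_chain_mapping(model, c3_trimer, ifaces)
            for iface_id in base:
                assert results[iface_id].metrics.fnat == base[iface_id].metrics.fnat
                assert results[iface_id].dockq_value == pytest.approx(
                    base[iface_id].dockq_value, abs=1e-9
                )

    def test_incompatible_stoichiometry_errors(self, c2_dimer, c3_trimer):
        ifaces = enumerate_interfaces(c3_trimer)
        with pytest.raises(ChainMappingError, match="stoichiometry"):
            best_chain_mapping(c2_dimer, c3_trimer, ifaces)


def _result(cat, q):
    from capriq.assembly import InterfaceResult
    from capriq.quality import DockQValue

    return InterfaceResult(
        interface_id="x", metrics=None, label=QualityLabel(Category[cat]),
        dockq=DockQValue(q) if q > 0 else None,
    )


class TestScoreAU:
    def _au(self, k):
        return AUDefinition(
            au_id="AU", interface_groups={
                f"g{i}": frozenset({f"i{i}"}) for i in range(k)
            }
        )

    def test_printed_weight_examples(self):
        au = self._au(3)
        results = {"i0": _result("High", 0.9), "i1": _result("Medium", 0.6),
                   "i2": _result("Acceptable", 0.3)}
        out = score_au(au, results)
        assert out.score_au == 6.0
        assert out.score_au_norm == pytest.approx(2.0)

    def test_all_incorrect_scores_zero(self):
        au = self._au(2)
        results = {"i0": _result("Incorrect", 0.05), "i1": _result("Incorrect", 0.1)}
        assert score_au(au, results).score_au == 0.0

    def test_single_group_high(self):
        out = score_au(self._au(1), {"i0": _result("High", 1.0)})
        assert out.score_au == 3.0 and out.score_au_norm == 3.0

    @pytest.mark.parametrize("k", [1, 2, 3, 4])
    def test_bounds_exhaustive(self, k):
        au = self._au(k)
        names = ["Incorrect", "Acceptable", "Medium", "High"]
        for combo in itertools.product(names, repeat=k):
            results = {f"i{i}": _result(c, 0.5) for i, c in enumerate(combo)}
            s = score_au(au, results).score_au
            assert 0.0 <= s <= 3.0 * k

    def test_best_replica_represents_group(self):
        au = AUDefinition(au_id="AU", interface_groups={
            "g": frozenset({"a", "b"})
        })
        results = {"a": _result("Acceptable", 0.2), "b": _result("High", 0.9)}
        out = score_au(au, results)
        assert out.per_group_best["g"][0].category == Category.High
        assert out.score_au == 3.0


class TestDockQAU:
    def test_mean_of_groups(self):
        assert dockq_au({"g1": 0.8, "g2": 0.4}) == pytest.approx(0.6)

    def test_single_interface_identity(self):
        assert dockq_au({"g": 0.37}) == pytest.approx(0.37)

    def test_best_replica_rule_through_score_au(self):
        au = AUDefinition(au_id="AU", interface_groups={"g": frozenset({"a", "b"})})
        results = {"a": _result("Acceptable", 0.2), "b": _result("High", 0.9)}
        assert score_au(au, results).dockq_au == pytest.approx(0.9)

    def test_bounded_by_group_extremes(self):
        vals = {"g1": 0.1, "g2": 0.9, "g3": 0.5}
        out = dockq_au(vals)
        assert min(vals.values()) <= out <= max(vals.values())


def test_au_groups_must_be_disjoint():
    with pytest.raises(ValueError, match="disjoint"):
        AUDefinition(au_id="AU", interface_groups={
            "g1": frozenset({"a"}), "g2": frozenset({"a", "b"}),
        })
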