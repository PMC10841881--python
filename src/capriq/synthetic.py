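"""Self-contained synthetic fixtures: toy complexes, graded decoys,
submission manifests, and the transcribed round metadata.

Toy complexes are built from ideal alpha-helical chains (rise 1.5 A,
twist 100 deg/residue) decorated with short schematic side chains, and
placed with controllable symmetry (none, C2, C3, C6) so that declared
interfaces carry at least 10 native contacts at 5 A and the reference
itself is clash-free.  The geometry is idealised on purpose: every
metric has an analytic or brute-force handle, e.g. a pure ligand
translation by t gives L_rms = |t| exactly.

Decoys perturb one chain (rigid displacement, side-chain jitter,
truncation) and carry their expected metrics, computed by this module's
own brute-force oracles (all-pairs contact enumeration and an
SVD-free superposition via scipy's rotation alignment) — deliberately
independent of the metrics module they validate.

The round metadata (the 37 targets with their categories and the
assessment-unit splitting of T203, T204 and T219-T221) ships as a
packaged TSV plus YAML configs, transcribed once and checksummed.
"""

from __future__ import annotations

import hashlib
import math
from collections import OrderedDict
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .assembly import AUDefinition, load_au_config
from .metrics import MetricsRecord
from .quality import CATEGORY_TABLE, Category, QualityLabel
from .ranking import ModelEntry, SubmissionSet
from .structure_io import AssemblyStructure, AtomRecord, ResidueRecord

__all__ = [
    "ToyComplexSpec",
    "DecoySpec",
    "TargetRecord",
    "make_toy_complex",
    "make_decoy",
    "make_decoy_ladder",
    "make_submission_manifest",
    "load_target_table",
    "au_accounting",
    "oracle_contact_pairs",
    "oracle_superpose",
    "oracle_metrics",
]

HELIX_RISE = 1.5       # A per residue
HELIX_TWIST = 100.0    # degrees per residue
HELIX_RADIUS = 2.3     # A, CA radius

# Schematic side chains: per residue type, (atom name, element, radial
# extension from CA, tangential offset, axial offset).  Extensions are
# kept modest so facing chains interact without steric overlap.
_SIDECHAINS: Dict[str, List[Tuple[str, str, float, float, float]]] = {
    "GLY": [],
    "ALA": [("CB", "C", 1.5, 0.1, 0.3)],
    "SER": [("CB", "C", 1.5, 0.1, 0.3), ("OG", "O", 2.4, -0.2, 0.5)],
    "VAL": [("CB", "C", 1.5, 0.1, 0.3), ("CG1", "C", 2.4, 0.6, 0.1),
            ("CG2", "C", 2.4, -0.5, 0.6)],
    "ASP": [("CB", "C", 1.5, 0.1, 0.3), ("CG", "C", 2.2, 0.2, 0.2),
            ("OD1", "O", 2.6, 0.6, 0.0)],
    "LEU": [("CB", "C", 1.5, 0.1, 0.3), ("CG", "C", 2.2, -0.3, 0.4),
            ("CD1", "C", 2.6, 0.3, 0.8)],
}
# repeating sequence cycled over chain length; varied so side-chain
# atom counts differ along the chain
_SEQUENCE_CYCLE = ("ALA", "ASP", "LEU", "SER", "VAL", "GLY")

_DATA_PACKAGE = "capriq.data"
# sha256 of the packaged fixtures, frozen at transcription time
_FIXTURE_CHECKSUMS = {
    "target_table.tsv": "1a4c38d42ee0280dc09626370ca36a48b004cc38616cc7fa9dddfc21b9dc2b3f",
    "au_t203.yaml": "784a77eca120010be6930f97726df7cb7cdb40d4afbc3322e54b8d0fb2e96298",
    "au_t204.yaml": "64a301c7a17b158cd7744e243109e900f4d9a37d70cc7fda373d783ce9ab9c9c",
    "au_t219_221.yaml": "e8bd02b934f9a2f8b5c9095a2fb5936caeddad8dfce1723ad2bdc3d16743615a",
}


@dataclass(frozen=True)
class ToyComplexSpec:
    """Deterministic recipe for a toy multi-chain complex."""

    n_chains: int = 2
    chain_lengths: Tuple[int, ...] = (20, 20)
    symmetry: str = "C2"          # none | C2 | C3 | C6
    axis_separation: float = 8.0  # A between neighbouring helix axes
    hetero: bool = False           # distinct sequences per chain
    all_glycine: bool = False      # degenerate side-chain-free variant
    seed: int = 0

    def __post_init__(self):
        if self.symmetry not in ("none", "C2", "C3", "C6"):
            raise ValueError(f"unknown symmetry {self.symmetry!r}")
        expected = {"C2": 2, "C3": 3, "C6": 6}.get(self.symmetry)
        if expected is not None and self.n_chains != expected:
            raise ValueError(f"{self.symmetry} symmetry needs {expected} chains")
        if len(self.chain_lengths) != self.n_chains:
            raise ValueError("chain_lengths must have one entry per chain")


@dataclass(frozen=True)
class DecoySpec:
    """A perturbation of one toy complex's ligand chain."""

    base: ToyComplexSpec = ToyComplexSpec()
    ligand_translation: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    rotation_axis: Tuple[float, float, float] = (0.0, 0.0, 1.0)
    rotation_angle_deg: float = 0.0
    sidechain_sigma: float = 0.0  # A, Gaussian per coordinate
    truncate: int = 0             # residues removed from the ligand C-terminus
    seed: int = 0
    intended_category: str = "unspecified"


@dataclass(frozen=True)
class TargetRecord:
    """One transcribed prediction-round target (inert metadata)."""

    capri_id: str
    casp_id: str
    category: str        # I..V
    kingdom: str         # B | E | V | designed | unannotated
    size: str            # residues (as printed; '/' separates chains)
    bsa: str             # A^2 (as printed)
    name: str
    oligomer_class: str  # homodimer | homotrimer | heterodimer | large
    au_ids: Tuple[str, ...]

    def __post_init__(self):
        if self.category not in ("I", "II", "III", "IV", "V"):
            raise ValueError(f"{self.capri_id}: category {self.category!r} not in I..V")


# ---------------------------------------------------------------------------
# Toy complex generation
# ---------------------------------------------------------------------------

def _helix_chain(chain_id: str, length: int, seq_offset: int,
                 all_glycine: bool,
                 sidechain_dir: Tuple[float, float, float] = (1.0, 0.0, 0.0),
                 ) -> List[ResidueRecord]:
    """One ideal helical chain along +z, axis through the origin.

    Side chains extend along the fixed *sidechain_dir* (a unit vector in
    the xy-plane) rather than radially, so a chain can be placed with
    its side chains facing away from its binding partners; the interface
    then forms through the dense, regular backbone envelope, which keeps
    contact counts stable and the reference clash-free.
    """
    f = np.asarray(sidechain_dir, float)
    f = f / np.linalg.norm(f)
    g = np.array([-f[1], f[0], 0.0])  # in-plane perpendicular
    residues = []
    for i in range(length):
        theta = math.radians(HELIX_TWIST * i)
        u = np.array([math.cos(theta), math.sin(theta), 0.0])   # radial
        v = np.array([-math.sin(theta), math.cos(theta), 0.0])  # tangential
        w = np.array([0.0, 0.0, 1.0])
        ca = HELIX_RADIUS * u + HELIX_RISE * i * w
        atoms = [
            AtomRecord("N", "N", ca - 0.6 * u - 0.9 * v - 0.5 * w),
            AtomRecord("CA", "C", ca),
            AtomRecord("C", "C", ca - 0.5 * u + 0.9 * v + 0.6 * w),
            AtomRecord("O", "O", ca - 1.2 * u + 1.1 * v + 1.0 * w),
        ]
        res_name = "GLY" if all_glycine else _SEQUENCE_CYCLE[(i + seq_offset) % len(_SEQUENCE_CYCLE)]
        for name, element, radial, tang, axial in _SIDECHAINS[res_name]:
            atoms.append(AtomRecord(name, element, ca + radial * f + tang * g + axial * w))
        residues.append(ResidueRecord(chain_id, str(i + 1), res_name, atoms))
    return residues


def _place_chain(residues: List[ResidueRecord], rotation: np.ndarray,
                 translation: np.ndarray) -> List[ResidueRecord]:
    out = []
    for r in residues:
        atoms = [
            AtomRecord(a.name, a.element, rotation @ a.position + translation,
                       a.occupancy, a.altloc)
            for a in r.atoms
        ]
        out.append(ResidueRecord(r.chain_id, r.seq_id, r.res_name, atoms))
    return out


def make_toy_complex(spec: ToyComplexSpec) -> AssemblyStructure:
    """Build the reference complex described by *spec*.

    Raises if the placement produces inter-chain clashes (<3 A) or
    fewer than 10 native contacts (at 5 A) on a declared interface.
    """
    chain_ids = [chr(ord("A") + k) for k in range(spec.n_chains)]
    chains: "OrderedDict[str, List[ResidueRecord]]" = OrderedDict()
    d = spec.axis_separation

    # side chains point away from the binding partner(s): outward for
    # ring symmetries (local +x maps to radially outward), sideways for
    # a linear arrangement
    if spec.symmetry == "none":
        placements = [
            (np.eye(3), np.array([k * d, 0.0, 0.0])) for k in range(spec.n_chains)
        ]
        sidechain_dirs = []
        for k in range(spec.n_chains):
            if k == 0:
                sidechain_dirs.append((-1.0, 0.0, 0.0))
            elif k == spec.n_chains - 1:
                sidechain_dirs.append((1.0, 0.0, 0.0))
            else:
                sidechain_dirs.append((0.0, 1.0, 0.0))
    else:
        n = spec.n_chains
        # axis offset so neighbouring helix axes sit d apart
        radius = d / (2.0 * math.sin(math.pi / n))
        placements = []
        for k in range(n):
            ang = 2.0 * math.pi * k / n
            rot = Rotation.from_euler("z", ang).as_matrix()
            placements.append((rot, rot @ np.array([radius, 0.0, 0.0])))
        sidechain_dirs = [(1.0, 0.0, 0.0)] * n

    for k, cid in enumerate(chain_ids):
        seq_offset = 0 if (spec.symmetry != "none" and not spec.hetero) else 2 * k
        length = spec.chain_lengths[k]
        base = _helix_chain(cid, length, seq_offset, spec.all_glycine,
                            sidechain_dir=sidechain_dirs[k])
        rot, tr = placements[k]
        chains[cid] = _place_chain(base, rot, tr)

    structure = AssemblyStructure(chains, name=f"toy_{spec.symmetry}_{spec.n_chains}")

    # validate declared interfaces: ring neighbours (or consecutive chains)
    neighbours = []
    for k in range(spec.n_chains - 1):
        neighbours.append((chain_ids[k], chain_ids[k + 1]))
    if spec.symmetry in ("C3", "C6"):
        neighbours.append((chain_ids[-1], chain_ids[0]))
    for a, b in neighbours:
        contacts = oracle_contact_pairs(structure, a, b, 5.0)
        clashes = oracle_clash_count(structure, a, b, 3.0)
        if clashes:
            raise ValueError(
                f"generated reference has {clashes} clash(es) on {a}:{b}; "
                f"increase axis_separation"
            )
        if len(contacts) < 10:
            raise ValueError(
                f"interface {a}:{b} has only {len(contacts)} contacts (<10); "
                f"decrease axis_separation"
            )
    return structure


# ---------------------------------------------------------------------------
# Brute-force oracles (independent of the metrics module)
# ---------------------------------------------------------------------------

def _chain_atoms(structure: AssemblyStructure, chain_id: str):
    coords, owners, names = [], [], []
    for res in structure.chains[chain_id]:
        for a in res.atoms:
            coords.append(a.position)
            owners.append(res.key)
            names.append(a.name)
    return np.asarray(coords), owners, names


def oracle_contact_pairs(structure: AssemblyStructure, chain_a: str, chain_b: str,
                         threshold: float) -> set:
    """All-pairs residue contact enumeration (O(n^2), no tree)."""
    ca, oa, _ = _chain_atoms(structure, chain_a)
    cb, ob, _ = _chain_atoms(structure, chain_b)
    dist = cdist(ca, cb)
    pairs = set()
    for i, j in zip(*np.nonzero(dist <= threshold)):
        pairs.add((oa[i], ob[j]))
    return pairs


def oracle_clash_count(structure: AssemblyStructure, chain_a: str, chain_b: str,
                       threshold: float) -> int:
    ca, _, _ = _chain_atoms(structure, chain_a)
    cb, _, _ = _chain_atoms(structure, chain_b)
    return int(np.count_nonzero(cdist(ca, cb) < threshold))


def oracle_superpose(moving: np.ndarray, fixed: np.ndarray) -> Tuple[np.ndarray, np.ndarray, float]:
    """Optimal proper-rotation superposition via scipy's rotation
    alignment (independent of the package's own SVD Kabsch)."""
    moving = np.asarray(moving, float)
    fixed = np.asarray(fixed, float)
    mc, fc = moving.mean(axis=0), fixed.mean(axis=0)
    rot, rssd = Rotation.align_vectors(fixed - fc, moving - mc)
    R = rot.as_matrix()
    t = fc - R @ mc
    rmsd = float(rssd / math.sqrt(len(moving)))
    return R, t, rmsd


def oracle_metrics(
    model: AssemblyStructure,
    target: AssemblyStructure,
    receptor: str,
    ligand: str,
    contact_threshold: float = 5.0,
    interface_threshold: float = 10.0,
    clash_threshold: float = 3.0,
) -> MetricsRecord:
    """Brute-force metric computation assuming identity residue
    correspondence (model chains named as in the target)."""
    native = oracle_contact_pairs(target, receptor, ligand, contact_threshold)
    if not native:
        raise ValueError("oracle: no native contacts")
    model_keys = {
        r.key for cid in (receptor, ligand) for r in model.chains.get(cid, [])
    }
    model_pairs = oracle_contact_pairs(model, receptor, ligand, contact_threshold)
    recalled = {p for p in native if p in model_pairs}
    fnat_val = len(recalled) / len(native)

    def backbone(structure, keys):
        pts = {}
        for cid in (receptor, ligand):
            for res in structure.chains.get(cid, []):
                if res.key in keys:
                    for a in res.atoms:
                        if a.name in ("N", "CA", "C", "O"):
                            pts[(res.key, a.name)] = a.position
        return pts

    # L_rms: receptor fit over common residues, ligand deviation
    t_rec_keys = {r.key for r in target.chains[receptor]}
    t_lig_keys = {r.key for r in target.chains[ligand]}
    m_bb = backbone(model, t_rec_keys | t_lig_keys)
    t_bb = backbone(target, t_rec_keys | t_lig_keys)
    shared = sorted(set(m_bb) & set(t_bb))
    rec_ids = [k for k in shared if k[0][0] == receptor]
    lig_ids = [k for k in shared if k[0][0] == ligand]
    m_rec = np.array([m_bb[k] for k in rec_ids])
    t_rec = np.array([t_bb[k] for k in rec_ids])
    m_lig = np.array([m_bb[k] for k in lig_ids])
    t_lig = np.array([t_bb[k] for k in lig_ids])
    R, t, _ = oracle_superpose(m_rec, t_rec)
    moved = m_lig @ R.T + t
    lrms_val = float(np.sqrt(np.mean(np.sum((moved - t_lig) ** 2, axis=1))))

    # i_rms: target-side 10 A interface residues, fit over them
    iface_pairs = oracle_contact_pairs(target, receptor, ligand, interface_threshold)
    iface_keys = {r for r, _ in iface_pairs} | {l for _, l in iface_pairs}
    m_ib = backbone(model, iface_keys)
    t_ib = backbone(target, iface_keys)
    ishared = sorted(set(m_ib) & set(t_ib))
    m_ipts = np.array([m_ib[k] for k in ishared])
    t_ipts = np.array([t_ib[k] for k in ishared])
    Ri, ti, irms_val = oracle_superpose(m_ipts, t_ipts)

    # S_rms under the i_rms fit
    def sidechains(structure, keys):
        pts = {}
        for cid in (receptor, ligand):
            for res in structure.chains.get(cid, []):
                if res.key in keys:
                    for a in res.atoms:
                        if a.name not in ("N", "CA", "C", "O"):
                            pts[(res.key, a.name)] = a.position
        return pts

    m_sc = sidechains(model, iface_keys)
    t_sc = sidechains(target, iface_keys)
    sshared = sorted(set(m_sc) & set(t_sc))
    if sshared:
        m_spts = np.array([m_sc[k] for k in sshared])
        t_spts = np.array([t_sc[k] for k in sshared])
        moved_s = m_spts @ Ri.T + ti
        srms_val = float(np.sqrt(np.mean(np.sum((moved_s - t_spts) ** 2, axis=1))))
    else:
        srms_val = None

    clashes = oracle_clash_count(model, receptor, ligand, clash_threshold)
    return MetricsRecord(
        fnat=fnat_val,
        lrms=lrms_val,
        irms=irms_val,
        srms=srms_val,
        clashes=clashes,
        n_common_residues=len({key for key, _ in shared}),
    )


# ---------------------------------------------------------------------------
# Decoys
# ---------------------------------------------------------------------------

def make_decoy(spec: DecoySpec) -> Tuple[AssemblyStructure, AssemblyStructure, MetricsRecord]:
    """Build (model, target, expected metrics) for one decoy.

    The last chain of the base complex is taken as the perturbed
    "ligand".  Expected metrics come from the module's own oracles; for
    a pure translation with no other perturbation the expected L_rms is
    |t| exactly (the receptor fit is the identity and every ligand atom
    deviates uniformly).
    """
    target = make_toy_complex(spec.base)
    ligand = target.chain_ids[-1]
    receptor = _oracle_receptor(target, target.chain_ids[0], ligand)

    model = target
    angle = math.radians(spec.rotation_angle_deg)
    if angle != 0.0:
        axis = np.asarray(spec.rotation_axis, float)
        axis = axis / np.linalg.norm(axis)
        R = Rotation.from_rotvec(angle * axis).as_matrix()
        centroid = model.chain_coords(ligand).mean(axis=0)
        model = model.transformed(R, centroid - R @ centroid, chain_ids=[ligand])
    t = np.asarray(spec.ligand_translation, float)
    if np.any(t != 0.0):
        model = model.transformed(np.eye(3), t, chain_ids=[ligand])
    if spec.sidechain_sigma > 0.0:
        rng = np.random.default_rng(spec.seed)
        model = _jitter_sidechains(model, spec.sidechain_sigma, rng)
    if spec.truncate > 0:
        chains = OrderedDict(
            (cid, list(residues) if cid != ligand else list(residues)[:-spec.truncate])
            for cid, residues in model.chains.items()
        )
        model = AssemblyStructure(chains, model.source_format, model.name + "_trunc")

    expected = oracle_metrics(model, target, receptor, ligand)
    pure_translation = (
        spec.rotation_angle_deg == 0.0
        and spec.sidechain_sigma == 0.0
        and spec.truncate == 0
    )
    if pure_translation:
        expected = replace(expected, lrms=float(np.linalg.norm(t)))
    return model, target, expected


def _oracle_receptor(structure: AssemblyStructure, a: str, b: str) -> str:
    na, nb = len(structure.chains[a]), len(structure.chains[b])
    if na > nb or (na == nb and a < b):
        return a
    return b


def _jitter_sidechains(structure: AssemblyStructure, sigma: float, rng) -> AssemblyStructure:
    chains: "OrderedDict[str, List[ResidueRecord]]" = OrderedDict()
    for cid, residues in structure.chains.items():
        out = []
        for r in residues:
            atoms = []
            for a in r.atoms:
                if a.name in ("N", "CA", "C", "O"):
                    atoms.append(a)
                else:
                    atoms.append(
                        AtomRecord(a.name, a.element,
                                   a.position + rng.normal(0.0, sigma, 3),
                                   a.occupancy, a.altloc)
                    )
            out.append(ResidueRecord(cid, r.seq_id, r.res_name, atoms))
        chains[cid] = out
    return AssemblyStructure(chains, structure.source_format, structure.name + "_jit")


def _oracle_classify(m: MetricsRecord) -> Category:
    """Independent re-statement of the category table for truth labels."""
    for name, fnat_floor, lrms_ceil, irms_ceil in CATEGORY_TABLE:
        if m.fnat >= fnat_floor and (m.lrms <= lrms_ceil or m.irms <= irms_ceil):
            return Category[name]
    return Category.Incorrect


def _boundary_safe(m: MetricsRecord, margin: float = 0.05) -> bool:
    """True when the label is stable under +-margin relative metric
    perturbation (keeps truth labels robust to floating-point detail)."""
    lo = replace(m, fnat=max(0.0, m.fnat * (1 - margin)),
                 lrms=m.lrms * (1 + margin), irms=m.irms * (1 + margin))
    hi = replace(m, fnat=min(1.0, m.fnat * (1 + margin)),
                 lrms=m.lrms * (1 - margin), irms=m.irms * (1 - margin))
    return _oracle_classify(lo) == _oracle_classify(m) == _oracle_classify(hi)


# per-category perturbation sampling ranges: translation magnitude (A),
# max rotation (deg)
_LADDER_RANGES = {
    "High": (0.1, 0.7, 2.0),
    "Medium": (1.5, 4.0, 6.0),
    "Acceptable": (4.5, 8.5, 10.0),
    "Incorrect": (14.0, 40.0, 180.0),
}


def make_decoy_ladder(
    base: ToyComplexSpec,
    n_per_category: int,
    seed: int = 0,
    max_attempts: int = 10_000,
) -> List[Tuple[DecoySpec, AssemblyStructure, AssemblyStructure, MetricsRecord, Category]]:
    """Rejection-sample decoys until each category holds *n_per_category*
    members, oracle-labelled and at least 5% clear of every threshold.

    Returns (spec, model, target, expected metrics, truth label) tuples.
    """
    if n_per_category < 1:
        raise ValueError("n_per_category must be >= 1")
    rng = np.random.default_rng(seed)
    out = []
    for cat_name, (t_lo, t_hi, rot_max) in _LADDER_RANGES.items():
        found = 0
        attempts = 0
        while found < n_per_category:
            attempts += 1
            if attempts > max_attempts:
                raise RuntimeError(
                    f"category {cat_name} unreachable in {max_attempts} attempts"
                )
            mag = rng.uniform(t_lo, t_hi)
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            spec = DecoySpec(
                base=base,
                ligand_translation=tuple(mag * direction),
                rotation_axis=tuple(axis),
                rotation_angle_deg=float(rng.uniform(0.0, rot_max)),
                seed=int(rng.integers(0, 2**31 - 1)),
                intended_category=cat_name,
            )
            model, target, expected = make_decoy(spec)
            label = _oracle_classify(expected)
            if label.name != cat_name or not _boundary_safe(expected):
                continue
            out.append((spec, model, target, expected, label))
            found += 1
    return out


# ---------------------------------------------------------------------------
# Submission manifests
# ---------------------------------------------------------------------------

# per-category DockQ sampling ranges for symbolic manifests
_DOCKQ_RANGES = {
    Category.Incorrect: (0.01, 0.20),
    Category.Acceptable: (0.25, 0.48),
    Category.Medium: (0.50, 0.78),
    Category.High: (0.82, 0.99),
}


def _skill_to_category(skill: float, u: float) -> Category:
    """Map a group skill in [0, 1] plus uniform noise to a category.

    Noise amplitude 0.3 keeps the extremes deterministic: skill 1 always
    yields High, skill 0 always Incorrect.
    """
    s = min(1.0, max(0.0, skill + 0.3 * (u - 0.5)))
    if s < 0.25:
        return Category.Incorrect
    if s < 0.5:
        return Category.Acceptable
    if s < 0.8:
        return Category.Medium
    return Category.High


def make_submission_manifest(
    n_groups: int,
    n_targets: int,
    quality_profile: Optional[Sequence[float]] = None,
    seed: int = 0,
    models_per_target: int = 5,
) -> List[SubmissionSet]:
    """Simulate ranked submissions for *n_groups* x *n_targets*.

    Each group has a skill in [0, 1] (given by *quality_profile* or
    spread evenly); per target it submits *models_per_target* ranked
    models whose categories are drawn from the skill and whose DockQ
    values are drawn from category-typical ranges.  Deterministic from
    *seed*.
    """
    if n_groups < 1 or n_targets < 1:
        raise ValueError("counts must be >= 1")
    if quality_profile is None:
        quality_profile = [1.0 - k / max(n_groups - 1, 1) for k in range(n_groups)]
    if len(quality_profile) != n_groups:
        raise ValueError("quality_profile length must equal n_groups")
    rng = np.random.default_rng(seed)
    targets = [f"T{k + 1:02d}" for k in range(n_targets)]
    sets = []
    for g, skill in enumerate(quality_profile):
        models: Dict[str, List[ModelEntry]] = {}
        for tid in targets:
            entries = []
            for rank in range(1, models_per_target + 1):
                cat = _skill_to_category(skill, rng.uniform())
                lo, hi = _DOCKQ_RANGES[cat]
                entries.append(
                    ModelEntry(
                        rank=rank,
                        label=QualityLabel(cat),
                        dockq=float(rng.uniform(lo, hi)),
                    )
                )
            models[tid] = entries
        sets.append(
            SubmissionSet(
                group_id=f"G{g + 1:02d}",
                role="predictor",
                models=models,
                top_n=models_per_target,
            )
        )
    return sets


# ---------------------------------------------------------------------------
# Transcribed round metadata
# ---------------------------------------------------------------------------

def _read_fixture(name: str) -> bytes:
    data = resources.files(_DATA_PACKAGE).joinpath(name).read_bytes()
    expected = _FIXTURE_CHECKSUMS[name]
    actual = hashlib.sha256(data).hexdigest()
    if actual != expected:
        raise ValueError(
            f"fixture {name} is corrupted: sha256 {actual} != expected {expected}"
        )
    return data


def load_target_table() -> Tuple[List[TargetRecord], List[AUDefinition]]:
    """Load the transcribed target table and the curated AU configs.

    Returns the 37 targets (with category, oligomer class and AU
    membership) and the AU definitions for the split targets (T203,
    T204, and the T219/T220/T221 family).
    """
    raw = _read_fixture("target_table.tsv").decode()
    lines = [ln for ln in raw.splitlines() if ln and not ln.startswith("#")]
    header = lines[0].split("\t")
    records = []
    for line in lines[1:]:
        row = dict(zip(header, line.split("\t")))
        records.append(
            TargetRecord(
                capri_id=row["capri_id"],
                casp_id=row["casp_id"],
                category=row["category"],
                kingdom=row["kingdom"],
                size=row["size"],
                bsa=row["bsa"],
                name=row["name"],
                oligomer_class=row["oligomer_class"],
                au_ids=tuple(row["au_ids"].split(";")),
            )
        )
    ids = [r.capri_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate target ids in fixture")

    aus: List[AUDefinition] = []
    import tempfile, os

    for name in ("au_t203.yaml", "au_t204.yaml", "au_t219_221.yaml"):
        data = _read_fixture(name)
        with tempfile.NamedTemporaryFile("wb", suffix=".yaml", delete=False) as fh:
            fh.write(data)
            tmp = fh.name
        try:
            aus.extend(load_au_config(tmp))
        finally:
            os.unlink(tmp)
    return records, aus


def au_accounting(records: Sequence[TargetRecord]) -> Dict[str, int]:
    """Summary counts: targets, distinct AUs, and oligomer classes."""
    au_ids = {au for r in records for au in r.au_ids}
    by_class = {}
    for r in records:
        by_class[r.oligomer_class] = by_class.get(r.oligomer_class, 0) + 1
    return {
        "n_targets": len(records),
        "n_assessment_units": len(au_ids),
        "n_homodimers": by_class.get("homodimer", 0),
        "n_homotrimers": by_class.get("homotrimer", 0),
        "n_heterodimers": by_class.get("heterodimer", 0),
        "n_large_assemblies": by_class.get("large", 0),
    }
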