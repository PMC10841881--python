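"""Interface quality metrics for one (model, target) interface pair.

The standard CAPRI protocol judges a predicted interface with three main
parameters — the fraction of recalled native contacts ``fnat``, the
ligand backbone RMSD after receptor superposition ``L_rms``, and the
interface backbone RMSD ``i_rms`` — complemented here by the side-chain
interface RMSD ``S_rms`` and an inter-chain steric clash count.

Conventions fixed by this module:

* distances use heavy atoms only (hydrogens are stripped at parse time);
* a native contact is a residue pair, one residue per chain, with any
  heavy-atom pair closer than the contact threshold (default 5 A);
* an interface residue has any heavy atom within the interface
  threshold (default 10 A) of the partner chain;
* atomic contacts below 3 A count as clashes;
* the receptor is the chain with more residues in the target pair,
  ties broken by lexicographic chain id — L_rms is asymmetric, so the
  convention matters and is applied consistently.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, FrozenSet, List, Optional, Set, Tuple

import numpy as np
from scipy.spatial import cKDTree

from .structure_io import (
    AssemblyStructure,
    ResidueCorrespondence,
    ResidueKey,
    ResidueRecord,
)

__all__ = [
    "CONTACT_THRESHOLD",
    "INTERFACE_THRESHOLD",
    "CLASH_THRESHOLD",
    "InterfaceDefinition",
    "MetricsRecord",
    "Superposition",
    "NotAssessable",
    "native_contacts",
    "model_contacts",
    "fnat",
    "clash_count",
    "superpose",
    "lrms",
    "irms",
    "srms",
    "compute_metrics",
    "order_pair",
]

CONTACT_THRESHOLD = 5.0    # A, residue-residue native contacts
INTERFACE_THRESHOLD = 10.0  # A, interface-residue definition
CLASH_THRESHOLD = 3.0       # A, atomic clashes

ContactPair = Tuple[ResidueKey, ResidueKey]


class NotAssessable(ValueError):
    """Raised when an interface has too little common material to score."""


@dataclass(frozen=True)
class InterfaceDefinition:
    """An interacting chain pair in the target.

    ``native_contacts`` holds (receptor residue, ligand residue) pairs;
    ``interface_residues`` the keys, on both chains, within the 10 A
    interface threshold of the partner chain.  Both are defined on the
    *target* coordinates only.
    """

    receptor_chain: str
    ligand_chain: str
    native_contacts: FrozenSet[ContactPair]
    interface_residues: FrozenSet[ResidueKey]
    contact_threshold: float = CONTACT_THRESHOLD
    interface_threshold: float = INTERFACE_THRESHOLD

    @property
    def assessable(self) -> bool:
        return len(self.native_contacts) > 0

    @property
    def interface_id(self) -> str:
        return f"{self.receptor_chain}:{self.ligand_chain}"


@dataclass
class MetricsRecord:
    """Per (model, interface) quality measures."""

    fnat: float
    lrms: float
    irms: float
    srms: Optional[float]  # None when no shared side-chain atoms exist
    clashes: int
    n_common_residues: int

    def __post_init__(self):
        if not 0.0 <= self.fnat <= 1.0:
            raise ValueError(f"fnat {self.fnat} outside [0, 1]")
        for name in ("lrms", "irms"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v >= 0):
                raise ValueError(f"{name} must be finite and non-negative, got {v}")
        if self.srms is not None and not (np.isfinite(self.srms) and self.srms >= 0):
            raise ValueError(f"srms must be finite and non-negative, got {self.srms}")


@dataclass(frozen=True)
class Superposition:
    """Optimal least-squares rigid transform ``x -> R x + t`` and its RMSD."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def __post_init__(self):
        R = np.asarray(self.rotation, float)
        if R.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8) or det_sign(R) < 0:
            raise ValueError("rotation must be proper orthonormal")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", np.asarray(self.translation, float))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def det_sign(R: np.ndarray) -> float:
    return float(np.sign(np.linalg.det(R)))


def order_pair(structure: AssemblyStructure, chain_a: str, chain_b: str) -> Tuple[str, str]:
    """Fix the (receptor, ligand) convention: more residues first, ties
    by chain id."""
    na, nb = len(structure.chains[chain_a]), len(structure.chains[chain_b])
    if (na, chain_b) > (nb, chain_a):  # more residues wins; tie -> smaller id
        return chain_a, chain_b
    if na == nb and chain_a < chain_b:
        return chain_a, chain_b
    return chain_b, chain_a


# ---------------------------------------------------------------------------
# Contacts and clashes
# ---------------------------------------------------------------------------

def _chain_atom_arrays(structure: AssemblyStructure, chain_id: str):
    """Coordinates plus a parallel list mapping atom row -> residue key."""
    coords = []
    owners: List[ResidueKey] = []
    for res in structure.chains[chain_id]:
        for a in res.atoms:
            coords.append(a.position)
            owners.append(res.key)
    return np.asarray(coords), owners


def _contact_pairs(
    structure: AssemblyStructure, receptor: str, ligand: str, threshold: float
) -> Set[ContactPair]:
    """Residue pairs with any heavy-atom pair within *threshold*.

    Uses a k-d tree; results are identical to all-pairs enumeration
    because the tree query is exact at the given radius.
    """
    r_coords, r_owners = _chain_atom_arrays(structure, receptor)
    l_coords, l_owners = _chain_atom_arrays(structure, ligand)
    tree_r = cKDTree(r_coords)
    tree_l = cKDTree(l_coords)
    pairs: Set[ContactPair] = set()
    hits = tree_r.query_ball_tree(tree_l, threshold, p=2.0)
    for i, js in enumerate(hits):
        for j in js:
            pairs.add((r_owners[i], l_owners[j]))
    return pairs


def native_contacts(
    target: AssemblyStructure,
    receptor: str,
    ligand: str,
    threshold: float = CONTACT_THRESHOLD,
    interface_threshold: float = INTERFACE_THRESHOLD,
) -> InterfaceDefinition:
    """Enumerate the target's native contacts and interface residues for
    one chain pair.

    An empty contact set is returned (not raised) with
    ``assessable == False`` so callers can skip non-interacting pairs.
    """
    if threshold <= 0 or interface_threshold <= 0:
        raise ValueError("thresholds must be positive")
    contacts = frozenset(_contact_pairs(target, receptor, ligand, threshold))
    iface_pairs = _contact_pairs(target, receptor, ligand, interface_threshold)
    interface_residues = frozenset(
        {r for r, _ in iface_pairs} | {l for _, l in iface_pairs}
    )
    return InterfaceDefinition(
        receptor_chain=receptor,
        ligand_chain=ligand,
        native_contacts=contacts,
        interface_residues=interface_residues,
        contact_threshold=threshold,
        interface_threshold=interface_threshold,
    )


def model_contacts(
    model: AssemblyStructure,
    corr: ResidueCorrespondence,
    iface: InterfaceDefinition,
) -> Set[ContactPair]:
    """Contacts present in the model, expressed in *target* residue keys."""
    t2m = corr.target_to_model()
    m2t = corr.model_to_target()
    # model chains carrying the two target chains
    r_chain = _model_chain_for(corr, iface.receptor_chain)
    l_chain = _model_chain_for(corr, iface.ligand_chain)
    if r_chain is None or l_chain is None:
        return set()
    raw = _contact_pairs(model, r_chain, l_chain, iface.contact_threshold)
    out: Set[ContactPair] = set()
    for mr, ml in raw:
        tr, tl = m2t.get(mr), m2t.get(ml)
        if tr is not None and tl is not None:
            out.add((tr, tl))
    return out


def _model_chain_for(corr: ResidueCorrespondence, target_chain: str) -> Optional[str]:
    for m, t in corr.pairs:
        if t[0] == target_chain:
            return m[0]
    return None


def fnat(
    model: AssemblyStructure,
    corr: ResidueCorrespondence,
    iface: InterfaceDefinition,
) -> float:
    """Fraction of the target's native contacts recalled in the model.

    The denominator is always the full native-contact count; contacts
    involving residues absent from the model count as missed, so a
    truncated model cannot inflate its recall.
    """
    if not iface.assessable:
        raise NotAssessable("interface has no native contacts")
    recalled = model_contacts(model, corr, iface) & iface.native_contacts
    return len(recalled) / len(iface.native_contacts)


def clash_count(
    model: AssemblyStructure,
    receptor: str,
    ligand: str,
    clash_threshold: float = CLASH_THRESHOLD,
) -> int:
    """Number of inter-chain heavy-atom pairs closer than the clash
    threshold (strictly below, default 3 A)."""
    r_coords, _ = _chain_atom_arrays(model, receptor)
    l_coords, _ = _chain_atom_arrays(model, ligand)
    tree_r = cKDTree(r_coords)
    tree_l = cKDTree(l_coords)
    # count_neighbors at radius r counts pairs with d <= r; back off an
    # epsilon so the rule is "strictly below threshold"
    eps = 1e-9
    return int(tree_r.count_neighbors(tree_l, clash_threshold - eps))


# ---------------------------------------------------------------------------
# Superposition and RMSDs
# ---------------------------------------------------------------------------

def superpose(moving: np.ndarray, fixed: np.ndarray) -> Superposition:
    """Least-squares optimal rigid superposition (Kabsch), reflections
    excluded.

    Returns the transform mapping *moving* onto *fixed* and the residual
    RMSD of the fit.
    """
    moving = np.asarray(moving, float)
    fixed = np.asarray(fixed, float)
    if moving.shape != fixed.shape or moving.ndim != 2 or moving.shape[1] != 3:
        raise ValueError("point sets must be equal-shape (n, 3) arrays")
    n = moving.shape[0]
    if n < 3:
        raise ValueError("need at least 3 points to superpose")
    mc = moving.mean(axis=0)
    fc = fixed.mean(axis=0)
    P = moving - mc
    Q = fixed - fc
    H = P.T @ Q
    U, S, Vt = np.linalg.svd(H)
    # degenerate: all points collinear -> two near-zero singular values
    if S[1] <= 1e-10 * max(S[0], 1.0):
        raise ValueError("degenerate (collinear) point set")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = fc - R @ mc
    rmsd = float(np.sqrt(np.mean(np.sum((P @ R.T - Q) ** 2, axis=1))))
    return Superposition(R, t, rmsd)


def _paired_backbone(
    model: AssemblyStructure,
    target: AssemblyStructure,
    corr: ResidueCorrespondence,
    target_keys,
) -> Tuple[np.ndarray, np.ndarray]:
    """Matched model/target backbone coordinates over the given target
    residues (atoms matched by name, missing atoms skipped)."""
    t2m = corr.target_to_model()
    m_pts, t_pts = [], []
    for tkey in sorted(target_keys):
        mkey = t2m.get(tkey)
        if mkey is None:
            continue
        t_res = target.residue(tkey)
        m_res = model.residue(mkey)
        for t_atom in t_res.backbone_atoms:
            m_atom = m_res.atom(t_atom.name)
            if m_atom is not None:
                m_pts.append(m_atom.position)
                t_pts.append(t_atom.position)
    if not m_pts:
        return np.empty((0, 3)), np.empty((0, 3))
    return np.asarray(m_pts), np.asarray(t_pts)


def lrms(
    model: AssemblyStructure,
    target: AssemblyStructure,
    corr: ResidueCorrespondence,
    iface: InterfaceDefinition,
) -> float:
    """Ligand backbone RMSD after superposing the receptor backbone.

    The receptor fit is computed over the common residue set; the
    resulting transform is applied to the model ligand backbone with no
    re-fit, and the RMSD to the target ligand backbone is reported.
    """
    r_keys = [t for _, t in corr.pairs if t[0] == iface.receptor_chain]
    l_keys = [t for _, t in corr.pairs if t[0] == iface.ligand_chain]
    m_rec, t_rec = _paired_backbone(model, target, corr, r_keys)
    m_lig, t_lig = _paired_backbone(model, target, corr, l_keys)
    if len(m_rec) < 3 or len(m_lig) < 3:
        raise NotAssessable("fewer than 3 common backbone atoms on receptor or ligand")
    fit = superpose(m_rec, t_rec)
    moved = fit.apply(m_lig)
    return float(np.sqrt(np.mean(np.sum((moved - t_lig) ** 2, axis=1))))


def _interface_fit(
    model: AssemblyStructure,
    target: AssemblyStructure,
    corr: ResidueCorrespondence,
    iface: InterfaceDefinition,
) -> Tuple[Superposition, np.ndarray, np.ndarray]:
    common_iface = iface.interface_residues & corr.target_keys
    m_pts, t_pts = _paired_backbone(model, target, corr, common_iface)
    if len(m_pts) < 3:
        raise NotAssessable("fewer than 3 common interface backbone atoms")
    fit = superpose(m_pts, t_pts)
    return fit, m_pts, t_pts


def irms(
    model: AssemblyStructure,
    target: AssemblyStructure,
    corr: ResidueCorrespondence,
    iface: InterfaceDefinition,
) -> float:
    """Backbone RMSD over the (target-defined) interface residues after
    superposing those very residues."""
    fit, _, _ = _interface_fit(model, target, corr, iface)
    return fit.rmsd


def srms(
    model: AssemblyStructure,
    target: AssemblyStructure,
    corr: ResidueCorrespondence,
    iface: InterfaceDefinition,
) -> Optional[float]:
    """Side-chain heavy-atom RMSD of interface residues under the i_rms
    backbone fit (no re-fit).

    Returns None when the interface shares no side-chain atoms (e.g. an
    all-glycine interface).
    """
    fit, _, _ = _interface_fit(model, target, corr, iface)
    t2m = corr.target_to_model()
    m_pts, t_pts = [], []
    for tkey in sorted(iface.interface_residues & corr.target_keys):
        mkey = t2m.get(tkey)
        if mkey is None:
            continue
        t_res = target.residue(tkey)
        m_res = model.residue(mkey)
        for t_atom in t_res.sidechain_atoms:
            m_atom = m_res.atom(t_atom.name)
            if m_atom is not None:
                m_pts.append(m_atom.position)
                t_pts.append(t_atom.position)
    if not m_pts:
        return None
    moved = fit.apply(np.asarray(m_pts))
    return float(np.sqrt(np.mean(np.sum((moved - np.asarray(t_pts)) ** 2, axis=1))))


def compute_metrics(
    model: AssemblyStructure,
    target: AssemblyStructure,
    corr: ResidueCorrespondence,
    iface: InterfaceDefinition,
    clash_threshold: float = CLASH_THRESHOLD,
) -> MetricsRecord:
    """All per-interface metrics in one record."""
    r_chain = _model_chain_for(corr, iface.receptor_chain)
    l_chain = _model_chain_for(corr, iface.ligand_chain)
    if r_chain is None or l_chain is None:
        raise NotAssessable("model does not cover both interface chains")
    return MetricsRecord(
        fnat=fnat(model, corr, iface),
        lrms=lrms(model, target, corr, iface),
        irms=irms(model, target, corr, iface),
        srms=srms(model, target, corr, iface),
        clashes=clash_count(model, r_chain, l_chain, clash_threshold),
        n_common_residues=len(corr.pairs),
    )
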