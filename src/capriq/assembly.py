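"""Whole-assembly evaluation: interface enumeration, chain-mapping
search, interface grouping, and assessment-unit (AU) aggregation.

Higher-order oligomers are evaluated by comparing each pair of
interacting subunits in the model to each relevant pair in the target.
For symmetric assemblies the model chain labelling is ambiguous, so the
model-to-target chain assignment is searched over all stoichiometry-
respecting permutations (exhaustively up to a budget, then greedily)
and the assignment giving the best summed interface quality is kept.

Identical or closely similar interfaces (symmetry copies) are grouped;
each group contributes its best replica.  An AU's CAPRI score is the
weighted count of its distinct interface groups by best achieved
category,

    Score_AU = w1 * n_ACC + w2 * n_MED + w3 * n_HIGH,   w = (1, 2, 3),

normalised by the number K of evaluated interface groups; its DockQ
score is the mean over groups of the best per-group DockQ.  Each group
is counted once, in its best category, which keeps Score_AU <= 3K.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple

import yaml

from .metrics import (
    InterfaceDefinition,
    MetricsRecord,
    NotAssessable,
    compute_metrics,
    native_contacts,
    order_pair,
)
from .quality import Category, DockQValue, QualityLabel, classify, dockq
from .structure_io import (
    AssemblyStructure,
    ChainMappingError,
    ResidueCorrespondence,
    build_correspondence,
)

__all__ = [
    "AU_WEIGHTS",
    "ChainMapping",
    "AUDefinition",
    "AUResult",
    "InterfaceResult",
    "enumerate_interfaces",
    "group_similar_interfaces",
    "best_chain_mapping",
    "score_au",
    "dockq_au",
    "evaluate_model",
    "load_au_config",
]

AU_WEIGHTS = (1, 2, 3)  # acceptable, medium, high


@dataclass
class ChainMapping:
    """A bijection from model chains to target chains, respecting
    sequence-equivalence classes, plus the quality basis that selected it."""

    assignment: Dict[str, str]
    score_basis: float = 0.0


@dataclass
class InterfaceResult:
    """Metrics + quality for one evaluated target interface."""

    interface_id: str
    metrics: Optional[MetricsRecord]
    label: QualityLabel
    dockq: Optional[DockQValue]
    assessable: bool = True

    @property
    def dockq_value(self) -> float:
        return self.dockq.value if self.dockq is not None else 0.0


@dataclass
class AUDefinition:
    """An assessment unit: disjoint groups of 'identical or closely
    similar' interfaces, possibly spanning several related targets.

    ``interface_groups`` maps group id -> set of member interface ids
    (an interface id is "CHAIN:CHAIN", optionally "TARGET/CHAIN:CHAIN"
    when the AU spans targets).
    """

    au_id: str
    interface_groups: Dict[str, FrozenSet[str]]
    member_targets: Tuple[str, ...] = ()

    def __post_init__(self):
        seen: Set[str] = set()
        for gid, members in self.interface_groups.items():
            if seen & set(members):
                raise ValueError(f"AU {self.au_id}: interface groups must be disjoint")
            seen |= set(members)

    @property
    def K(self) -> int:
        """Number of distinct (grouped) interfaces evaluated."""
        return len(self.interface_groups)

    @property
    def n_member_interfaces(self) -> int:
        return sum(len(m) for m in self.interface_groups.values())


@dataclass
class AUResult:
    """Aggregation of one model set over an AU's interface groups."""

    au_id: str
    per_group_best: Dict[str, Tuple[QualityLabel, float]]
    score_au: float
    score_au_norm: float
    dockq_au: float


# ---------------------------------------------------------------------------
# Interface enumeration and grouping
# ---------------------------------------------------------------------------

def enumerate_interfaces(
    target: AssemblyStructure,
    min_contacts: int = 1,
    contact_threshold: float = 5.0,
    interface_threshold: float = 10.0,
) -> List[InterfaceDefinition]:
    """One interface per chain pair with at least *min_contacts* native
    contacts, in deterministic (sorted chain-id) order."""
    if len(target.chain_ids) < 2:
        raise ValueError("target has fewer than 2 chains; nothing to assess")
    interfaces = []
    for a, b in itertools.combinations(sorted(target.chain_ids), 2):
        rec, lig = order_pair(target, a, b)
        iface = native_contacts(target, rec, lig, contact_threshold, interface_threshold)
        if len(iface.native_contacts) >= min_contacts:
            interfaces.append(iface)
    if not interfaces:
        raise ValueError("no chain pair forms an interface; nothing to assess")
    return interfaces


def _fingerprint(
    target: AssemblyStructure, iface: InterfaceDefinition
) -> FrozenSet[Tuple[int, int]]:
    """Chain-label-free contact fingerprint: contacts as pairs of
    per-chain sequence positions, so symmetry copies compare equal."""
    r_pos = {r.seq_id: i for i, r in enumerate(target.chains[iface.receptor_chain])}
    l_pos = {r.seq_id: i for i, r in enumerate(target.chains[iface.ligand_chain])}
    return frozenset(
        (r_pos[rk[1]], l_pos[lk[1]]) for rk, lk in iface.native_contacts
    )


def _jaccard(a: FrozenSet, b: FrozenSet) -> float:
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def group_similar_interfaces(
    interfaces: Sequence[InterfaceDefinition],
    target: AssemblyStructure,
    similarity_tolerance: float = 0.7,
    au_id: str = "AU1",
) -> AUDefinition:
    """Group interfaces whose relabelled contact fingerprints agree
    (Jaccard >= tolerance) and whose chains belong to the same
    sequence-equivalence classes.

    This automatic grouping serves generated complexes; curated AU
    definitions for real targets are supplied as explicit configuration
    instead (see :func:`load_au_config`).
    """
    classes = {
        cid: label
        for label, members in target.equivalence_classes().items()
        for cid in members
    }
    fps = [_fingerprint(target, ifc) for ifc in interfaces]
    class_pairs = [
        tuple(sorted((classes[ifc.receptor_chain], classes[ifc.ligand_chain])))
        for ifc in interfaces
    ]
    n = len(interfaces)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if class_pairs[i] != class_pairs[j]:
                continue
            # a symmetry copy may be enumerated in the opposite
            # receptor/ligand orientation; compare both ways
            flipped = frozenset((b, a) for a, b in fps[j])
            sim = max(_jaccard(fps[i], fps[j]), _jaccard(fps[i], flipped))
            if sim >= similarity_tolerance:
                parent[find(i)] = find(j)

    groups: Dict[int, List[str]] = {}
    for i, ifc in enumerate(interfaces):
        groups.setdefault(find(i), []).append(ifc.interface_id)
    interface_groups = {
        f"{au_id}.{k + 1}": frozenset(members)
        for k, (_, members) in enumerate(sorted(groups.items(), key=lambda kv: min(kv[1])))
    }
    return AUDefinition(au_id=au_id, interface_groups=interface_groups)


# ---------------------------------------------------------------------------
# Chain-mapping search
# ---------------------------------------------------------------------------

def _admissible_assignments(
    model: AssemblyStructure, target: AssemblyStructure, budget: int
):
    """Yield stoichiometry-respecting model->target chain bijections.

    Exhaustive while the permutation count stays within *budget*; beyond
    that only the identity-within-class assignment plus single swaps are
    explored (greedy fallback)."""
    m_classes = model.equivalence_classes()
    t_classes = target.equivalence_classes()
    m_counts = {k: len(v) for k, v in m_classes.items()}
    t_counts = {k: len(v) for k, v in t_classes.items()}
    # match classes by sequence content
    m_seq = {k: model.sequence(v[0]) for k, v in m_classes.items()}
    t_seq = {k: target.sequence(v[0]) for k, v in t_classes.items()}
    class_map: Dict[str, str] = {}
    used = set()
    for mk, seq in m_seq.items():
        match = next(
            (tk for tk, ts in t_seq.items() if tk not in used and _seqs_equivalent(seq, ts)),
            None,
        )
        if match is None or m_counts[mk] != t_counts[match]:
            raise ChainMappingError(
                f"incompatible stoichiometry: model {model.stoichiometry} "
                f"({m_counts}) vs target {target.stoichiometry} ({t_counts})"
            )
        class_map[mk] = match
        used.add(match)

    per_class_perms = []
    total = 1
    for mk, tk in class_map.items():
        m_members = m_classes[mk]
        t_members = t_classes[tk]
        perms = list(itertools.permutations(t_members))
        total *= len(perms)
        per_class_perms.append((m_members, perms))

    if total <= budget:
        for combo in itertools.product(*(perms for _, perms in per_class_perms)):
            assignment = {}
            for (m_members, _), perm in zip(per_class_perms, combo):
                assignment.update(dict(zip(m_members, perm)))
            yield assignment
    else:
        # greedy: identity-within-class plus all single transpositions
        base = {}
        for m_members, perms in per_class_perms:
            base.update(dict(zip(m_members, perms[0])))
        yield dict(base)
        for m_members, perms in per_class_perms:
            ids = list(m_members)
            for i in range(len(ids)):
                for j in range(i + 1, len(ids)):
                    alt = dict(base)
                    alt[ids[i]], alt[ids[j]] = base[ids[j]], base[ids[i]]
                    yield alt


def _seqs_equivalent(a: str, b: str, min_identity: float = 0.9) -> bool:
    if a == b:
        return True
    if abs(len(a) - len(b)) > 0.2 * max(len(a), len(b)):
        return False
    n = min(len(a), len(b))
    same = sum(x == y for x, y in zip(a, b))
    return same / max(n, 1) >= min_identity


def _evaluate_assignment(
    model: AssemblyStructure,
    target: AssemblyStructure,
    assignment: Dict[str, str],
    interfaces: Sequence[InterfaceDefinition],
    cache: Dict,
) -> Tuple[float, Dict[str, InterfaceResult]]:
    """Score one chain assignment: per-interface quality under it."""
    inv = {t: m for m, t in assignment.items()}
    results: Dict[str, InterfaceResult] = {}
    basis = 0.0
    for iface in interfaces:
        mr = inv.get(iface.receptor_chain)
        ml = inv.get(iface.ligand_chain)
        key = (iface.interface_id, mr, ml)
        if key not in cache:
            cache[key] = _single_interface_result(model, target, {mr: iface.receptor_chain,
                                                                  ml: iface.ligand_chain}, iface)
        res = cache[key]
        results[iface.interface_id] = res
        # category dominates, DockQ breaks ties
        basis += res.label.category.weight * 10.0 + res.dockq_value
    return basis, results


def _single_interface_result(
    model: AssemblyStructure,
    target: AssemblyStructure,
    chain_map: Dict[str, str],
    iface: InterfaceDefinition,
) -> InterfaceResult:
    try:
        corr = build_correspondence(model, target, chain_map)
        m = compute_metrics(model, target, corr, iface)
    except (NotAssessable, ChainMappingError):
        return InterfaceResult(
            interface_id=iface.interface_id,
            metrics=None,
            label=QualityLabel(Category.Incorrect),
            dockq=None,
            assessable=False,
        )
    label = classify(m)
    q = dockq(m.fnat, m.lrms, m.irms)
    return InterfaceResult(iface.interface_id, m, label, q)


def best_chain_mapping(
    model: AssemblyStructure,
    target: AssemblyStructure,
    interfaces: Sequence[InterfaceDefinition],
    permutation_budget: int = 40320,
) -> Tuple[ChainMapping, Dict[str, InterfaceResult]]:
    """Search model->target chain assignments and keep the one
    maximising summed interface quality (category first, DockQ
    tie-break).

    Non-assessable interfaces score Incorrect with a flag rather than
    erroring, so one bad chain does not void the whole assembly.
    """
    cache: Dict = {}
    best_basis = -1.0
    best_assignment = None
    best_results = None
    for assignment in _admissible_assignments(model, target, permutation_budget):
        basis, results = _evaluate_assignment(model, target, assignment, interfaces, cache)
        if basis > best_basis:
            best_basis, best_assignment, best_results = basis, assignment, results
    assert best_assignment is not None
    return ChainMapping(best_assignment, best_basis), best_results


def evaluate_model(
    model: AssemblyStructure,
    target: AssemblyStructure,
    min_contacts: int = 1,
    permutation_budget: int = 40320,
) -> Tuple[ChainMapping, Dict[str, InterfaceResult]]:
    """Convenience: enumerate target interfaces, then search the chain
    mapping."""
    interfaces = enumerate_interfaces(target, min_contacts=min_contacts)
    return best_chain_mapping(model, target, interfaces, permutation_budget)


# ---------------------------------------------------------------------------
# AU aggregation
# ---------------------------------------------------------------------------

def _best_in_group(
    results: Dict[str, InterfaceResult], members: FrozenSet[str]
) -> Tuple[QualityLabel, float]:
    """Best replica of a group: highest category, DockQ tie-break.
    Members missing from *results* contribute nothing; an empty group
    scores Incorrect / DockQ 0."""
    best_label = QualityLabel(Category.Incorrect)
    best_q = 0.0
    for mid in sorted(members):
        res = results.get(mid)
        if res is None:
            continue
        if (res.label.category, res.dockq_value) > (best_label.category, best_q):
            best_label, best_q = res.label, res.dockq_value
    return best_label, best_q


def score_au(
    au: AUDefinition,
    results: Dict[str, InterfaceResult],
    weights: Tuple[int, int, int] = AU_WEIGHTS,
) -> AUResult:
    """Aggregate per-interface results into the AU score.

    Each interface group is counted once, in its best achieved
    category (exclusive counting), then Score_AU = w1*n_ACC + w2*n_MED
    + w3*n_HIGH, normalised by K; the AU DockQ is the mean of the
    per-group best DockQ values.
    """
    per_group_best = {
        gid: _best_in_group(results, members)
        for gid, members in au.interface_groups.items()
    }
    n_acc = sum(1 for lab, _ in per_group_best.values() if lab.category == Category.Acceptable)
    n_med = sum(1 for lab, _ in per_group_best.values() if lab.category == Category.Medium)
    n_high = sum(1 for lab, _ in per_group_best.values() if lab.category == Category.High)
    w1, w2, w3 = weights
    score = w1 * n_acc + w2 * n_med + w3 * n_high
    k = au.K
    return AUResult(
        au_id=au.au_id,
        per_group_best=per_group_best,
        score_au=float(score),
        score_au_norm=score / k if k else 0.0,
        dockq_au=dockq_au({gid: q for gid, (_, q) in per_group_best.items()}),
    )


def dockq_au(per_group_best: Dict[str, float]) -> float:
    """Mean over distinct interface groups of the best per-group DockQ."""
    if not per_group_best:
        return 0.0
    vals = list(per_group_best.values())
    return float(sum(vals) / len(vals))


# ---------------------------------------------------------------------------
# AU configuration files
# ---------------------------------------------------------------------------

def load_au_config(path) -> List[AUDefinition]:
    """Load curated AU definitions from YAML.

    Schema::

        assessment_units:
          - au_id: AU219
            member_targets: [T219, T220, T221]
            interface_groups:
              AU219.1:
                - {member: T219.1, target: T219, chain_pairs: [[A, B], [B, C]]}
                ...

    Member interface ids are the per-target super-interfaces; their
    chain pairs identify the underlying subunit interfaces.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    aus = []
    for entry in doc["assessment_units"]:
        groups = {}
        for gid, members in entry["interface_groups"].items():
            ids = []
            for m in members:
                if isinstance(m, dict):
                    ids.append(str(m["member"]))
                else:
                    ids.append(str(m))
            groups[str(gid)] = frozenset(ids)
        aus.append(
            AUDefinition(
                au_id=str(entry["au_id"]),
                interface_groups=groups,
                member_targets=tuple(entry.get("member_targets", [])),
            )
        )
    return aus
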