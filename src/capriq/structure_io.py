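"""Reading, writing and aligning multi-chain protein assembly structures.

Structures are loaded from PDB or mmCIF into a light in-memory model
(:class:`AssemblyStructure`) that keeps only what interface assessment
needs: protein chains, residues and heavy atoms.  Hydrogens, waters and
non-polymer ligands are dropped at parse time, and alternate locations
are collapsed to the highest-occupancy conformer, so every downstream
distance computation sees a single, unambiguous set of heavy atoms.

Model-to-target residue correspondence is established by global sequence
alignment rather than author numbering, because predicted models are
frequently renumbered relative to the deposited reference.
"""

from __future__ import annotations

import string
from collections import Counter, OrderedDict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import gemmi
import numpy as np
from Bio import Align

__all__ = [
    "AtomRecord",
    "ResidueRecord",
    "AssemblyStructure",
    "ResidueCorrespondence",
    "StructureError",
    "ChainMappingError",
    "read_structure",
    "write_structure",
    "build_correspondence",
    "common_residue_set",
]

BACKBONE_ATOMS = ("N", "CA", "C", "O")

# 3-letter -> 1-letter, with common modified residues mapped to their
# parent amino acid so alignment treats them as identical.
_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "MSE": "M", "SEC": "C", "PYL": "K", "HYP": "P", "SEP": "S",
    "TPO": "T", "PTR": "Y", "CSO": "C", "MLY": "K",
}


class StructureError(ValueError):
    """Raised for unparseable, empty or unwritable structures."""


class ChainMappingError(ValueError):
    """Raised when a model chain cannot be mapped onto a target chain."""


# A residue is addressed by (chain_id, seq_id) where seq_id is the author
# residue number plus any insertion code, e.g. "100" or "100A".
ResidueKey = Tuple[str, str]


@dataclass(frozen=True)
class AtomRecord:
    """One heavy atom: label, element, Cartesian position in Angstrom."""

    name: str
    element: str
    position: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""

    def __post_init__(self):
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise StructureError(f"atom {self.name}: position must be a finite 3-vector")
        object.__setattr__(self, "position", pos)
        if not 0.0 <= self.occupancy <= 1.0:
            raise StructureError(f"atom {self.name}: occupancy {self.occupancy} outside [0, 1]")


@dataclass
class ResidueRecord:
    """One amino-acid residue with its heavy atoms."""

    chain_id: str
    seq_id: str
    res_name: str
    atoms: List[AtomRecord]

    def __post_init__(self):
        if not self.atoms:
            raise StructureError(
                f"residue {self.res_name} {self.chain_id}:{self.seq_id} has no atoms"
            )

    @property
    def key(self) -> ResidueKey:
        return (self.chain_id, self.seq_id)

    @property
    def one_letter(self) -> str:
        return _THREE_TO_ONE.get(self.res_name, "X")

    @property
    def backbone_atoms(self) -> List[AtomRecord]:
        return [a for a in self.atoms if a.name in BACKBONE_ATOMS]

    @property
    def sidechain_atoms(self) -> List[AtomRecord]:
        return [a for a in self.atoms if a.name not in BACKBONE_ATOMS]

    def atom(self, name: str) -> Optional[AtomRecord]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def coords(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms])


@dataclass
class AssemblyStructure:
    """A target or model complex: ordered chains of residues.

    ``stoichiometry`` is the multiset of sequence-equivalence classes,
    e.g. ``"A2"`` for a homodimer or ``"A3B1"`` for a trimer plus one
    distinct chain.  Chains with identical sequences share a class.
    """

    chains: "OrderedDict[str, List[ResidueRecord]]"
    source_format: str = "PDB"
    name: str = ""

    def __post_init__(self):
        for cid, residues in self.chains.items():
            for r in residues:
                if r.chain_id != cid:
                    raise StructureError(
                        f"residue {r.key} filed under chain {cid}: chain ids must agree"
                    )

    @property
    def chain_ids(self) -> List[str]:
        return list(self.chains.keys())

    @property
    def n_residues(self) -> int:
        return sum(len(r) for r in self.chains.values())

    @property
    def n_atoms(self) -> int:
        return sum(len(res.atoms) for residues in self.chains.values() for res in residues)

    def sequence(self, chain_id: str) -> str:
        return "".join(r.one_letter for r in self.chains[chain_id])

    def residue(self, key: ResidueKey) -> ResidueRecord:
        chain_id, seq_id = key
        for r in self.chains[chain_id]:
            if r.seq_id == seq_id:
                return r
        raise KeyError(key)

    def residue_index(self, chain_id: str) -> Dict[str, ResidueRecord]:
        return {r.seq_id: r for r in self.chains[chain_id]}

    def chain_coords(self, chain_id: str) -> np.ndarray:
        """All heavy-atom coordinates of one chain, in residue order."""
        return np.vstack([r.coords() for r in self.chains[chain_id]])

    def equivalence_classes(self) -> Dict[str, List[str]]:
        """Group chain ids by identical sequence; keys are class labels A, B, ..."""
        by_seq: "OrderedDict[str, List[str]]" = OrderedDict()
        for cid in self.chain_ids:
            by_seq.setdefault(self.sequence(cid), []).append(cid)
        labels = {}
        for label, (_, members) in zip(string.ascii_uppercase, by_seq.items()):
            labels[label] = members
        return labels

    @property
    def stoichiometry(self) -> str:
        return "".join(
            f"{label}{len(members)}" for label, members in self.equivalence_classes().items()
        )

    def transformed(self, rotation: np.ndarray, translation: np.ndarray,
                    chain_ids: Optional[Sequence[str]] = None) -> "AssemblyStructure":
        """Return a copy with ``x -> R x + t`` applied to the given chains
        (all chains when *chain_ids* is None)."""
        rot = np.asarray(rotation, float)
        tr = np.asarray(translation, float)
        which = set(chain_ids) if chain_ids is not None else set(self.chain_ids)
        new_chains: "OrderedDict[str, List[ResidueRecord]]" = OrderedDict()
        for cid, residues in self.chains.items():
            out = []
            for r in residues:
                if cid in which:
                    atoms = [
                        AtomRecord(a.name, a.element, rot @ a.position + tr,
                                   a.occupancy, a.altloc)
                        for a in r.atoms
                    ]
                else:
                    atoms = list(r.atoms)
                out.append(ResidueRecord(cid, r.seq_id, r.res_name, atoms))
            new_chains[cid] = out
        return AssemblyStructure(new_chains, self.source_format, self.name)


@dataclass
class ResidueCorrespondence:
    """Residue-level pairing between a model and its target.

    ``pairs`` maps (model chain, model seq_id) <-> (target chain, target
    seq_id); the mapping is injective in both directions and only covers
    residues present — and identical — in both structures.
    """

    pairs: List[Tuple[ResidueKey, ResidueKey]]
    per_chain_identity: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        model_keys = [m for m, _ in self.pairs]
        target_keys = [t for _, t in self.pairs]
        if len(set(model_keys)) != len(model_keys) or len(set(target_keys)) != len(target_keys):
            raise ChainMappingError("correspondence must be injective in both directions")

    def model_to_target(self) -> Dict[ResidueKey, ResidueKey]:
        return dict(self.pairs)

    def target_to_model(self) -> Dict[ResidueKey, ResidueKey]:
        return {t: m for m, t in self.pairs}

    @property
    def target_keys(self) -> set:
        return {t for _, t in self.pairs}

    def restricted_to_targets(self, keep: Iterable[ResidueKey]) -> "ResidueCorrespondence":
        keep = set(keep)
        return ResidueCorrespondence(
            [(m, t) for m, t in self.pairs if t in keep], dict(self.per_chain_identity)
        )

    def inverse(self) -> "ResidueCorrespondence":
        return ResidueCorrespondence(
            [(t, m) for m, t in self.pairs], dict(self.per_chain_identity)
        )


# ---------------------------------------------------------------------------
# Parsing and writing (gemmi-backed)
# ---------------------------------------------------------------------------

def _is_amino_acid(res_name: str) -> bool:
    if res_name in _THREE_TO_ONE:
        return True
    info = gemmi.find_tabulated_residue(res_name)
    return bool(info and info.is_amino_acid())


def read_structure(path, format_hint: Optional[str] = None) -> AssemblyStructure:
    """Read a PDB or mmCIF file into an :class:`AssemblyStructure`.

    Hydrogens are stripped, waters and non-protein HETATM entities are
    discarded, and for altloc duplicates only the highest-occupancy
    conformer is kept (ties broken by altloc letter).  Only the first
    MODEL of a multi-model file is read.
    """
    path = Path(path)
    if not path.exists():
        raise StructureError(f"no such file: {path}")
    fmt = (format_hint or "").lower()
    try:
        if fmt in ("pdb",):
            st = gemmi.read_pdb(str(path))
        elif fmt in ("cif", "mmcif"):
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        else:
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Detect)
    except (RuntimeError, ValueError) as exc:
        raise StructureError(f"cannot parse {path}: {exc}") from None
    source_format = "mmCIF" if st.input_format == gemmi.CoorFormat.Mmcif else "PDB"
    if len(st) == 0:
        raise StructureError(f"{path}: file contains no models")

    chains: "OrderedDict[str, List[ResidueRecord]]" = OrderedDict()
    model = st[0]
    for chain in model:
        residues: List[ResidueRecord] = []
        for res in chain:
            if not _is_amino_acid(res.name):
                continue
            # collapse altlocs: per atom name keep highest occupancy,
            # ties resolved by altloc letter order
            best: Dict[str, gemmi.Atom] = {}
            for atom in res:
                if atom.is_hydrogen():
                    continue
                prev = best.get(atom.name)
                if prev is None or (atom.occ, -ord(atom.altloc or "~")) > (
                    prev.occ, -ord(prev.altloc or "~")
                ):
                    best[atom.name] = atom
            if not best:
                continue
            atoms = [
                AtomRecord(
                    a.name,
                    a.element.name,
                    np.array([a.pos.x, a.pos.y, a.pos.z]),
                    min(max(a.occ, 0.0), 1.0),
                    (a.altloc or "").strip("\x00"),
                )
                for a in best.values()
            ]
            seq_id = f"{res.seqid.num}{(res.seqid.icode or '').strip()}"
            residues.append(ResidueRecord(chain.name, seq_id, res.name, atoms))
        if residues:
            chains[chain.name] = residues
    if not chains:
        raise StructureError(f"{path}: no protein residues found")
    return AssemblyStructure(chains, source_format=source_format, name=path.stem)


def write_structure(structure: AssemblyStructure, path, format: Optional[str] = None) -> None:
    """Write a structure as PDB or mmCIF (chosen from *format* or the
    file extension; default PDB)."""
    if not structure.chains:
        raise StructureError("refusing to write an empty structure")
    path = Path(path)
    fmt = (format or ("mmcif" if path.suffix.lower() in (".cif", ".mmcif") else "pdb")).lower()

    st = gemmi.Structure()
    st.name = structure.name or "assembly"
    model = gemmi.Model("1")
    for cid, residues in structure.chains.items():
        chain = gemmi.Chain(cid)
        for r in residues:
            res = gemmi.Residue()
            res.name = r.res_name
            num = r.seq_id.rstrip(string.ascii_letters)
            icode = r.seq_id[len(num):]
            res.seqid = gemmi.SeqId(int(num), icode or " ")
            res.het_flag = "A"
            for a in r.atoms:
                atom = gemmi.Atom()
                atom.name = a.name
                atom.element = gemmi.Element(a.element)
                atom.pos = gemmi.Position(*a.position)
                atom.occ = a.occupancy
                atom.altloc = a.altloc or "\x00"
                res.add_atom(atom)
            chain.add_residue(res)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    try:
        if fmt == "pdb":
            st.write_pdb(str(path))
        else:
            st.make_mmcif_document().write_file(str(path))
    except (RuntimeError, OSError) as exc:
        raise StructureError(f"cannot write {path}: {exc}") from None


# ---------------------------------------------------------------------------
# Residue correspondence
# ---------------------------------------------------------------------------

def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -0.5
    # end gaps free: truncated termini are common in models
    aligner.end_gap_score = 0.0
    return aligner


def build_correspondence(
    model: AssemblyStructure,
    target: AssemblyStructure,
    chain_map: Dict[str, str],
    min_identity: float = 0.3,
) -> ResidueCorrespondence:
    """Pair model and target residues chain by chain via global sequence
    alignment.

    Only aligned positions where the amino acid is identical are paired
    (model and target share the construct sequence, so substitutions
    signal a mis-mapping, not a mutation to tolerate).  A mapped chain
    pair aligning below *min_identity* raises :class:`ChainMappingError`.
    """
    aligner = _make_aligner()
    pairs: List[Tuple[ResidueKey, ResidueKey]] = []
    per_chain_identity: Dict[str, float] = {}
    for model_cid, target_cid in chain_map.items():
        if model_cid not in model.chains:
            raise ChainMappingError(f"model has no chain {model_cid!r}")
        if target_cid not in target.chains:
            raise ChainMappingError(f"target has no chain {target_cid!r}")
        m_res = model.chains[model_cid]
        t_res = target.chains[target_cid]
        m_seq = model.sequence(model_cid)
        t_seq = target.sequence(target_cid)
        alignment = aligner.align(m_seq, t_seq)[0]
        n_aligned = 0
        n_identical = 0
        chain_pairs = []
        for (m_i, t_i) in zip(*alignment.indices):
            if m_i < 0 or t_i < 0:
                continue
            n_aligned += 1
            if m_seq[m_i] == t_seq[t_i] and m_seq[m_i] != "X":
                n_identical += 1
                chain_pairs.append((m_res[m_i].key, t_res[t_i].key))
        identity = n_identical / max(n_aligned, 1)
        if identity < min_identity:
            raise ChainMappingError(
                f"chains {model_cid}->{target_cid}: {identity:.0%} sequence identity "
                f"after alignment; wrong chain_map?"
            )
        per_chain_identity[model_cid] = identity
        pairs.extend(chain_pairs)
    return ResidueCorrespondence(pairs, per_chain_identity)


def common_residue_set(correspondences: Sequence[ResidueCorrespondence]) -> ResidueCorrespondence:
    """Intersect the target-side residue sets of several model
    correspondences.

    Used in batch mode so that all models of one target are measured on
    identical residues.  The result is expressed as identity pairs over
    the common target residues; restrict each model's correspondence to
    it with :meth:`ResidueCorrespondence.restricted_to_targets`.
    """
    if not correspondences:
        raise ValueError("need at least one correspondence")
    common = set(correspondences[0].target_keys)
    for corr in correspondences[1:]:
        common &= corr.target_keys
    if not common:
        raise ValueError(
            "no residue is covered by every model; consider per-model evaluation mode"
        )
    ordered = sorted(common)
    return ResidueCorrespondence([(k, k) for k in ordered])
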