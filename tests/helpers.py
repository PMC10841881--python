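"""Independent oracles used by the test suite.

Everything here deliberately avoids the code paths it checks: contacts
and clashes by dense all-pairs enumeration, superposition by a random
rotation-grid search, category labels by a literal threshold-table
lookup, and group scores by plain spreadsheet-style loops.
"""

from __future__ import annotations

from collections import OrderedDict
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from capriq.structure_io import AssemblyStructure, AtomRecord, ResidueRecord


# --- structure construction -------------------------------------------------

def mini_structure(chains: Dict[str, List[Tuple[str, List[Tuple[str, tuple]]]]]):
    """Build an AssemblyStructure from plain data:
    {chain_id: [(res_name, [(atom_name, (x, y, z)), ...]), ...]}."""
    built = OrderedDict()
    for cid, residues in chains.items():
        recs = []
        for i, (res_name, atoms) in enumerate(residues):
            recs.append(
                ResidueRecord(
                    cid, str(i + 1), res_name,
                    [AtomRecord(name, name[0], np.array(pos, float))
                     for name, pos in atoms],
                )
            )
        built[cid] = recs
    return AssemblyStructure(built)


def identity_chain_map(structure: AssemblyStructure) -> Dict[str, str]:
    return {cid: cid for cid in structure.chain_ids}


# --- contact / clash oracles ------------------------------------------------

def allpairs_contacts(structure, chain_a, chain_b, threshold):
    """Residue contact pairs by dense distance-matrix enumeration."""
    coords_a, owners_a = _atoms(structure, chain_a)
    coords_b, owners_b = _atoms(structure, chain_b)
    dist = cdist(coords_a, coords_b)
    return {
        (owners_a[i], owners_b[j]) for i, j in zip(*np.nonzero(dist <= threshold))
    }


def allpairs_clashes(structure, chain_a, chain_b, threshold):
    coords_a, _ = _atoms(structure, chain_a)
    coords_b, _ = _atoms(structure, chain_b)
    return int(np.count_nonzero(cdist(coords_a, coords_b) < threshold))


def _atoms(structure, chain_id):
    coords, owners = [], []
    for res in structure.chains[chain_id]:
        for a in res.atoms:
            coords.append(a.position)
            owners.append(res.key)
    return np.asarray(coords), owners


# --- superposition grid oracle ----------------------------------------------

def grid_superpose_rmsd(moving, fixed, n_rotations=4000, seed=0):
    """Best RMSD over a dense random-rotation grid with centroid-matching
    translation; lower-bounds nothing, upper-bounds the optimum."""
    rng = np.random.default_rng(seed)
    moving = np.asarray(moving, float)
    fixed = np.asarray(fixed, float)
    P = moving - moving.mean(axis=0)
    Q = fixed - fixed.mean(axis=0)
    best = np.inf
    mats = Rotation.random(n_rotations, random_state=rng).as_matrix()
    for R in mats:
        rmsd = np.sqrt(np.mean(np.sum((P @ R.T - Q) ** 2, axis=1)))
        best = min(best, rmsd)
    return float(best)


# --- category / scoring oracles ---------------------------------------------

_TABLE = (
    ("High", 0.5, 1.0, 1.0),
    ("Medium", 0.3, 5.0, 2.0),
    ("Acceptable", 0.1, 10.0, 4.0),
)


def table_lookup_category(fnat, lrms, irms):
    """Literal threshold-table category lookup."""
    for name, f_floor, l_ceil, i_ceil in _TABLE:
        if fnat >= f_floor and (lrms <= l_ceil or irms <= i_ceil):
            return name
    return "Incorrect"


def spreadsheet_score_group(per_au_best_categories, per_au_norm=None, weights=(1, 2, 3)):
    """Direct weighted-sum recomputation: categories is {au: name};
    per_au_norm optionally replaces the category weight for multi-
    interface AUs."""
    w = {"Acceptable": weights[0], "Medium": weights[1], "High": weights[2],
         "Incorrect": 0}
    total = 0.0
    for au, cat in per_au_best_categories.items():
        if per_au_norm and au in per_au_norm:
            total += per_au_norm[au]
        else:
            total += w[cat]
    return total


def column_zscores_positive(matrix):
    """Per-column standardisation, negatives truncated, row sums."""
    m = np.asarray(matrix, float)
    sums = np.zeros(m.shape[0])
    for j in range(m.shape[1]):
        col = m[:, j]
        sd = col.std()
        if sd == 0:
            continue
        z = (col - col.mean()) / sd
        sums += np.maximum(z, 0.0)
    return sums
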