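"""Group rankings across targets/assessment units.

A predictor, server or scorer group is judged by the best model among
its top-ranked submissions (depth 5 by default, 1 for the top-1
analysis) for each target or AU.  Three ranking schemes are provided:

* the CAPRI score, Score_G = w1*N_ACC + w2*N_MED + w3*N_HIGH with
  weights (1, 2, 3), where the N are the numbers of targets/AUs whose
  best model reached (exactly) each category; multi-interface AUs
  contribute their normalised AU score instead of a category weight;
* the DockQ sum over per-AU best models — which, unlike the CAPRI
  score, also collects contributions from incorrect models;
* the positive-truncated Z-score sum: per AU, scores are standardised
  across groups, negative Z values are truncated to zero, and the
  per-group sums are ranked.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .quality import Category, QualityLabel

__all__ = [
    "ModelEntry",
    "SubmissionSet",
    "GroupScore",
    "top_n_selection",
    "score_group",
    "sum_dockq",
    "zscore_rank",
    "render_reports",
]

GROUP_WEIGHTS = (1, 2, 3)


@dataclass(frozen=True)
class ModelEntry:
    """One evaluated model of one AU: its submission rank and quality."""

    rank: int
    label: QualityLabel
    dockq: float
    au_norm_score: Optional[float] = None  # set for multi-interface AUs

    def __post_init__(self):
        if self.rank < 1:
            raise ValueError("ranks are 1-based")
        if not 0.0 <= self.dockq <= 1.0:
            raise ValueError(f"DockQ {self.dockq} outside [0, 1]")


@dataclass
class SubmissionSet:
    """All evaluated models of one group: AU id -> ranked models."""

    group_id: str
    role: str  # predictor | server | scorer
    models: Dict[str, List[ModelEntry]]
    top_n: int = 5

    def __post_init__(self):
        if self.top_n < 1:
            raise ValueError("top_n must be >= 1")
        if self.role not in ("predictor", "server", "scorer"):
            raise ValueError(f"unknown role {self.role!r}")
        for au, entries in self.models.items():
            ranks = [e.rank for e in entries]
            if len(set(ranks)) != len(ranks):
                raise ValueError(f"{self.group_id}/{au}: duplicate ranks")


@dataclass
class GroupScore:
    group_id: str
    role: str
    score_g: float
    n_acc: int
    n_med: int
    n_high: int
    sum_dockq: float
    n_correct: int
    sum_z: float = 0.0


def top_n_selection(entries: Sequence[ModelEntry], n: int) -> Optional[ModelEntry]:
    """Best model among the *n* top-ranked submissions.

    Best = highest category, then highest DockQ, then lowest submission
    rank.  Returns None when nothing was submitted within depth *n*.
    """
    pool = [e for e in entries if e.rank <= n]
    if not pool:
        return None
    return max(pool, key=lambda e: (e.label.category, e.dockq, -e.rank))


def score_group(
    submissions: SubmissionSet,
    au_universe: Sequence[str],
    weights: Tuple[int, int, int] = GROUP_WEIGHTS,
    top_n: Optional[int] = None,
) -> GroupScore:
    """Compute Score_G and companions for one group.

    Single-interface AUs contribute the weight of their best category;
    multi-interface AUs contribute their normalised AU score (carried on
    the entry).  Categories are counted exclusively — each AU once, in
    its best achieved category.  AUs with no submission contribute 0.
    """
    n = top_n if top_n is not None else submissions.top_n
    w = dict(zip((Category.Acceptable, Category.Medium, Category.High), weights))
    score = 0.0
    n_acc = n_med = n_high = n_correct = 0
    total_dockq = 0.0
    for au in au_universe:
        pool = [e for e in submissions.models.get(au, []) if e.rank <= n]
        best = top_n_selection(submissions.models.get(au, []), n)
        if best is None:
            continue
        # the DockQ sum takes the best DockQ in the pool, whatever its
        # category — incorrect models still contribute here
        total_dockq += max(e.dockq for e in pool)
        cat = best.label.category
        if cat == Category.Acceptable:
            n_acc += 1
        elif cat == Category.Medium:
            n_med += 1
        elif cat == Category.High:
            n_high += 1
        if cat >= Category.Acceptable:
            n_correct += 1
        if best.au_norm_score is not None:
            score += best.au_norm_score
        else:
            score += w.get(cat, 0)
    return GroupScore(
        group_id=submissions.group_id,
        role=submissions.role,
        score_g=score,
        n_acc=n_acc,
        n_med=n_med,
        n_high=n_high,
        sum_dockq=total_dockq,
        n_correct=n_correct,
    )


def sum_dockq(per_au_best_dockq: Dict[str, float]) -> float:
    """Sum of per-AU best DockQ values (0 for missing submissions).

    Note the contract difference with :func:`score_group`: sub-cutoff
    (incorrect) models still contribute their DockQ here.
    """
    return float(sum(per_au_best_dockq.values()))


def zscore_rank(
    matrix: pd.DataFrame, tie_break: bool = True
) -> pd.DataFrame:
    """Rank groups by summed positive Z-scores.

    *matrix* is groups x AUs of per-AU scores (DockQ or CAPRI
    contributions); missing submissions must already be entered as 0.
    Per AU, Z = (x - mean) / SD across groups; an AU with zero variance
    contributes Z = 0 for everyone; negative Z values are truncated to
    0.  Returns a DataFrame indexed by group with columns ``sum_z`` and
    ``rank`` (descending sum, ties broken by group id).
    """
    if matrix.shape[0] < 2:
        raise ValueError("Z-scores need at least 2 groups")
    values = matrix.to_numpy(dtype=float)
    mean = values.mean(axis=0)
    sd = values.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (values - mean) / sd
    z[:, sd == 0] = 0.0
    z = np.clip(z, 0.0, None)
    sums = z.sum(axis=1)
    out = pd.DataFrame({"sum_z": sums}, index=matrix.index)
    order = sorted(out.index, key=lambda g: (-out.loc[g, "sum_z"], str(g)))
    out = out.loc[order]
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def render_reports(
    scores: Sequence[GroupScore],
    au_results: Optional[Dict[str, Dict[str, ModelEntry]]] = None,
    out_dir=".",
) -> Dict[str, str]:
    """Write ranked TSVs per role plus a per-AU quality matrix.

    *au_results* maps group id -> AU id -> best entry (used for the
    matrix); returns the written file paths keyed by report name.
    """
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: Dict[str, str] = {}
    columns = [
        "group_id", "score_g", "n_high", "n_med", "n_acc",
        "n_correct", "sum_dockq", "sum_z",
    ]
    for role in ("predictor", "server", "scorer"):
        rows = [
            {c: getattr(s, c) for c in columns}
            for s in scores
            if s.role == role
        ]
        df = pd.DataFrame(rows, columns=columns)
        if not df.empty:
            df = df.sort_values(
                by=["score_g", "sum_dockq", "group_id"], ascending=[False, False, True]
            )
        path = out_dir / f"ranking_{role}.tsv"
        df.to_csv(path, sep="\t", index=False)
        written[f"ranking_{role}"] = str(path)

    if au_results is not None:
        aus = sorted({au for per_au in au_results.values() for au in per_au})
        rows = []
        for gid in sorted(au_results):
            row = {"group_id": gid}
            for au in aus:
                entry = au_results[gid].get(au)
                row[au] = entry.label.category.name if entry else "NoSubmission"
            rows.append(row)
        df = pd.DataFrame(rows, columns=["group_id"] + aus)
        path = out_dir / "au_matrix.tsv"
        df.to_csv(path, sep="\t", index=False)
        written["au_matrix"] = str(path)
    return written
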