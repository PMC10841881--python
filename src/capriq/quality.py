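"""CAPRI quality categories and the DockQ score.

A model interface is ranked into one of four discrete categories —
high, medium, acceptable, incorrect — from its (fnat, L_rms, i_rms)
triple, using the canonical CAPRI threshold table:

=========  =========  ==================================
category   fnat       rmsd condition (either suffices)
=========  =========  ==================================
High       >= 0.5     L_rms <= 1.0 A  or  i_rms <= 1.0 A
Medium     >= 0.3     L_rms <= 5.0 A  or  i_rms <= 2.0 A
Acceptable >= 0.1     L_rms <= 10.0 A or  i_rms <= 4.0 A
=========  =========  ==================================

Thresholds are inclusive.  The continuous DockQ score combines the same
three measures:

    DockQ = (fnat + rms_scaled(L_rms, d1) + rms_scaled(i_rms, d2)) / 3
    rms_scaled(r, d) = 1 / (1 + (r/d)^2)

with scaling constants d1 = 8.5 A (L_rms) and d2 = 1.5 A (i_rms) that
were previously optimised against the CAPRI criteria.  There is no
strict correspondence between DockQ and the discrete categories;
incorrect models roughly correspond to DockQ < 0.23, and
:func:`dockq_consistency` flags (diagnostically, never altering labels)
where the two views disagree.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

from .metrics import MetricsRecord

__all__ = [
    "D1",
    "D2",
    "DOCKQ_INCORRECT_CUTOFF",
    "CATEGORY_TABLE",
    "Category",
    "QualityLabel",
    "DockQValue",
    "rms_scaled",
    "dockq",
    "classify",
    "dockq_consistency",
]

D1 = 8.5   # A, L_rms scaling
D2 = 1.5   # A, i_rms scaling
DOCKQ_INCORRECT_CUTOFF = 0.23

# (name, fnat floor, lrms ceiling, irms ceiling), best first
CATEGORY_TABLE: Tuple[Tuple[str, float, float, float], ...] = (
    ("High", 0.5, 1.0, 1.0),
    ("Medium", 0.3, 5.0, 2.0),
    ("Acceptable", 0.1, 10.0, 4.0),
)


class Category(enum.IntEnum):
    """Ordered so that comparisons follow quality (higher is better)."""

    Incorrect = 0
    Acceptable = 1
    Medium = 2
    High = 3

    @property
    def weight(self) -> int:
        """Contribution weight in the weighted scores (1/2/3, 0 if incorrect)."""
        return int(self)


@dataclass(frozen=True)
class QualityLabel:
    category: Category
    disqualified: bool = False

    def __post_init__(self):
        if self.disqualified and self.category != Category.Incorrect:
            raise ValueError("a disqualified model must be labelled Incorrect")

    @property
    def correct(self) -> bool:
        return self.category >= Category.Acceptable


@dataclass(frozen=True)
class DockQValue:
    value: float
    d1: float = D1
    d2: float = D2
    incorrect_cutoff: float = DOCKQ_INCORRECT_CUTOFF

    def __post_init__(self):
        if not 0.0 < self.value <= 1.0 + 1e-12:
            raise ValueError(f"DockQ value {self.value} outside (0, 1]")

    @property
    def below_cutoff(self) -> bool:
        return self.value < self.incorrect_cutoff


def rms_scaled(rms: float, d: float) -> float:
    """Scaled rms deviation 1 / (1 + (rms/d)^2), in (0, 1]."""
    if rms < 0:
        raise ValueError("rms must be non-negative")
    if d <= 0:
        raise ValueError("scaling constant must be positive")
    return 1.0 / (1.0 + (rms / d) ** 2)


def dockq(fnat: float, lrms: float, irms: float, d1: float = D1, d2: float = D2) -> DockQValue:
    """The DockQ score of one interface."""
    if not 0.0 <= fnat <= 1.0:
        raise ValueError(f"fnat {fnat} outside [0, 1]")
    value = (fnat + rms_scaled(lrms, d1) + rms_scaled(irms, d2)) / 3.0
    return DockQValue(value=value, d1=d1, d2=d2)


def classify(
    m: MetricsRecord,
    disqualify: bool = False,
    table: Sequence[Tuple[str, float, float, float]] = CATEGORY_TABLE,
) -> QualityLabel:
    """Map a metrics record to its CAPRI category.

    *disqualify* applies the clash rule decided by the caller (the
    threshold is batch-relative, see :func:`clash_disqualification`);
    a disqualified model is forced Incorrect.
    """
    if disqualify:
        return QualityLabel(Category.Incorrect, disqualified=True)
    for name, fnat_floor, lrms_ceil, irms_ceil in table:
        if m.fnat >= fnat_floor and (m.lrms <= lrms_ceil or m.irms <= irms_ceil):
            return QualityLabel(Category[name])
    return QualityLabel(Category.Incorrect)


def clash_disqualification(
    clash_counts: Sequence[int],
    absolute_cap: Optional[int] = None,
    n_sd: float = 2.0,
) -> List[bool]:
    """Batch-relative clash rule: disqualify models whose clash count
    exceeds mean + *n_sd* standard deviations over the batch.

    With a single model (no batch context) only *absolute_cap* applies;
    when that is None, nothing is disqualified.
    """
    import numpy as np

    counts = np.asarray(clash_counts, float)
    flags = np.zeros(len(counts), dtype=bool)
    if len(counts) >= 2:
        cutoff = counts.mean() + n_sd * counts.std()
        flags |= counts > cutoff
    if absolute_cap is not None:
        flags |= counts > absolute_cap
    return list(flags)


@dataclass(frozen=True)
class ConsistencyReport:
    label: QualityLabel
    dockq: DockQValue
    discordant: bool
    note: str = ""


def dockq_consistency(label: QualityLabel, q: DockQValue) -> ConsistencyReport:
    """Flag label/DockQ disagreements around the incorrect cutoff.

    Diagnostic only — the discrete category is never altered.  A
    correct-category label with DockQ below the cutoff (or vice versa)
    is expected occasionally since the two schemes combine the metrics
    differently.
    """
    cat_correct = label.correct
    dockq_correct = not q.below_cutoff
    discordant = cat_correct != dockq_correct
    note = ""
    if discordant:
        note = (
            f"category {label.category.name} vs DockQ {q.value:.3f} "
            f"(cutoff {q.incorrect_cutoff}): no strict correspondence expected"
        )
    return ConsistencyReport(label=label, dockq=q, discordant=discordant, note=note)
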