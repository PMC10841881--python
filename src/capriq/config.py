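"""Run configuration: every tunable constant of the assessment in one
place, with YAML loading and CLI override precedence (CLI > file >
defaults)."""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Optional, Sequence, Tuple

import yaml

from .metrics import CLASH_THRESHOLD, CONTACT_THRESHOLD, INTERFACE_THRESHOLD
from .quality import CATEGORY_TABLE, D1, D2, DOCKQ_INCORRECT_CUTOFF

__all__ = ["RunConfig", "load_config"]

# standing round arithmetic: scorer groups each submit 5 ranked models
N_SCORER_GROUPS = 15
MODELS_PER_SUBMISSION = 5


@dataclass(frozen=True)
class RunConfig:
    contact_threshold: float = CONTACT_THRESHOLD
    interface_threshold: float = INTERFACE_THRESHOLD
    clash_threshold: float = CLASH_THRESHOLD
    d1: float = D1
    d2: float = D2
    incorrect_cutoff: float = DOCKQ_INCORRECT_CUTOFF
    category_table: Tuple[Tuple[str, float, float, float], ...] = CATEGORY_TABLE
    permutation_budget: int = 40320
    top_n: int = 5
    min_contacts: int = 1
    similarity_tolerance: float = 0.7
    clash_cap: Optional[int] = None  # absolute fallback for single-model mode
    output_dir: str = "."
    log_level: str = "INFO"
    seed: int = 0

    def __post_init__(self):
        for name in ("contact_threshold", "interface_threshold", "clash_threshold",
                     "d1", "d2", "incorrect_cutoff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.top_n < 1:
            raise ValueError("top_n must be >= 1")


def load_config(path=None, **overrides) -> RunConfig:
    """Build a RunConfig from an optional YAML file plus keyword
    overrides (overrides win; file entries beat defaults).

    The file may carry the keys either flat or under a ``quality:``
    section.
    """
    values = {}
    if path is not None:
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        section = doc.get("quality", {})
        merged = {**{k: v for k, v in doc.items() if k != "quality"}, **section}
        valid = {f.name for f in fields(RunConfig)}
        unknown = set(merged) - valid
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        values.update(merged)
    values.update({k: v for k, v in overrides.items() if v is not None})
    if "category_table" in values and not isinstance(values["category_table"], tuple):
        values["category_table"] = tuple(tuple(row) for row in values["category_table"])
    return RunConfig(**values)
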