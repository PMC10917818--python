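"""Week-resolved activity matrix and temporal classification of enhancers.

Each catalog enhancer gets a boolean activity vector over gestational weeks
4-8 (active in a week iff supported there by enough distinct samples) and a
temporal class:

* ``constant``       — active in all five weeks;
* ``week_specific``  — active in exactly one week;
* ``continuous``     — active in 2-4 weeks forming one contiguous run;
* ``non_continuous`` — >= 2 active weeks with at least one gap.

The four classes are exhaustive and mutually exclusive over rows with at
least one active week.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .catalog import WEEKS, EnhancerCatalog

__all__ = [
    "ActivityMatrix",
    "TEMPORAL_CLASSES",
    "build_activity_matrix",
    "classify_temporal",
    "classify_all",
    "week_transition_summary",
]

TEMPORAL_CLASSES = ("constant", "week_specific", "continuous", "non_continuous")


@dataclass
class ActivityMatrix:
    enhancer_ids: list[str]
    weeks: tuple[int, ...]
    active: np.ndarray  # bool, (n_enhancers, n_weeks)

    def __post_init__(self) -> None:
        self.active = np.asarray(self.active, dtype=bool)
        if self.active.shape != (len(self.enhancer_ids), len(self.weeks)):
            raise ValueError("activity matrix shape mismatch")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.active, columns=[f"wk{w}" for w in self.weeks]
        )
        df.insert(0, "enhancer_id", self.enhancer_ids)
        return df


def build_activity_matrix(
    catalog: EnhancerCatalog, min_samples_per_week: int = 2
) -> ActivityMatrix:
    """active[e, w] iff >= ``min_samples_per_week`` distinct samples of week w
    support enhancer e. With the same threshold used for catalog membership
    (and the within-week reproducibility scope), every row has an active week."""
    active = np.zeros((len(catalog), len(WEEKS)), dtype=bool)
    for i in range(len(catalog)):
        for j, w in enumerate(WEEKS):
            active[i, j] = len(catalog.support[i].get(w, frozenset())) >= min_samples_per_week
    return ActivityMatrix(list(catalog.ids), WEEKS, active)


def classify_temporal(row) -> str:
    """Classify one boolean activity vector; raises on an all-false row."""
    row = np.asarray(row, dtype=bool)
    n = int(row.sum())
    if n == 0:
        raise ValueError("all-false activity row cannot be classified")
    if n == row.size:
        return "constant"
    if n == 1:
        return "week_specific"
    idx = np.flatnonzero(row)
    contiguous = idx[-1] - idx[0] + 1 == n
    return "continuous" if contiguous else "non_continuous"


def classify_all(m: ActivityMatrix) -> pd.DataFrame:
    """Per-enhancer class table plus weekly booleans."""
    df = m.to_frame()
    df["temporal_class"] = [classify_temporal(m.active[i]) for i in range(len(df))]
    return df


def week_transition_summary(m: ActivityMatrix) -> pd.DataFrame:
    """Gained / lost / retained enhancer counts for each adjacent week pair."""
    if len(m.weeks) < 2:
        raise ValueError("need at least two weeks")
    rows = []
    for j in range(len(m.weeks) - 1):
        a, b = m.active[:, j], m.active[:, j + 1]
        rows.append({
            "week_from": m.weeks[j],
            "week_to": m.weeks[j + 1],
            "retained": int((a & b).sum()),
            "gained": int((~a & b).sum()),
            "lost": int((a & ~b).sum()),
        })
    return pd.DataFrame(rows)
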