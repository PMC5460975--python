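"""Recognition-memory indices and covariate preparation.

Two-high-threshold indices from old/new recognition counts (hits collapsed
over Remember and Know responses): discrimination Pr = P_hit - P_fa and
response bias Br = P_fa / (1 - Pr), with Br > 0.5 indicating a liberal bias
to respond "old". Pr on the drug-free session serves as the performance
covariate in the group analyses, mean-centered within age group, with a
single-pass 2.5 SD within-group outlier exclusion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "RecognitionCounts",
    "BehavioralSummary",
    "pr_index",
    "br_index",
    "center_covariate",
    "flag_covariate_outliers",
    "read_behavior_csv",
]


@dataclass(frozen=True)
class RecognitionCounts:
    n_old: int
    n_new: int
    hits: int
    false_alarms: int

    def __post_init__(self) -> None:
        if self.n_old <= 0 or self.n_new <= 0:
            raise ValueError("item counts must be positive")
        if not 0 <= self.hits <= self.n_old:
            raise ValueError("hits must lie in [0, n_old]")
        if not 0 <= self.false_alarms <= self.n_new:
            raise ValueError("false_alarms must lie in [0, n_new]")


@dataclass(frozen=True)
class BehavioralSummary:
    pr: float
    br: float | None
    pr_centered: float | None = None


def pr_index(c: RecognitionCounts) -> float:
    """Discrimination index Pr = hit rate - false-alarm rate."""
    return c.hits / c.n_old - c.false_alarms / c.n_new


def br_index(c: RecognitionCounts) -> float:
    """Response bias Br = false-alarm rate / (1 - Pr); undefined at Pr = 1."""
    pr = pr_index(c)
    if pr == 1:
        raise ValueError("Br undefined at Pr = 1")
    return (c.false_alarms / c.n_new) / (1.0 - pr)


def center_covariate(values: pd.Series, group: pd.Series) -> pd.Series:
    """Subtract the within-group mean; each group's output mean is 0."""
    values = pd.Series(values)
    return values - values.groupby(pd.Series(group).to_numpy()).transform("mean")


def flag_covariate_outliers(
    values: pd.Series, group: pd.Series, z_thresh: float = 2.5
) -> list:
    """Subjects whose covariate deviates > z_thresh within-group SDs.

    Single pass: group mean and SD are computed once, on all subjects.
    """
    values = pd.Series(values)
    group = pd.Series(group, index=values.index)
    flagged = []
    for g, sl in values.groupby(group.to_numpy()):
        if len(sl) < 3:
            raise ValueError(f"group {g!r} has fewer than 3 subjects")
        sd = sl.std(ddof=1)
        if sd == 0:
            continue
        z = (sl - sl.mean()).abs() / sd
        flagged.extend(sl.index[z > z_thresh].tolist())
    return flagged


def read_behavior_csv(path) -> pd.DataFrame:
    """Load behavioral counts; Remember and Know hits are collapsed.

    Expects columns subject, group, drug, n_old, n_new, hits_r, hits_k, fa.
    Adds ``hits``, ``pr`` and ``br`` columns.
    """
    df = pd.read_csv(path)
    df["hits"] = df["hits_r"] + df["hits_k"]
    counts = [
        RecognitionCounts(r.n_old, r.n_new, r.hits, r.fa) for r in df.itertuples()
    ]
    df["pr"] = [pr_index(c) for c in counts]
    df["br"] = [br_index(c) if pr_index(c) != 1 else np.nan for c in counts]
    return df
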