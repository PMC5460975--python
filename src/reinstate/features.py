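"""ANOVA-based voxel selection.

Voxels are ranked by a two-group (semantic vs. phonological) one-way ANOVA F
computed on training-phase scans only, and the top-N form the feature set for
decoding. Candidate set sizes default to {500, 150, 50}; a per-ROI choice
rule picks, among sizes showing no age-group difference in Placebo task
specificity, the one maximizing grand-mean accuracy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FeatureSet",
    "DEFAULT_SET_SIZES",
    "ROI_PRESET_SIZES",
    "anova_f_per_voxel",
    "select_top",
    "choose_set_size",
    "SetSizeChoice",
]

DEFAULT_SET_SIZES = (500, 150, 50)

# Per-ROI set sizes frozen from the reference analysis configuration:
# prefrontal ROIs use 500 voxels, hippocampus 50, the two posterior ROIs 150.
ROI_PRESET_SIZES = {
    "LIFG": 500,
    "RIFG": 500,
    "LMFG": 500,
    "RMFG": 500,
    "HC": 50,
    "LSOG": 150,
    "FusG": 150,
}


@dataclass(frozen=True)
class FeatureSet:
    """Ordered selected voxels (descending F) for one ROI/training set."""

    roi_name: str
    voxel_indices: np.ndarray
    f_values: np.ndarray
    set_size: int

    def __post_init__(self) -> None:
        idx = np.asarray(self.voxel_indices)
        if len(np.unique(idx)) != idx.size:
            raise ValueError("voxel indices must be unique")

    def __len__(self) -> int:
        return len(self.voxel_indices)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "roi": self.roi_name,
                "rank": np.arange(len(self)),
                "voxel_index": self.voxel_indices,
                "F": self.f_values,
            }
        )


def anova_f_per_voxel(data: np.ndarray, task_codes: np.ndarray) -> np.ndarray:
    """Two-group one-way ANOVA F per voxel, fixation scans excluded.

    ``task_codes`` is the per-scan +1/-1/0 coding; scans with code 0
    (fixation) are dropped. F = between-group MS / within-group MS. A voxel
    with zero within-group variance but nonzero group difference gets +inf;
    zero between-group variance gives 0.
    """
    codes = np.asarray(task_codes, dtype=float)
    mask = codes != 0
    x = np.asarray(data, dtype=float)[mask]
    g = codes[mask]
    a = x[g > 0]
    b = x[g < 0]
    n_a, n_b = a.shape[0], b.shape[0]
    if n_a < 2 or n_b < 2:
        raise ValueError("each task condition needs at least 2 training scans")
    mean_a = a.mean(axis=0)
    mean_b = b.mean(axis=0)
    grand = x.mean(axis=0)
    ss_between = n_a * (mean_a - grand) ** 2 + n_b * (mean_b - grand) ** 2
    ss_within = ((a - mean_a) ** 2).sum(axis=0) + ((b - mean_b) ** 2).sum(axis=0)
    ms_between = ss_between  # df = 1
    ms_within = ss_within / (n_a + n_b - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = ms_between / ms_within
    f = np.where(ms_between == 0, 0.0, f)
    f = np.where((ms_within == 0) & (ms_between > 0), np.inf, f)
    return f


def select_top(f_values: np.ndarray, n: int, roi_name: str = "roi") -> FeatureSet:
    """Indices of the ``n`` largest F, descending; ties by ascending index.

    ``n`` larger than the number of voxels clamps to all voxels with a
    warning.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    f = np.asarray(f_values, dtype=float)
    if n > f.size:
        warnings.warn(
            f"requested {n} voxels but only {f.size} available; using all",
            stacklevel=2,
        )
        n = f.size
    # lexsort: primary key descending F, secondary ascending index
    order = np.lexsort((np.arange(f.size), -f))[:n]
    return FeatureSet(roi_name, order, f[order], set_size=n)


@dataclass(frozen=True)
class SetSizeChoice:
    size: int
    rationale: str
    confounded: bool
    table: pd.DataFrame


def choose_set_size(
    placebo_results: pd.DataFrame,
    sizes: tuple[int, ...] = DEFAULT_SET_SIZES,
    alpha: float = 0.05,
) -> SetSizeChoice:
    """Pick a feature-set size from Placebo task-specificity results.

    ``placebo_results`` is a long table with columns ``subject``, ``group``,
    ``set_size``, ``value`` (task specificity on Placebo). Among sizes with
    no significant young/old difference (two-sample t-test at ``alpha``),
    the size maximizing grand-mean accuracy wins; mean ties break to the
    smaller size. If every size shows a group difference, the size with the
    smallest absolute group difference is chosen and the result flagged as
    confounded.
    """
    rows = []
    for size in sizes:
        sl = placebo_results[placebo_results["set_size"] == size]
        if sl.empty:
            continue
        young = sl.loc[sl["group"] == "young", "value"].to_numpy()
        old = sl.loc[sl["group"] == "old", "value"].to_numpy()
        _, p = stats.ttest_ind(young, old)
        rows.append(
            {
                "set_size": size,
                "grand_mean": sl["value"].mean(),
                "group_diff": young.mean() - old.mean(),
                "p_group": p,
            }
        )
    if len(rows) < 2:
        raise ValueError("need results for at least 2 set sizes")
    table = pd.DataFrame(rows)
    eligible = table[table["p_group"] > alpha]
    if not eligible.empty:
        best = eligible.sort_values(
            ["grand_mean", "set_size"], ascending=[False, True]
        ).iloc[0]
        return SetSizeChoice(
            int(best["set_size"]),
            "maximum grand-mean accuracy among sizes without a group difference",
            False,
            table,
        )
    best = table.loc[table["group_diff"].abs().idxmin()]
    return SetSizeChoice(
        int(best["set_size"]),
        "all sizes group-confounded; minimized |group difference|",
        True,
        table,
    )
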