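"""Correlation-distance metric of encoding-retrieval reinstatement.

A model-free replication of the ridge memory-specificity measure: block-mean
activity patterns are formed per task and phase (discarding fixation scans
and the first scans of each block to allow for hemodynamic delay), and
memory specificity is the mean within-task minus the mean between-task
Pearson correlation across phases.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .features import FeatureSet
from .preprocess import RoiTimeseries

__all__ = [
    "PhaseMeanPatterns",
    "block_mean_patterns",
    "memory_specificity_corr",
    "within_between_components",
]


@dataclass(frozen=True)
class PhaseMeanPatterns:
    """Task-mean voxel patterns per phase, in feature-set voxel order."""

    sem_enc: np.ndarray
    phon_enc: np.ndarray
    sem_ret: np.ndarray
    phon_ret: np.ndarray
    n_scans_used: dict[str, list[int]]


def _task_means(
    ts: RoiTimeseries, cols: np.ndarray, discard_first: int
) -> tuple[np.ndarray, np.ndarray, list[int]]:
    """Per-task mean over block means, dropping the first scans of each block.

    ``discard_first`` counts block scans only (fixation scans are already
    excluded); block scans with 0-based within-block rank < discard_first
    are dropped.
    """
    blocks = ts.block_indices
    ranks = np.array(
        [-1 if a.within_block_rank is None else a.within_block_rank
         for a in ts.annotations]
    )
    sem_means, phon_means, counts = [], [], []
    for b in range(blocks.max() + 1):
        keep = np.flatnonzero((blocks == b) & (ranks >= discard_first))
        if keep.size == 0:
            raise ValueError(f"block {b} fully discarded (discard_first too large)")
        counts.append(int(keep.size))
        mean = ts.data[np.ix_(keep, cols)].mean(axis=0)
        task = ts.annotations[keep[0]].task
        (sem_means if task.code > 0 else phon_means).append(mean)
    return (
        np.mean(sem_means, axis=0),
        np.mean(phon_means, axis=0),
        counts,
    )


def block_mean_patterns(
    study_ts: RoiTimeseries,
    test_ts_pair: tuple[RoiTimeseries, RoiTimeseries | None],
    feature_set: FeatureSet,
    discard_first: int = 7,
) -> PhaseMeanPatterns:
    """Task-mean patterns for encoding and retrieval, feature-set voxels only.

    Retrieval blocks from both test sessions are pooled before averaging.
    """
    cols = feature_set.voxel_indices
    sem_enc, phon_enc, n_enc = _task_means(study_ts, cols, discard_first)
    sem_parts, phon_parts, n_ret = [], [], []
    for ts in test_ts_pair:
        if ts is None:
            continue
        s, p, n = _task_means(ts, cols, discard_first)
        sem_parts.append(s)
        phon_parts.append(p)
        n_ret.extend(n)
    if not sem_parts:
        raise ValueError("no retrieval sessions provided")
    return PhaseMeanPatterns(
        sem_enc=sem_enc,
        phon_enc=phon_enc,
        sem_ret=np.mean(sem_parts, axis=0),
        phon_ret=np.mean(phon_parts, axis=0),
        n_scans_used={"encoding": n_enc, "retrieval": n_ret},
    )


def _corr(a: np.ndarray, b: np.ndarray, fisher_z: bool) -> float:
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("constant pattern vector: correlation undefined")
    r = float(stats.pearsonr(a, b).statistic)
    return float(np.arctanh(r)) if fisher_z else r


def within_between_components(
    p: PhaseMeanPatterns, fisher_z: bool = False
) -> tuple[float, float]:
    """(mean within-task, mean between-task) encoding-retrieval correlation."""
    within = 0.5 * (
        _corr(p.sem_enc, p.sem_ret, fisher_z) + _corr(p.phon_enc, p.phon_ret, fisher_z)
    )
    between = 0.5 * (
        _corr(p.sem_enc, p.phon_ret, fisher_z) + _corr(p.phon_enc, p.sem_ret, fisher_z)
    )
    return within, between


def memory_specificity_corr(p: PhaseMeanPatterns, fisher_z: bool = False) -> float:
    """Within-task minus between-task mean correlation across phases."""
    within, between = within_between_components(p, fisher_z)
    return within - between
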