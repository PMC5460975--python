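"""Ridge-regression decoding of task context from ROI activity.

Task specificity is the leave-one-block-pair-out cross-validated accuracy of
a ridge regressor trained to discriminate semantic from phonological
mini-blocks within the encoding phase. Memory specificity is the accuracy
with which the encoding-trained regressor predicts the cued task during the
two retrieval sessions (averaged), i.e., reinstatement of the encoding
pattern at retrieval. Performance is the Pearson correlation of the
continuous predictions with the HRF-convolved +/-1 targets of the test set
(range -1..1, chance = 0). The ridge penalty λ is chosen per subject by
nested cross-validation over the grid (0, 0.01, 0.1, 1, 10, 100, 1000,
10000) on Placebo encoding data and reused for all subsequent analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .features import FeatureSet, anova_f_per_voxel, select_top
from .preprocess import RoiTimeseries

__all__ = [
    "DEFAULT_PENALTY_GRID",
    "RidgeConfig",
    "TrainedDecoder",
    "SpecificityRecord",
    "fit_ridge",
    "predict",
    "performance_corr",
    "nested_cv_penalty",
    "block_pair_folds",
    "task_specificity",
    "memory_specificity_ridge",
]

DEFAULT_PENALTY_GRID = (0.0, 0.01, 0.1, 1.0, 10.0, 100.0, 1000.0, 10000.0)


@dataclass(frozen=True)
class RidgeConfig:
    penalty_grid: tuple[float, ...] = DEFAULT_PENALTY_GRID
    chosen_penalty: float | None = None
    selection_context: str = ""


@dataclass(frozen=True)
class TrainedDecoder:
    weights: np.ndarray
    target_mean: float
    feature_set: FeatureSet | None
    penalty: float
    pinv_used: bool = False


@dataclass(frozen=True)
class SpecificityRecord:
    subject_id: str
    group: str
    drug: str
    roi_name: str
    metric: str  # task_ridge | memory_ridge | memory_corr
    value: float


def fit_ridge(X: np.ndarray, y: np.ndarray, penalty: float) -> TrainedDecoder:
    """Closed-form penalized least squares.

    The target is centered by its mean before fitting; weights minimize
    ||y - Xw||^2 + λ||w||^2 via the normal equations. At λ=0 with
    rank-deficient X the pseudo-inverse solution is used and flagged.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if penalty < 0:
        raise ValueError("penalty must be >= 0")
    if not np.all(np.isfinite(X)):
        raise ValueError("X must be finite")
    mu = y.mean()
    yc = y - mu
    gram = X.T @ X
    b = X.T @ yc
    pinv_used = False
    if penalty == 0:
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            w = np.linalg.pinv(X) @ yc
            pinv_used = True
        else:
            w = np.linalg.solve(gram, b)
    else:
        w = np.linalg.solve(gram + penalty * np.eye(X.shape[1]), b)
    return TrainedDecoder(w, float(mu), None, float(penalty), pinv_used)


def predict(decoder: TrainedDecoder, X_test: np.ndarray) -> np.ndarray:
    X_test = np.asarray(X_test, dtype=float)
    if X_test.shape[1] != decoder.weights.size:
        raise ValueError(
            f"feature mismatch: test has {X_test.shape[1]} columns, "
            f"decoder was trained on {decoder.weights.size}"
        )
    return X_test @ decoder.weights + decoder.target_mean


def performance_corr(predictions: np.ndarray, test_targets: np.ndarray) -> float:
    """Pearson correlation of continuous predictions with test-set targets.

    Constant predictions (undefined correlation) map to 0, the chance level
    of the metric, with a warning. Callers exclude fixation scans from both
    vectors before calling.
    """
    p = np.asarray(predictions, dtype=float)
    t = np.asarray(test_targets, dtype=float)
    if p.size < 3:
        raise ValueError("need at least 3 scans")
    if np.ptp(t) == 0:
        raise ValueError("test targets are constant")
    if np.ptp(p) == 0:
        warnings.warn("constant predictions: performance set to 0", stacklevel=2)
        return 0.0
    return float(np.corrcoef(p, t)[0, 1])


def _solve_gram(gram: np.ndarray, b: np.ndarray, penalty: float) -> np.ndarray:
    a = gram + penalty * np.eye(gram.shape[0])
    try:
        return np.linalg.solve(a, b)
    except np.linalg.LinAlgError:
        return np.linalg.lstsq(a, b, rcond=None)[0]


def nested_cv_penalty(
    folds: list[tuple[np.ndarray, np.ndarray]],
    grid: tuple[float, ...] = DEFAULT_PENALTY_GRID,
) -> float:
    """Subject-level penalty choice by nested cross-validation.

    ``folds`` is the list of (X, y) outer cross-validation subsets. For each
    outer fold, an inner leave-one-fold-out loop over the remaining folds
    trains on all but one and scores the held-out inner fold. Performances
    are pooled over all (outer, inner) splits into a single subject-level
    mean per grid value; the maximizing λ wins, ties to the smaller λ.
    """
    if len(folds) < 3:
        raise ValueError("need at least 3 folds")
    grid = tuple(sorted(grid))
    # per-fold sufficient statistics so each inner fit is a small solve
    grams = [X.T @ X for X, _ in folds]
    xys = [X.T @ y for X, y in folds]
    xsums = [X.sum(axis=0) for X, _ in folds]
    ysums = [float(y.sum()) for _, y in folds]
    ns = [len(y) for _, y in folds]
    k = len(folds)
    total_gram = sum(grams)
    total_xy = sum(xys)
    total_xsum = sum(xsums)
    scores = {lam: [] for lam in grid}
    for outer in range(k):
        for inner in range(k):
            if inner == outer:
                continue
            gram = total_gram - grams[outer] - grams[inner]
            n = sum(ns) - ns[outer] - ns[inner]
            mu = (sum(ysums) - ysums[outer] - ysums[inner]) / n
            b = (total_xy - xys[outer] - xys[inner]) - mu * (
                total_xsum - xsums[outer] - xsums[inner]
            )
            # one eigendecomposition serves the whole penalty grid
            evals, evecs = np.linalg.eigh(gram)
            bt = evecs.T @ b
            X_in, y_in = folds[inner]
            yc = y_in - y_in.mean()
            ynorm = float(np.sqrt(yc @ yc))
            for lam in grid:
                denom = evals + lam
                if np.any(denom <= 0):
                    w = _solve_gram(gram, b, lam)
                else:
                    w = evecs @ (bt / denom)
                pred = X_in @ w
                pc = pred - pred.mean()
                norm = float(np.sqrt(pc @ pc)) * ynorm
                scores[lam].append(0.0 if norm == 0 else float(pc @ yc) / norm)
    means = {lam: float(np.mean(v)) for lam, v in scores.items()}
    best = max(means.values())
    for lam in grid:  # ascending: smaller λ wins ties (within numerical noise)
        if means[lam] >= best - 1e-9:
            return lam
    raise AssertionError("unreachable")


def block_pair_folds(ts: RoiTimeseries) -> list[tuple[np.ndarray, np.ndarray]]:
    """Leave-one-block-pair-out folds over non-fixation scans.

    Each fold holds out one semantic+phonological block pair (consecutive
    blocks 2k, 2k+1). Returns (train_indices, test_indices) per fold as
    row indices into the timeseries. Odd block counts are rejected.
    """
    blocks = ts.block_indices
    task_scans = np.flatnonzero(blocks >= 0)
    n_blocks = blocks.max() + 1
    if n_blocks % 2 != 0:
        raise ValueError(f"{n_blocks} blocks cannot form complete pairs")
    pair = blocks[task_scans] // 2
    folds = []
    for p in range(n_blocks // 2):
        test = task_scans[pair == p]
        train = task_scans[pair != p]
        folds.append((train, test))
    return folds


def task_specificity(
    study_ts: RoiTimeseries,
    targets: np.ndarray,
    set_size: int,
    penalty: float,
    nested_selection: bool = True,
) -> float:
    """Leave-one-pair-out cross-validated encoding-task decoding accuracy.

    With ``nested_selection`` (default), voxels are re-ranked by ANOVA F on
    each fold's training scans, so feature selection never sees the held-out
    pair. The value is the mean Pearson performance over the folds.
    """
    folds = block_pair_folds(study_ts)
    codes = study_ts.task_codes
    perfs = []
    if not nested_selection:
        f_all = anova_f_per_voxel(study_ts.data, codes)
        fs_all = select_top(f_all, set_size, study_ts.roi_name)
    for train, test in folds:
        if nested_selection:
            f = anova_f_per_voxel(study_ts.data[train], codes[train])
            fs = select_top(f, set_size, study_ts.roi_name)
        else:
            fs = fs_all
        cols = fs.voxel_indices
        dec = fit_ridge(study_ts.data[np.ix_(train, cols)], targets[train], penalty)
        pred = predict(dec, study_ts.data[np.ix_(test, cols)])
        perfs.append(performance_corr(pred, targets[test]))
    return float(np.mean(perfs))


def memory_specificity_ridge(
    study_ts: RoiTimeseries,
    test_ts_pair: tuple[RoiTimeseries, RoiTimeseries | None],
    study_targets: np.ndarray,
    test_targets_pair: tuple[np.ndarray, np.ndarray | None],
    set_size: int,
    penalty: float,
) -> float:
    """Cross-phase reinstatement accuracy.

    One decoder is trained on all encoding scans (features selected on all
    encoding data); its predictions are scored against each retrieval
    session's convolved targets and the two session performances averaged.
    A missing second session yields the single-session value with a warning.
    """
    codes = study_ts.task_codes
    f = anova_f_per_voxel(study_ts.data, codes)
    fs = select_top(f, set_size, study_ts.roi_name)
    cols = fs.voxel_indices
    train = np.flatnonzero(codes != 0)
    dec = fit_ridge(study_ts.data[np.ix_(train, cols)], study_targets[train], penalty)
    perfs = []
    for ts, tgt in zip(test_ts_pair, test_targets_pair):
        if ts is None:
            continue
        keep = np.flatnonzero(~ts.fixation_mask)
        pred = predict(dec, ts.data[np.ix_(keep, cols)])
        perfs.append(performance_corr(pred, tgt[keep]))
    if not perfs:
        raise ValueError("no retrieval sessions provided")
    if len(perfs) == 1:
        warnings.warn(
            "single retrieval session: memory specificity not averaged",
            stacklevel=2,
        )
    return float(np.mean(perfs))
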