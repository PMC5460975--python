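"""Per-run conditioning of ROI timeseries.

The chain mirrors standard post-normalization MVPA preparation: outlier-scan
replacement, linear detrend plus discrete-cosine high-pass at 1/180 Hz, and
per-voxel scaling to the range (-1, 1). Each step operates on a single run;
runs are never concatenated before conditioning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .design import ScanAnnotation

__all__ = [
    "RoiTimeseries",
    "PreprocessConfig",
    "replace_outlier_scans",
    "detrend_highpass",
    "scale_unit_range",
    "preprocess_timeseries",
]


@dataclass
class RoiTimeseries:
    """scans x voxels matrix for one subject/session/phase/ROI.

    Rows align 1:1 with ``annotations``.
    """

    data: np.ndarray
    annotations: list[ScanAnnotation]
    roi_name: str = "roi"
    subject_id: str = "sub"
    drug: str = "placebo"
    phase: str = "study"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D scans x voxels matrix")
        if len(self.annotations) != self.data.shape[0]:
            raise ValueError("annotations must align 1:1 with scan rows")

    @property
    def n_scans(self) -> int:
        return self.data.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.data.shape[1]

    @property
    def fixation_mask(self) -> np.ndarray:
        return np.array([a.is_fixation for a in self.annotations], dtype=bool)

    @property
    def task_codes(self) -> np.ndarray:
        """+1 (semantic) / -1 (phonological) / 0 (fixation) per scan."""
        return np.array(
            [0 if a.is_fixation else a.task.code for a in self.annotations],
            dtype=float,
        )

    @property
    def block_indices(self) -> np.ndarray:
        """Block index per scan, -1 at fixation."""
        return np.array(
            [-1 if a.block_index is None else a.block_index for a in self.annotations],
            dtype=int,
        )

    def with_data(self, data: np.ndarray) -> "RoiTimeseries":
        return replace(self, data=np.asarray(data, dtype=float))


@dataclass(frozen=True)
class PreprocessConfig:
    outlier_z: float = 5.0
    hp_cutoff_hz: float = 1.0 / 180.0
    scale_mode: str = "per_voxel"  # or "global"


def replace_outlier_scans(
    ts: RoiTimeseries, z_thresh: float = 5.0
) -> tuple[RoiTimeseries, list[int]]:
    """Replace spike scans with the mean of their two neighboring scans.

    A scan is an outlier when its mean absolute voxel value exceeds
    ``z_thresh`` standard deviations of that statistic's per-run
    distribution. At run ends the single existing neighbor is used.
    Returns the repaired timeseries and the list of replaced scan indices.
    """
    if ts.n_scans < 3:
        raise ValueError("need at least 3 scans for neighbor repair")
    stat = np.mean(np.abs(ts.data), axis=1)
    sd = stat.std(ddof=1)
    if sd == 0:
        return ts.with_data(ts.data.copy()), []
    z = (stat - stat.mean()) / sd
    outliers = np.flatnonzero(np.abs(z) > z_thresh)
    data = ts.data.copy()
    n = ts.n_scans
    for k in outliers:
        if k == 0:
            data[k] = ts.data[1]
        elif k == n - 1:
            data[k] = ts.data[n - 2]
        else:
            data[k] = 0.5 * (ts.data[k - 1] + ts.data[k + 1])
    return ts.with_data(data), list(map(int, outliers))


def _dct_basis(n_scans: int, tr_s: float, cutoff_hz: float) -> np.ndarray:
    """Intercept + linear trend + DCT-II columns with frequency < cutoff_hz.

    DCT-II basis function k has frequency k / (2 * N * TR) Hz, the standard
    high-pass parameterization.
    """
    k_max = int(np.floor(2.0 * n_scans * tr_s * cutoff_hz))
    t = np.arange(n_scans)
    cols = [np.ones(n_scans), t - t.mean()]
    for k in range(1, k_max + 1):
        cols.append(np.cos(np.pi * k * (2 * t + 1) / (2.0 * n_scans)))
    return np.column_stack(cols)


def detrend_highpass(
    ts: RoiTimeseries, cutoff_hz: float = 1.0 / 180.0, tr_s: float | None = None
) -> RoiTimeseries:
    """Remove linear trends and frequencies below ``cutoff_hz`` per voxel.

    Implemented as residualization against an intercept, a linear term, and
    a discrete-cosine basis spanning all frequencies below the cutoff.
    Output columns have zero mean.
    """
    if tr_s is None:
        onsets = [a.onset_s for a in ts.annotations[:2]]
        tr_s = onsets[1] - onsets[0] if len(onsets) == 2 else 1.0
    basis = _dct_basis(ts.n_scans, tr_s, cutoff_hz)
    if basis.shape[1] >= ts.n_scans:
        raise ValueError("high-pass cutoff too high: basis spans the data")
    coef, *_ = np.linalg.lstsq(basis, ts.data, rcond=None)
    return ts.with_data(ts.data - basis @ coef)


def scale_unit_range(ts: RoiTimeseries, mode: str = "per_voxel") -> RoiTimeseries:
    """Affinely map each voxel's run to the range [-1, 1].

    ``mode="per_voxel"`` rescales each column independently (accommodating
    varying ranges of voxel activity); ``mode="global"`` uses a single
    min/max over the whole matrix. Constant voxels are set to 0 with a
    warning.
    """
    x = ts.data
    if mode == "per_voxel":
        lo = x.min(axis=0)
        hi = x.max(axis=0)
    elif mode == "global":
        lo = np.full(x.shape[1], x.min())
        hi = np.full(x.shape[1], x.max())
    else:
        raise ValueError(f"unknown scale mode {mode!r}")
    rng = hi - lo
    constant = rng == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant voxel(s) set to 0 during scaling",
            stacklevel=2,
        )
    safe = np.where(constant, 1.0, rng)
    out = 2.0 * (x - lo) / safe - 1.0
    out[:, constant] = 0.0
    return ts.with_data(out)


def preprocess_timeseries(
    ts: RoiTimeseries, config: PreprocessConfig = PreprocessConfig()
) -> tuple[RoiTimeseries, list[int]]:
    """Full per-run chain: outlier repair -> detrend/high-pass -> scaling."""
    repaired, log = replace_outlier_scans(ts, config.outlier_z)
    detrended = detrend_highpass(repaired, config.hp_cutoff_hz)
    scaled = scale_unit_range(detrended, config.scale_mode)
    return scaled, log
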