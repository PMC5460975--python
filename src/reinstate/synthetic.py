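"""Synthetic ROI timeseries cohorts with known ground truth.

Each simulated subject carries two orthogonal task-specific spatial patterns
over a subset of voxels. Encoding-phase signal is the task's pattern scaled
by an HRF-convolved block boxcar; retrieval-phase signal is the same pattern
scaled additionally by a reinstatement strength ρ in [0, 1], so ρ = 0 means
no cross-phase pattern carry-over and ρ = 1 full reinstatement. Noise is
per-voxel AR(1) Gaussian plus a slow sinusoidal drift and occasional
amplitude-inflated outlier scans.

Cohorts cross two age groups with three within-subject drug sessions
(sulpiride, placebo, bromocriptine; ordinal codes -1, 0, +1). The default
effect configuration plants the qualitative structure under study: reduced
reinstatement in the old group, an age-invariant encoding-amplitude boost
under both active drugs, and an old-group drug x performance interaction in
which bromocriptine raises ρ for poorer performers and lowers it for better
performers (sulpiride the reverse). Recognition behavior is linked to ρ
through the hit rate, so baseline Pr correlates with reinstatement strength.
"""

from __future__ import annotations

import functools
import gzip
import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .behavior import RecognitionCounts
from .design import (
    ExperimentDesign,
    TaskLabel,
    annotate_scans,
    hrf_kernel,
)
from .preprocess import RoiTimeseries

__all__ = [
    "GenerativeParams",
    "SubjectSpec",
    "EffectConfig",
    "CohortDataset",
    "DRUG_CODE",
    "DRUGS",
    "make_task_patterns",
    "simulate_subject",
    "simulate_cohort",
    "simulate_behavior",
]

DRUG_CODE = {"sulpiride": -1, "placebo": 0, "bromocriptine": 1}
DRUGS = ("sulpiride", "placebo", "bromocriptine")


@dataclass(frozen=True)
class GenerativeParams:
    """Generative settings for one subject-session's ROI timeseries."""

    n_voxels: int = 120
    n_signal_voxels: int = 24
    encode_amp: float = 1.0
    reinstatement: float = 0.6
    noise_sd: float = 1.0
    ar1: float = 0.3
    drift_amp: float = 1.0
    drift_period_s: float = 240.0
    outlier_rate: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_signal_voxels > self.n_voxels:
            raise ValueError("n_signal_voxels must be <= n_voxels")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not 0 <= self.ar1 < 1:
            raise ValueError("ar1 must lie in [0, 1)")


@dataclass(frozen=True)
class SubjectSpec:
    subject_id: str
    group: str  # young | old
    drug: str  # sulpiride | placebo | bromocriptine
    baseline_pr: float
    params: GenerativeParams

    def __post_init__(self) -> None:
        if self.drug not in DRUG_CODE:
            raise ValueError(f"unknown drug {self.drug!r}")

    @property
    def drug_code(self) -> int:
        return DRUG_CODE[self.drug]


@dataclass(frozen=True)
class EffectConfig:
    """Cohort-level effect structure.

    rho_young/rho_old: group means of reinstatement strength; delta scales
    the old-group drug x Pr interaction (bromocriptine lowers ρ in better
    performers for delta > 0); drug_amp_boost multiplies encoding amplitude
    under both active drugs in both groups; pr_link couples baseline Pr to
    reinstatement strength.
    """

    rho_young: float = 0.6
    rho_old: float = 0.3
    rho_sd: float = 0.15
    delta: float = 1.2
    encode_amp: float = 1.0
    drug_amp_boost: float = 1.4
    pr_mean: float = 0.47
    pr_link: float = 0.3
    pr_jitter_sd: float = 0.08
    p_fa: float = 0.2
    behavior_slope: float = 0.25


@dataclass
class CohortDataset:
    """Emitted cohort: per-(subject, drug) phase timeseries plus ground truth."""

    design: ExperimentDesign
    sessions: dict  # (subject_id, drug) -> {phase: RoiTimeseries}
    truth: pd.DataFrame
    behavior: pd.DataFrame


def make_task_patterns(
    n_voxels: int, n_signal_voxels: int, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Two unit-norm, exactly orthogonal spatial patterns on a voxel subset.

    Both patterns share the same randomly chosen support of
    ``n_signal_voxels`` voxels; Gram-Schmidt enforces orthogonality.
    """
    if n_signal_voxels < 2:
        raise ValueError("need at least 2 signal voxels to orthogonalize")
    if n_signal_voxels > n_voxels:
        raise ValueError("n_signal_voxels must be <= n_voxels")
    rng = np.random.default_rng(seed)
    support = rng.choice(n_voxels, size=n_signal_voxels, replace=False)
    v1 = rng.standard_normal(n_signal_voxels)
    v2 = rng.standard_normal(n_signal_voxels)
    u1 = v1 / np.linalg.norm(v1)
    v2 = v2 - (u1 @ v2) * u1
    u2 = v2 / np.linalg.norm(v2)
    p1 = np.zeros(n_voxels)
    p2 = np.zeros(n_voxels)
    p1[support] = u1
    p2[support] = u2
    return p1, p2


@functools.lru_cache(maxsize=32)
def _phase_structure(design: ExperimentDesign, phase: str):
    """Cached annotations and HRF-convolved per-task indicator regressors."""
    ann = annotate_scans(design, phase)
    sem = np.array(
        [0.0 if a.is_fixation else float(a.task is TaskLabel.SEMANTIC) for a in ann]
    )
    phon = np.array(
        [0.0 if a.is_fixation else float(a.task is TaskLabel.PHONOLOGICAL) for a in ann]
    )
    kernel = hrf_kernel(design.tr_s)
    conv_sem = np.convolve(sem, kernel)[: sem.size]
    conv_phon = np.convolve(phon, kernel)[: phon.size]
    return ann, conv_sem, conv_phon


def _noise(
    rng: np.random.Generator, n_scans: int, params: GenerativeParams, tr_s: float
) -> np.ndarray:
    """AR(1) noise (marginal SD = noise_sd) + slow sinusoidal drift + outliers."""
    innov_sd = params.noise_sd * np.sqrt(1.0 - params.ar1**2)
    white = rng.standard_normal((n_scans, params.n_voxels)) * innov_sd
    noise = lfilter([1.0], [1.0, -params.ar1], white, axis=0)
    t = np.arange(n_scans) * tr_s
    phases = rng.uniform(0, 2 * np.pi, params.n_voxels)
    noise += params.drift_amp * np.sin(
        2 * np.pi * t[:, None] / params.drift_period_s + phases[None, :]
    )
    if params.outlier_rate > 0:
        spikes = np.flatnonzero(rng.random(n_scans) < params.outlier_rate)
        noise[spikes] += rng.standard_normal(
            (spikes.size, params.n_voxels)
        ) * (10.0 * params.noise_sd)
    return noise


def simulate_subject(
    design: ExperimentDesign, spec: SubjectSpec
) -> tuple[dict[str, RoiTimeseries], dict]:
    """ROI timeseries for all three phases of one subject-session.

    Encoding signal = encode_amp x task pattern x HRF-convolved block
    indicator; retrieval signal is additionally scaled by the reinstatement
    strength ρ. Returns the per-phase timeseries and the subject's truth row.
    """
    p = spec.params
    rng = np.random.default_rng(p.seed)
    pat_sem, pat_phon = make_task_patterns(
        p.n_voxels, p.n_signal_voxels, int(rng.integers(2**31))
    )
    out: dict[str, RoiTimeseries] = {}
    for phase in ("study", "test1", "test2"):
        ann, conv_sem, conv_phon = _phase_structure(design, phase)
        gain = p.encode_amp if phase == "study" else p.reinstatement * p.encode_amp
        signal = gain * (np.outer(conv_sem, pat_sem) + np.outer(conv_phon, pat_phon))
        data = signal + _noise(rng, len(ann), p, design.tr_s)
        out[phase] = RoiTimeseries(
            data=data,
            annotations=list(ann),
            roi_name="synthROI",
            subject_id=spec.subject_id,
            drug=spec.drug,
            phase=phase,
        )
    truth = {
        "subject_id": spec.subject_id,
        "group": spec.group,
        "drug": spec.drug,
        "drug_code": spec.drug_code,
        "rho": p.reinstatement,
        "encode_amp": p.encode_amp,
        "baseline_pr": spec.baseline_pr,
        "seed": p.seed,
    }
    return out, truth


def simulate_behavior(
    spec: SubjectSpec,
    n_old_items: int = 120,
    n_new_items: int = 60,
    behavior_slope: float = 0.25,
    p_fa: float = 0.2,
    base: float | None = None,
) -> RecognitionCounts:
    """Binomial recognition counts linked to reinstatement strength.

    P_hit = clamp(base + behavior_slope * ρ); P_fa is fixed. When ``base``
    is omitted it is placed so that the expected Pr equals the subject's
    baseline Pr at their generative ρ.
    """
    if n_old_items <= 0 or n_new_items <= 0:
        raise ValueError("item counts must be positive")
    rho = spec.params.reinstatement
    if base is None:
        base = p_fa + spec.baseline_pr - behavior_slope * rho
    p_hit = float(np.clip(base + behavior_slope * rho, 0.0, 1.0))
    rng = np.random.default_rng(spec.params.seed + 7)
    hits = int(rng.binomial(n_old_items, p_hit))
    fas = int(rng.binomial(n_new_items, p_fa))
    return RecognitionCounts(n_old_items, n_new_items, hits, fas)


def simulate_cohort(
    n_young: int,
    n_old: int,
    effect_config: EffectConfig = EffectConfig(),
    master_seed: int = 0,
    design: ExperimentDesign | None = None,
    base_params: GenerativeParams = GenerativeParams(),
) -> CohortDataset:
    """Full two-group, three-drug-session cohort with ground truth.

    Per subject, a baseline reinstatement strength ρ is drawn around the
    group mean and baseline Pr around the cohort mean with a positive link
    to ρ. Per session, old-group ρ is perturbed by
    delta * drug_code * (group mean Pr - baseline Pr), planting the
    drug x Pr interaction, and encoding amplitude is boosted equally under
    both active drugs. All draws descend from ``master_seed``.
    """
    if n_young < 1 or n_old < 1:
        raise ValueError("cohort sizes must be >= 1")
    if design is None:
        design = _default_design_cached()
    cfg = effect_config
    root = np.random.SeedSequence(master_seed)
    cohort_rng = np.random.default_rng(root.spawn(1)[0])
    groups = ["young"] * n_young + ["old"] * n_old
    rho_means = {"young": cfg.rho_young, "old": cfg.rho_old}
    rho_base = np.clip(
        [
            cohort_rng.normal(rho_means[g], cfg.rho_sd)
            for g in groups
        ],
        0.0,
        1.0,
    )
    pr = np.clip(
        [
            cfg.pr_mean
            + cfg.pr_link * (rho_base[i] - rho_means[groups[i]])
            + cohort_rng.normal(0, cfg.pr_jitter_sd)
            for i in range(len(groups))
        ],
        0.02,
        0.98,
    )
    group_pr_mean = {
        g: float(np.mean([pr[i] for i in range(len(groups)) if groups[i] == g]))
        for g in ("young", "old")
    }

    sessions = {}
    truth_rows = []
    behavior_rows = []
    session_seeds = iter(root.spawn(len(groups) * len(DRUGS) + 1)[1:])
    for i, group in enumerate(groups):
        subject_id = f"{group[0]}{i:03d}"
        for drug in DRUGS:
            code = DRUG_CODE[drug]
            rho = rho_base[i]
            if group == "old":
                rho += cfg.delta * code * (group_pr_mean[group] - pr[i])
            rho = float(np.clip(rho, 0.0, 1.0))
            amp = cfg.encode_amp * (cfg.drug_amp_boost if code != 0 else 1.0)
            seed = int(
                np.random.default_rng(next(session_seeds)).integers(2**31)
            )
            spec = SubjectSpec(
                subject_id=subject_id,
                group=group,
                drug=drug,
                baseline_pr=float(pr[i]),
                params=replace(
                    base_params, encode_amp=amp, reinstatement=rho, seed=seed
                ),
            )
            phases, truth = simulate_subject(design, spec)
            sessions[(subject_id, drug)] = phases
            truth["rho_base"] = float(rho_base[i])
            truth_rows.append(truth)
            counts = simulate_behavior(
                spec,
                behavior_slope=cfg.behavior_slope,
                p_fa=cfg.p_fa,
            )
            behavior_rows.append(
                {
                    "subject": subject_id,
                    "group": group,
                    "drug": drug,
                    "n_old": counts.n_old,
                    "n_new": counts.n_new,
                    "hits": counts.hits,
                    "fa": counts.false_alarms,
                }
            )
    return CohortDataset(
        design=design,
        sessions=sessions,
        truth=pd.DataFrame(truth_rows),
        behavior=pd.DataFrame(behavior_rows),
    )


@functools.lru_cache(maxsize=1)
def _default_design_cached() -> ExperimentDesign:
    from .design import default_design

    return default_design()


# -- serialization ---------------------------------------------------------


def write_timeseries(ts: RoiTimeseries, path) -> None:
    """Gzipped TSV matrix (scans x voxels) plus a JSON annotation sidecar."""
    path = str(path)
    with gzip.open(path, "wt") as fh:
        pd.DataFrame(ts.data).to_csv(fh, sep="\t", index=False, header=False)
    sidecar = {
        "roi_name": ts.roi_name,
        "subject_id": ts.subject_id,
        "drug": ts.drug,
        "phase": ts.phase,
        "annotations": [
            {
                "scan_index": a.scan_index,
                "onset_s": a.onset_s,
                "block_index": a.block_index,
                "task": None if a.task is None else a.task.value,
                "within_block_rank": a.within_block_rank,
                "is_fixation": a.is_fixation,
            }
            for a in ts.annotations
        ],
    }
    with open(path + ".json", "w") as fh:
        json.dump(sidecar, fh)


def read_timeseries(path) -> RoiTimeseries:
    from .design import ScanAnnotation

    path = str(path)
    with gzip.open(path, "rt") as fh:
        data = pd.read_csv(fh, sep="\t", header=None).to_numpy(dtype=float)
    with open(path + ".json") as fh:
        sidecar = json.load(fh)
    ann = [
        ScanAnnotation(
            scan_index=a["scan_index"],
            onset_s=a["onset_s"],
            block_index=a["block_index"],
            task=None if a["task"] is None else TaskLabel(a["task"]),
            within_block_rank=a["within_block_rank"],
            is_fixation=a["is_fixation"],
        )
        for a in sidecar["annotations"]
    ]
    return RoiTimeseries(
        data=data,
        annotations=ann,
        roi_name=sidecar["roi_name"],
        subject_id=sidecar["subject_id"],
        drug=sidecar["drug"],
        phase=sidecar["phase"],
    )


def export_nifti(ts: RoiTimeseries, path) -> None:
    """Embed the ROI voxels in a dummy 3-D grid and save as 4-D NIfTI."""
    import nibabel as nib

    n_vox = ts.n_voxels
    side = int(np.ceil(n_vox ** (1 / 3)))
    vol = np.zeros((side, side, side, ts.n_scans))
    flat = vol.reshape(-1, ts.n_scans)
    flat[:n_vox] = ts.data.T
    img = nib.Nifti1Image(vol, affine=np.eye(4))
    img.header.set_zooms((1.0, 1.0, 1.0, 1.2))
    nib.save(img, str(path))
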