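"""Cohort orchestration and group-level statistics.

``run_pipeline`` turns a cohort of ROI timeseries into a tidy table of
specificity records (task_ridge, memory_ridge, memory_corr per subject x
drug), selecting the ridge penalty per subject on Placebo encoding data and
reusing it across sessions. Group tests follow the repeated-measures
playbook for a 2 (age group) x 3 (drug, within) design with a mean-centered
behavioral covariate: ANCOVA by effect-coded OLS with Type III-style nested
F tests, polynomial drug-trend contrasts (linear: B - S; quadratic:
S - 2P + B), a Greenhouse-Geisser-corrected omnibus drug effect, and the
drug x covariate interaction assessed by regressing per-subject linear drug
effects on group, centered Pr, and their product.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .behavior import center_covariate
from .design import ExperimentDesign, convolved_target
from .preprocess import PreprocessConfig, RoiTimeseries, preprocess_timeseries
from .ridge import (
    DEFAULT_PENALTY_GRID,
    block_pair_folds,
    memory_specificity_ridge,
    nested_cv_penalty,
    task_specificity,
)
from .features import anova_f_per_voxel, select_top
from .similarity import block_mean_patterns, memory_specificity_corr
from .synthetic import DRUG_CODE, CohortDataset

__all__ = [
    "PipelineConfig",
    "TestResult",
    "analyze_subject_session",
    "select_subject_penalty",
    "run_pipeline",
    "group_ancova",
    "drug_trend",
    "drug_by_covariate_interaction",
    "gg_epsilon",
    "qualitative_findings",
]

GROUP_CODE = {"young": 1, "old": -1}


@dataclass(frozen=True)
class PipelineConfig:
    set_size: int = 50
    penalty_grid: tuple[float, ...] = DEFAULT_PENALTY_GRID
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    nested_selection: bool = True
    discard_first: int = 7
    fisher_z: bool = False


@dataclass(frozen=True)
class TestResult:
    effect: str
    F: float
    df: tuple[float, float]
    p: float
    epsilon: float | None = None


# -- subject-level orchestration ------------------------------------------


def _phase_targets(design: ExperimentDesign, phase: str) -> np.ndarray:
    return convolved_target(design, phase)


def select_subject_penalty(
    study_ts: RoiTimeseries,
    targets: np.ndarray,
    set_size: int,
    grid: tuple[float, ...] = DEFAULT_PENALTY_GRID,
) -> float:
    """Nested-CV penalty choice on one (Placebo) encoding run.

    Features for the penalty search are selected once on all encoding data;
    the chosen λ is a subject-level hyperparameter reused downstream.
    """
    codes = study_ts.task_codes
    fs = select_top(anova_f_per_voxel(study_ts.data, codes), set_size,
                    study_ts.roi_name)
    cols = fs.voxel_indices
    folds = [
        (study_ts.data[np.ix_(te, cols)], targets[te])
        for _, te in block_pair_folds(study_ts)
    ]
    return nested_cv_penalty(folds, grid)


def analyze_subject_session(
    phases: dict[str, RoiTimeseries],
    design: ExperimentDesign,
    penalty: float,
    config: PipelineConfig = PipelineConfig(),
    preprocessed: bool = False,
) -> dict[str, float]:
    """All three specificity metrics for one subject-session.

    ``phases`` maps {study, test1, test2} to raw (or, with
    ``preprocessed=True``, already conditioned) timeseries.
    """
    ts = dict(phases)
    if not preprocessed:
        ts = {k: preprocess_timeseries(v, config.preprocess)[0] for k, v in ts.items()}
    study = ts["study"]
    tgt_study = _phase_targets(design, "study")
    tgt1 = _phase_targets(design, "test1")
    tgt2 = _phase_targets(design, "test2") if "test2" in ts else None
    test_pair = (ts["test1"], ts.get("test2"))
    task = task_specificity(
        study, tgt_study, config.set_size, penalty, config.nested_selection
    )
    mem_ridge = memory_specificity_ridge(
        study, test_pair, tgt_study, (tgt1, tgt2), config.set_size, penalty
    )
    fs = select_top(
        anova_f_per_voxel(study.data, study.task_codes),
        config.set_size,
        study.roi_name,
    )
    patterns = block_mean_patterns(study, test_pair, fs, config.discard_first)
    mem_corr = memory_specificity_corr(patterns, config.fisher_z)
    return {"task_ridge": task, "memory_ridge": mem_ridge, "memory_corr": mem_corr}


def run_pipeline(
    dataset: CohortDataset, config: PipelineConfig = PipelineConfig()
) -> pd.DataFrame:
    """Tidy long table of specificity records for a whole cohort.

    Per subject: preprocess every session, choose λ by nested CV on the
    Placebo encoding run, then compute task_ridge, memory_ridge and
    memory_corr for each drug session with that λ. The Placebo-session Pr
    (from the cohort's behavioral counts) is attached as the covariate,
    mean-centered within age group.
    """
    design = dataset.design
    tgt_study = _phase_targets(design, "study")
    subjects: dict[str, list[str]] = {}
    for (sub, drug) in dataset.sessions:
        subjects.setdefault(sub, []).append(drug)

    beh = dataset.behavior
    beh = beh.assign(pr=beh["hits"] / beh["n_old"] - beh["fa"] / beh["n_new"])
    placebo_pr = beh[beh["drug"] == "placebo"].set_index("subject")["pr"]

    rows = []
    for sub, drugs in subjects.items():
        pre = {
            drug: {
                phase: preprocess_timeseries(ts, config.preprocess)[0]
                for phase, ts in dataset.sessions[(sub, drug)].items()
            }
            for drug in drugs
        }
        if "placebo" in pre:
            lam_session = "placebo"
        else:
            lam_session = drugs[0]
            warnings.warn(
                f"subject {sub} has no placebo session; "
                f"penalty chosen on {lam_session}",
                stacklevel=2,
            )
        lam = select_subject_penalty(
            pre[lam_session]["study"], tgt_study, config.set_size, config.penalty_grid
        )
        group = dataset.truth.loc[
            dataset.truth["subject_id"] == sub, "group"
        ].iloc[0]
        for drug in drugs:
            metrics = analyze_subject_session(
                pre[drug], design, lam, config, preprocessed=True
            )
            for metric, value in metrics.items():
                rows.append(
                    {
                        "subject": sub,
                        "group": group,
                        "drug": drug,
                        "drug_code": DRUG_CODE[drug],
                        "roi": dataset.sessions[(sub, drug)]["study"].roi_name,
                        "metric": metric,
                        "value": value,
                        "penalty": lam,
                        "pr": placebo_pr.get(sub, np.nan),
                    }
                )
    table = pd.DataFrame(rows)
    subj = table.drop_duplicates("subject")[["subject", "group", "pr"]]
    centered = center_covariate(subj.set_index("subject")["pr"],
                                subj.set_index("subject")["group"])
    table["pr_centered"] = table["subject"].map(centered)
    return table


# -- group statistics ------------------------------------------------------


def _ols_type3(y: np.ndarray, X: np.ndarray, names: list[str]) -> dict[str, TestResult]:
    """Type III-style nested-model F tests: drop one column at a time."""
    n, k = X.shape
    if np.linalg.matrix_rank(X) < k:
        raise ValueError("rank-deficient design matrix")
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    rss_full = float(np.sum((y - X @ beta) ** 2))
    df_den = n - k
    out = {}
    for j, name in enumerate(names):
        if name == "intercept":
            continue
        Xr = np.delete(X, j, axis=1)
        br, _, _, _ = np.linalg.lstsq(Xr, y, rcond=None)
        rss_r = float(np.sum((y - Xr @ br) ** 2))
        if rss_full == 0:
            f = 0.0 if rss_r == rss_full else np.inf
        else:
            f = (rss_r - rss_full) / (rss_full / df_den)
        f = max(f, 0.0)
        p = float(sps.f.sf(f, 1, df_den)) if np.isfinite(f) else 0.0
        out[name] = TestResult(name, float(f), (1.0, float(df_den)), p)
    return out


def group_ancova(slice_table: pd.DataFrame) -> dict[str, TestResult]:
    """ANCOVA on one roi/metric/drug slice: group + Pr + group x Pr.

    Group is effect-coded (young = +1, old = -1) and the covariate is the
    within-group mean-centered Pr, so the three terms are orthogonalizable
    and the drop-one-term F tests are Type III-equivalent.
    """
    df = slice_table.dropna(subset=["value", "pr_centered"])
    for g, n in df["group"].value_counts().items():
        if n < 3:
            raise ValueError(f"group {g!r} has fewer than 3 subjects")
    y = df["value"].to_numpy(dtype=float)
    g = df["group"].map(GROUP_CODE).to_numpy(dtype=float)
    pr = df["pr_centered"].to_numpy(dtype=float)
    X = np.column_stack([np.ones_like(y), g, pr, g * pr])
    return _ols_type3(y, X, ["intercept", "group", "pr", "group_x_pr"])


def gg_epsilon(cov: np.ndarray) -> float:
    """Greenhouse-Geisser sphericity correction from a k-level covariance.

    Box's epsilon on the orthonormal-contrast-transformed covariance
    M = C S C': epsilon = tr(M)^2 / ((k-1) tr(M M)). Equals 1 under
    compound symmetry, bounded below by 1/(k-1).
    """
    cov = np.asarray(cov, dtype=float)
    k = cov.shape[0]
    # orthonormal basis of the contrast space (orthogonal complement of 1)
    C = np.linalg.qr(
        np.eye(k) - np.ones((k, k)) / k
    )[0][:, : k - 1].T
    m = C @ cov @ C.T
    denom = (k - 1) * float(np.trace(m @ m))
    if denom == 0:
        return 1.0
    return float(np.trace(m) ** 2 / denom)


def _contrast_f(scores: np.ndarray, effect: str) -> TestResult:
    """One-sample F on per-subject contrast scores (df 1, n-1)."""
    n = scores.size
    mean = scores.mean()
    var = scores.var(ddof=1) if n > 1 else 0.0
    if var == 0:
        f = 0.0 if mean == 0 else np.inf
        p = 1.0 if mean == 0 else 0.0
    else:
        f = n * mean**2 / var
        p = float(sps.f.sf(f, 1, n - 1))
    return TestResult(effect, float(f), (1.0, float(n - 1)), p)


def drug_trend(slice_table: pd.DataFrame) -> dict[str, TestResult]:
    """Within-subject drug analysis on one roi/metric slice.

    Subjects missing any of the three sessions are dropped. Returns the
    linear (bromocriptine - sulpiride) and quadratic (S - 2P + B) contrast
    tests plus the omnibus drug effect with Greenhouse-Geisser-corrected
    degrees of freedom.
    """
    wide = slice_table.pivot_table(
        index="subject", columns="drug", values="value"
    ).dropna()
    for col in ("sulpiride", "placebo", "bromocriptine"):
        if col not in wide.columns:
            raise ValueError(f"missing drug session {col!r}")
    Y = wide[["sulpiride", "placebo", "bromocriptine"]].to_numpy(dtype=float)
    n, k = Y.shape
    lin = Y[:, 2] - Y[:, 0]
    quad = Y[:, 0] - 2 * Y[:, 1] + Y[:, 2]
    out = {
        "linear": _contrast_f(lin, "linear"),
        "quadratic": _contrast_f(quad, "quadratic"),
    }
    # omnibus via orthonormal contrasts
    C = np.linalg.qr(np.eye(k) - np.ones((k, k)) / k)[0][:, : k - 1].T
    Z = Y @ C.T
    ms_treat = n * float((Z.mean(axis=0) ** 2).sum()) / (k - 1)
    ms_err = float(((Z - Z.mean(axis=0)) ** 2).sum()) / ((n - 1) * (k - 1))
    # contrasts annihilate constant profiles only to rounding error
    tiny = (1e-10 * max(1.0, float(np.abs(Y).max()))) ** 2
    if ms_treat < tiny:
        ms_treat = 0.0
    if ms_err < tiny:
        ms_err = 0.0
    eps = gg_epsilon(np.cov(Y, rowvar=False))
    if ms_err == 0:
        f = 0.0 if ms_treat == 0 else np.inf
        p = 1.0 if ms_treat == 0 else 0.0
    else:
        f = ms_treat / ms_err
        p = float(sps.f.sf(f, eps * (k - 1), eps * (k - 1) * (n - 1)))
    out["drug"] = TestResult(
        "drug", float(f), (eps * (k - 1), eps * (k - 1) * (n - 1)), p, epsilon=eps
    )
    return out


def linear_drug_effects(slice_table: pd.DataFrame) -> pd.DataFrame:
    """Per-subject linear drug effect (bromocriptine - sulpiride) table."""
    wide = slice_table.pivot_table(
        index="subject", columns="drug", values="value"
    ).dropna()
    meta = slice_table.drop_duplicates("subject").set_index("subject")
    out = pd.DataFrame(
        {
            "linear_effect": wide["bromocriptine"] - wide["sulpiride"],
            "group": meta["group"],
            "pr_centered": meta["pr_centered"],
        }
    ).dropna()
    return out


def drug_by_covariate_interaction(
    slice_table: pd.DataFrame,
) -> dict[str, TestResult]:
    """Group x drug x Pr interaction via linear drug-effect scores.

    Each subject's linear drug effect (B - S) on the metric is regressed on
    effect-coded group, centered Pr, and their product; the group x Pr term
    is the three-way interaction of interest.
    """
    eff = linear_drug_effects(slice_table)
    y = eff["linear_effect"].to_numpy(dtype=float)
    g = eff["group"].map(GROUP_CODE).to_numpy(dtype=float)
    pr = eff["pr_centered"].to_numpy(dtype=float)
    X = np.column_stack([np.ones_like(y), g, pr, g * pr])
    return _ols_type3(y, X, ["intercept", "group", "pr", "group_x_pr"])


# -- qualitative summary ---------------------------------------------------


def qualitative_findings(table: pd.DataFrame, alpha: float = 0.05) -> dict[str, bool]:
    """Directional checks of the headline effect structure on one cohort.

    Returns flags for: reduced old-group memory specificity on Placebo
    (ridge), age-invariant Placebo task specificity (non-significant group
    difference), task-specificity increase under both active drugs, and the
    old-group negative association between the linear drug effect on memory
    specificity and baseline Pr (the drug x Pr crossover).
    """
    mem = table[(table["metric"] == "memory_ridge")]
    task = table[(table["metric"] == "task_ridge")]
    mem_pl = mem[mem["drug"] == "placebo"]
    task_pl = task[task["drug"] == "placebo"]

    young_mem = mem_pl.loc[mem_pl["group"] == "young", "value"]
    old_mem = mem_pl.loc[mem_pl["group"] == "old", "value"]
    finding_a = old_mem.mean() < young_mem.mean()

    _, p_task = sps.ttest_ind(
        task_pl.loc[task_pl["group"] == "young", "value"],
        task_pl.loc[task_pl["group"] == "old", "value"],
    )
    finding_b = p_task > alpha

    means = task.groupby("drug")["value"].mean()
    finding_c = (
        means["sulpiride"] > means["placebo"]
        and means["bromocriptine"] > means["placebo"]
    )

    old_eff = linear_drug_effects(mem[mem["group"] == "old"])
    slope = np.polyfit(
        old_eff["pr_centered"].to_numpy(), old_eff["linear_effect"].to_numpy(), 1
    )[0]
    finding_d = slope < 0

    return {
        "old_memory_specificity_reduced": bool(finding_a),
        "task_specificity_age_invariant": bool(finding_b),
        "both_drugs_increase_task_specificity": bool(finding_c),
        "old_drug_by_pr_crossover": bool(finding_d),
    }
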