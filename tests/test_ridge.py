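import numpy as np
import pytest
from scipy.optimize import minimize

from reinstate.design import annotate_scans, convolved_target
from reinstate.preprocess import RoiTimeseries
from reinstate.ridge import (
    DEFAULT_PENALTY_GRID,
    block_pair_folds,
    fit_ridge,
    memory_specificity_ridge,
    nested_cv_penalty,
    performance_corr,
    predict,
    task_specificity,
)
from reinstate.synthetic import GenerativeParams, SubjectSpec, simulate_subject


def _ridge_oracle(X, y, lam):
    """Generic numeric minimizer of the penalized loss (independent route)."""
    yc = y - y.mean()

    def loss(w):
        r = yc - X @ w
        return r @ r + lam * w @ w

    def grad(w):
        return -2 * X.T @ (yc - X @ w) + 2 * lam * w

    res = minimize(loss, np.zeros(X.shape[1]), jac=grad, method="BFGS",
                   options={"gtol": 1e-12, "maxiter": 2000})
    return res.x


@pytest.fixture()
def planted(small_design):
    """Noise-free planted task signal on the scaled design."""
    spec = SubjectSpec(
        "s", "young", "placebo", 0.5,
        GenerativeParams(n_voxels=30, n_signal_voxels=8, noise_sd=1e-9,
                         ar1=0.0, drift_amp=0.0, outlier_rate=0.0,
                         reinstatement=1.0, seed=11),
    )
    phases, _ = simulate_subject(small_design, spec)
    targets = {p: convolved_target(small_design, p) for p in phases}
    return phases, targets


class TestFitRidge:
    def test_zero_penalty_equals_ols(self, rng):
        X = rng.standard_normal((30, 5))
        y = rng.standard_normal(30)
        w = fit_ridge(X, y, 0.0).weights
        w_ols, *_ = np.linalg.lstsq(X, y - y.mean(), rcond=None)
        np.testing.assert_allclose(w, w_ols, atol=1e-8)

    def test_extreme_penalty_shrinks_to_constant(self, rng):
        X = rng.standard_normal((30, 5))
        y = rng.standard_normal(30)
        dec = fit_ridge(X, y, 1e12)
        assert np.linalg.norm(dec.weights) < 1e-6
        assert np.allclose(predict(dec, X), y.mean(), atol=1e-4)

    def test_small_integer_problem_matches_numeric_minimizer(self):
        X = np.array([[1, 2, 0], [0, 1, 1], [2, 0, 1], [1, 1, 1], [0, 2, 2]],
                     dtype=float)
        y = np.array([3.0, 1.0, 2.0, 2.0, 4.0])
        w = fit_ridge(X, y, 1.0).weights
        np.testing.assert_allclose(w, _ridge_oracle(X, y, 1.0), atol=1e-6)

    def test_rank_deficient_unpenalized_uses_pinv_flagged(self, rng):
        X = rng.standard_normal((10, 3))
        X = np.hstack([X, X[:, :1]])  # duplicated column
        dec = fit_ridge(X, rng.standard_normal(10), 0.0)
        assert dec.pinv_used
        assert np.all(np.isfinite(dec.weights))

    def test_negative_penalty_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_ridge(rng.standard_normal((5, 2)), np.zeros(5), -1.0)


class TestPredict:
    def test_fitted_values_at_zero_penalty(self, rng):
        X = rng.standard_normal((20, 4))
        y = rng.standard_normal(20)
        dec = fit_ridge(X, y, 0.0)
        fitted = X @ np.linalg.lstsq(X, y - y.mean(), rcond=None)[0] + y.mean()
        np.testing.assert_allclose(predict(dec, X), fitted, atol=1e-10)

    def test_zero_matrix_predicts_target_mean(self, rng):
        dec = fit_ridge(rng.standard_normal((10, 3)), np.arange(10.0), 1.0)
        np.testing.assert_allclose(predict(dec, np.zeros((4, 3))), 4.5)

    def test_column_mismatch_rejected(self, rng):
        dec = fit_ridge(rng.standard_normal((10, 3)), np.zeros(10), 1.0)
        with pytest.raises(ValueError):
            predict(dec, np.zeros((4, 2)))


class TestPerformanceCorr:
    def test_perfect_and_anticorrelated(self, rng):
        t = rng.standard_normal(50)
        assert performance_corr(t, t) == pytest.approx(1.0)
        assert performance_corr(-t, t) == pytest.approx(-1.0)

    def test_independent_noise_has_zero_mean(self, rng):
        # chance level of the metric is 0
        vals = [
            performance_corr(rng.standard_normal(200), rng.standard_normal(200))
            for _ in range(1000)
        ]
        vals = np.asarray(vals)
        assert abs(vals.mean()) < 2 * vals.std(ddof=1) / np.sqrt(vals.size)

    def test_constant_predictions_map_to_chance(self):
        with pytest.warns(UserWarning, match="constant"):
            assert performance_corr(np.ones(5), np.arange(5.0)) == 0.0

    def test_constant_targets_rejected(self):
        with pytest.raises(ValueError):
            performance_corr(np.arange(5.0), np.ones(5))


class TestNestedCvPenalty:
    def test_noiseless_signal_prefers_minimal_shrinkage(self, rng):
        # exactly representable signal (constant column absorbs the target
        # mean): zero penalty attains perfect correlation and the tie rule
        # keeps the smallest grid value
        w_true = rng.standard_normal(6)
        folds = []
        for _ in range(4):
            X = np.hstack([np.ones((25, 1)), rng.standard_normal((25, 5))])
            folds.append((X, X @ w_true))
        lam = nested_cv_penalty(folds)
        assert lam in (0.0, 0.01)

    def test_singleton_grid(self, rng):
        folds = [(rng.standard_normal((10, 3)), rng.standard_normal(10))
                 for _ in range(3)]
        assert nested_cv_penalty(folds, grid=(10.0,)) == 10.0

    def test_pure_noise_choice_is_deterministic(self, rng):
        folds = [(rng.standard_normal((12, 4)), rng.standard_normal(12))
                 for _ in range(4)]
        assert nested_cv_penalty(folds) == nested_cv_penalty(folds)

    def test_too_few_folds_rejected(self, rng):
        with pytest.raises(ValueError):
            nested_cv_penalty([(np.ones((3, 1)), np.ones(3))] * 2)


class TestFolds:
    def test_train_test_partitions_disjoint_and_exhaustive(self, small_design, rng):
        ann = annotate_scans(small_design, "study")
        ts = RoiTimeseries(rng.standard_normal((len(ann), 5)), ann)
        folds = block_pair_folds(ts)
        task_scans = set(np.flatnonzero(ts.block_indices >= 0))
        for train, test in folds:
            assert set(train) & set(test) == set()
            assert set(train) | set(test) == task_scans
        all_test = np.concatenate([te for _, te in folds])
        assert len(all_test) == len(set(all_test))

    def test_unpaired_blocks_rejected(self, small_design, rng):
        ann = annotate_scans(small_design, "study")
        # drop the final block's scans to leave an odd count
        last = max(a.block_index for a in ann if a.block_index is not None)
        keep = [i for i, a in enumerate(ann) if a.block_index != last]
        ts = RoiTimeseries(
            rng.standard_normal((len(keep), 5)), [ann[i] for i in keep]
        )
        with pytest.raises(ValueError):
            block_pair_folds(ts)


class TestTaskSpecificity:
    def test_noiseless_planted_patterns_decode_almost_perfectly(self, planted):
        phases, targets = planted
        value = task_specificity(phases["study"], targets["study"], 10, 0.01)
        assert value > 0.95

    def test_value_in_metric_range(self, small_design, rng):
        ann = annotate_scans(small_design, "study")
        ts = RoiTimeseries(rng.standard_normal((len(ann), 8)), ann)
        v = task_specificity(ts, convolved_target(small_design, "study"), 5, 1.0)
        assert -1.0 <= v <= 1.0

    def test_voxel_order_invariance(self, planted, rng):
        phases, targets = planted
        ts = phases["study"]
        v1 = task_specificity(ts, targets["study"], 10, 1.0)
        perm = rng.permutation(ts.n_voxels)
        v2 = task_specificity(ts.with_data(ts.data[:, perm]), targets["study"],
                              10, 1.0)
        assert v1 == pytest.approx(v2, abs=1e-10)

    def test_shuffled_targets_destroy_signal(self, small_design):
        # permuting scan labels within the run removes temporal alignment
        rng = np.random.default_rng(7)
        spec = SubjectSpec(
            "s", "young", "placebo", 0.5,
            GenerativeParams(n_voxels=30, n_signal_voxels=8, noise_sd=1.0,
                             ar1=0.0, drift_amp=0.0, outlier_rate=0.0, seed=23),
        )
        phases, _ = simulate_subject(small_design, spec)
        tgt = np.array(convolved_target(small_design, "study"))
        vals = []
        for _ in range(60):
            shuffled = tgt.copy()
            rng.shuffle(shuffled)
            vals.append(
                task_specificity(phases["study"], shuffled, 10, 10.0)
            )
        vals = np.asarray(vals)
        assert abs(vals.mean()) < 2.5 * vals.std(ddof=1) / np.sqrt(vals.size)


class TestMemorySpecificity:
    def test_full_reinstatement_matches_task_specificity(self, planted):
        phases, targets = planted
        v_task = task_specificity(phases["study"], targets["study"], 10, 0.01)
        v_mem = memory_specificity_ridge(
            phases["study"], (phases["test1"], phases["test2"]),
            targets["study"], (targets["test1"], targets["test2"]), 10, 0.01,
        )
        assert v_mem == pytest.approx(v_task, abs=0.05)

    def test_sign_flipped_reinstatement_is_negative(self, small_design):
        spec = SubjectSpec(
            "s", "young", "placebo", 0.5,
            GenerativeParams(n_voxels=30, n_signal_voxels=8, noise_sd=0.1,
                             ar1=0.0, drift_amp=0.0, outlier_rate=0.0,
                             reinstatement=-1.0, seed=13),
        )
        phases, _ = simulate_subject(small_design, spec)
        targets = {p: convolved_target(small_design, p) for p in phases}
        v = memory_specificity_ridge(
            phases["study"], (phases["test1"], phases["test2"]),
            targets["study"], (targets["test1"], targets["test2"]), 10, 0.01,
        )
        assert v < 0

    def test_missing_session_warns_and_uses_single_session(self, planted):
        phases, targets = planted
        with pytest.warns(UserWarning, match="single retrieval"):
            v = memory_specificity_ridge(
                phases["study"], (phases["test1"], None),
                targets["study"], (targets["test1"], None), 10, 0.01,
            )
        assert v > 0.9
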