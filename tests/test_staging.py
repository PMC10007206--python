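"""Classifier evaluation, Bayes bounds, slopes, and confusion pooling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from jitterhrv.staging import (
    ClassTooSmallError,
    EvalConfig,
    aggregate_confusion,
    bayes_bounds,
    cv_error,
    ensemble_curve,
    mean_sensitivity_slope,
    sensitivity_slope,
)
from jitterhrv.synthdata import ValidationError


def blobs(rng, n=200, sep=8.0):
    X = np.vstack([rng.normal(0, 1, (n, 2)), rng.normal(sep, 1, (n, 2))])
    y = np.array(["a"] * n + ["b"] * n)
    return X, y


class TestCvError:
    def test_separable_blobs_near_zero_error(self, rng):
        X, y = blobs(rng)
        assert cv_error(X, y, EvalConfig(feature_subset=("HR_s",), seed=0)) < 2.0

    def test_permuted_labels_hit_chance(self, rng):
        X, y = blobs(rng, n=600)
        y = rng.permutation(y)
        err = cv_error(X, y, EvalConfig(feature_subset=("HR_s",), seed=0))
        assert err == pytest.approx(50.0, abs=3.0)  # 100*(1 - max prior)

    def test_deterministic_given_seed(self, rng):
        X, y = blobs(rng, sep=2.0)
        cfg = EvalConfig(feature_subset=("HR_s",), seed=7)
        assert cv_error(X, y, cfg) == cv_error(X, y, cfg)

    def test_small_class_flagged_not_dropped(self, rng):
        X = rng.normal(0, 1, (50, 2))
        y = np.array(["a"] * 45 + ["b"] * 5)
        with pytest.raises(ClassTooSmallError):
            cv_error(X, y, EvalConfig(feature_subset=("HR_s",), k_folds=10))

    def test_knn_backend(self, rng):
        X, y = blobs(rng)
        cfg = EvalConfig(classifier="knn", feature_subset=("HR_s",), seed=0)
        assert cv_error(X, y, cfg) < 2.0


class TestBayesBounds:
    def test_zero_error_gives_zero_bounds(self):
        for L in (2, 3, 5):
            assert bayes_bounds(0.0, L) == (0.0, 0.0)

    def test_two_class_chance_saturates(self):
        lo, hi = bayes_bounds(0.5, 2)
        assert lo == pytest.approx(0.5)
        assert hi == pytest.approx(0.5)

    def test_five_class_worked_value(self):
        lo, hi = bayes_bounds(0.2, 5)
        assert lo == pytest.approx(0.8 * (1 - np.sqrt(0.75)), abs=1e-12)
        assert lo == pytest.approx(0.1072, abs=5e-4)
        assert hi == 0.2

    def test_rejects_error_beyond_chance(self):
        with pytest.raises(ValidationError):
            bayes_bounds(0.9, 5)

    @given(
        st.integers(min_value=2, max_value=6),
        st.floats(min_value=0.0, max_value=1.0),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_bound_sandwich_and_monotonicity(self, L, frac):
        """lower <= upper on the whole domain, and lower grows with e_knn."""
        e = frac * (L - 1) / L
        lo, hi = bayes_bounds(e, L)
        assert 0.0 <= lo <= hi <= (L - 1) / L + 1e-12
        e2 = min(e + 0.01, (L - 1) / L)
        lo2, _ = bayes_bounds(e2, L)
        assert lo2 >= lo - 1e-12


class TestSensitivitySlope:
    def test_constant_curve_zero_slope(self):
        mae = np.linspace(0, 0.06, 10)
        assert sensitivity_slope(mae, np.full(10, 25.0)) == pytest.approx(0.0)

    def test_exact_line_recovered(self):
        mae = np.linspace(0, 0.06, 21)
        err = 10.0 + 50.0 * mae
        assert sensitivity_slope(mae, err) == pytest.approx(50.0)

    def test_matches_normal_equations_oracle(self, rng):
        mae = np.sort(rng.uniform(0, 0.06, 97))
        err = 10 + 300 * mae + rng.normal(0, 1.5, 97)
        A = np.vstack([mae, np.ones_like(mae)]).T
        beta = np.linalg.solve(A.T @ A, A.T @ err)
        assert sensitivity_slope(mae, err) == pytest.approx(beta[0], abs=1e-9)

    def test_degenerate_spread_rejected(self):
        with pytest.raises(ValidationError):
            sensitivity_slope(np.full(5, 0.01), np.arange(5.0))

    def test_too_few_points_rejected(self):
        with pytest.raises(ValidationError):
            sensitivity_slope(np.array([0.0, 0.1]), np.array([1.0, 2.0]))

    def test_mean_slope_averages_participants(self):
        mae = np.linspace(0, 0.06, 5)
        frames = []
        for pid, slope in (("a", 10.0), ("b", 30.0)):
            frames.append(
                pd.DataFrame(
                    {
                        "participant_id": pid,
                        "mae_ms": mae * 1000,
                        "error_pct": 5 + slope * mae,
                    }
                )
            )
        assert mean_sensitivity_slope(pd.concat(frames)) == pytest.approx(20.0)


class TestEnsembleCurve:
    def test_identical_curves_collapse_band(self):
        rows = []
        for pid in ("a", "b", "c"):
            for lvl, err in ((0, 10.0), (1, 20.0)):
                rows.append(
                    {"participant_id": pid, "level": lvl, "mae_ms": lvl * 10.0,
                     "error_pct": err}
                )
        curve = ensemble_curve(pd.DataFrame(rows))
        assert np.allclose(curve["sd_error_pct"], 0.0)
        assert np.allclose(curve["lo_error_pct"], curve["mean_error_pct"])

    def test_two_participant_mean(self):
        df = pd.DataFrame(
            {
                "participant_id": ["a", "b"],
                "level": [1, 1],
                "mae_ms": [10.0, 10.0],
                "error_pct": [10.0, 30.0],
            }
        )
        curve = ensemble_curve(df)
        assert curve["mean_error_pct"].iloc[0] == pytest.approx(20.0)

    def test_matches_direct_recomputation(self, rng):
        rows = []
        for pid in "abcde":
            for lvl in range(4):
                rows.append(
                    {"participant_id": pid, "level": lvl, "mae_ms": 3.0 * lvl,
                     "error_pct": rng.uniform(5, 40)}
                )
        df = pd.DataFrame(rows)
        curve = ensemble_curve(df).set_index("level")
        for lvl in range(4):
            errs = df[df["level"] == lvl]["error_pct"]
            assert curve.loc[lvl, "mean_error_pct"] == pytest.approx(errs.mean())
            assert curve.loc[lvl, "sd_error_pct"] == pytest.approx(errs.std(ddof=1))
            assert curve.loc[lvl, "hi_error_pct"] == pytest.approx(
                errs.mean() + 1.96 * errs.std(ddof=1)
            )


class TestAggregateConfusion:
    def test_participant_never_predicting_a_class_excluded(self):
        ok = np.array([[5, 1], [1, 5]])
        bad = np.array([[6, 0], [6, 0]])  # second class never predicted
        pooled, excluded = aggregate_confusion([ok, bad, ok])
        np.testing.assert_array_equal(pooled, 2 * ok)
        assert excluded == 1

    def test_all_valid_plain_sum(self):
        m = np.array([[3, 1], [2, 4]])
        pooled, excluded = aggregate_confusion([m, m])
        np.testing.assert_array_equal(pooled, 2 * m)
        assert excluded == 0

    def test_all_excluded_is_error(self):
        bad = np.array([[2, 0], [2, 0]])
        with pytest.raises(ValidationError):
            aggregate_confusion([bad, bad])
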