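"""Aggregation, OLS regression, sensitivity ranking, bone-model comparison."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fusegap import (
    aggregate_samples,
    compare_bone_models,
    fit_linear,
    sensitivity,
)


class TestAggregate:
    def test_closed_forms(self):
        s = aggregate_samples(np.array([[2.0], [2.0], [2.0]]))
        assert (s.mean[0], s.sd[0]) == (2.0, 0.0)
        s = aggregate_samples(np.array([[1.0], [3.0]]))
        assert s.mean[0] == 2.0
        assert s.sd[0] == pytest.approx(np.sqrt(2.0))

    def test_recovers_normal_moments(self):
        rng = np.random.default_rng(0)
        v = rng.normal(17000, 3400, size=(10_000, 1))
        s = aggregate_samples(v)
        assert abs(s.mean[0] - 17000) < 3 * 3400 / 100
        assert abs(s.sd[0] - 3400) < 3 * 3400 / np.sqrt(2 * 9999)

    @given(st.integers(0, 2**31 - 1))
    @settings(deadline=None, max_examples=10, derandomize=True)
    def test_permutation_invariant(self, seed):
        rng = np.random.default_rng(seed)
        v = rng.normal(size=(13, 4))
        s1 = aggregate_samples(v)
        s2 = aggregate_samples(v[rng.permutation(13)])
        assert np.allclose(s1.mean, s2.mean)
        assert np.allclose(s1.sd, s2.sd)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            aggregate_samples(np.empty((0, 3)))


class TestFitLinear:
    def test_exact_line(self):
        x = np.linspace(0, 10, 8)
        r = fit_linear(x, 2.0 * x + 1.0)
        assert r.slope == pytest.approx(2.0)
        assert r.intercept == pytest.approx(1.0)
        assert r.r_squared == pytest.approx(1.0)

    def test_constant_response_r2_zero(self):
        r = fit_linear(np.arange(5.0), np.full(5, 3.0))
        assert r.slope == pytest.approx(0.0, abs=1e-14)
        assert r.r_squared == 0.0

    def test_degenerate_x_flagged(self):
        r = fit_linear(np.full(5, 2.0), np.arange(5.0))
        assert r.degenerate

    def test_residuals_orthogonal_to_x(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=40)
        y = 1.5 * x - 0.3 + rng.normal(scale=0.2, size=40)
        r = fit_linear(x, y)
        resid = y - r.predict(x)
        assert abs(resid @ x) < 1e-9 * np.abs(y).sum()
        assert abs(resid.sum()) < 1e-9 * np.abs(y).sum()

    @given(st.integers(0, 2**31 - 1))
    @settings(deadline=None, max_examples=15, derandomize=True)
    def test_r2_invariant_under_affine_rescaling(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=25)
        y = 0.7 * x + rng.normal(scale=0.5, size=25)
        r0 = fit_linear(x, y)
        r1 = fit_linear(3.0 * x - 7.0, -2.0 * y + 11.0)
        assert r0.r_squared == pytest.approx(r1.r_squared, rel=1e-9)

    def test_confidence_interval_coverage(self):
        """95% CIs for slope and intercept cover the truth >= 93% of 500 runs."""
        from scipy import stats

        rng = np.random.default_rng(77)
        a, b, sigma, n, reps = 2.0, -1.0, 0.5, 20, 500
        x = np.linspace(0, 5, n)
        tcrit = stats.t.ppf(0.975, n - 2)
        hit_a = hit_b = 0
        for _ in range(reps):
            y = a * x + b + rng.normal(scale=sigma, size=n)
            r = fit_linear(x, y)
            hit_a += abs(r.slope - a) <= tcrit * r.stderr_slope
            hit_b += abs(r.intercept - b) <= tcrit * r.stderr_intercept
        assert hit_a / reps >= 0.93
        assert hit_b / reps >= 0.93


class TestSensitivity:
    def test_single_driver_dominates(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(100, 4)) * [3400, 20, 4400, 300] + [
            17000, 100, 110000, 3000
        ]
        y = 2e-5 * X[:, 0]
        df = sensitivity(X, y, names=["cortical", "cancellous", "ti", "pmma"])
        assert df.iloc[0]["parameter"] == "cortical"
        assert df.iloc[0]["coefficient"] == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.abs(df["coefficient"].values[1:]) < 1e-9)

    def test_independent_output_has_null_coefficients(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(60, 3))
        y = np.full(60, 5.0)
        df = sensitivity(X, y)
        assert np.all(np.abs(df["coefficient"]) < 1e-12)

    def test_known_mixture_recovered(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(500, 3)) * [10.0, 1.0, 100.0]
        w = np.array([0.5, -1.2, 0.01])
        y = X @ w + rng.normal(scale=0.05, size=500)
        df = sensitivity(X, y, names=["a", "b", "c"]).set_index("parameter")
        expected = w * X.std(axis=0, ddof=1) / y.std(ddof=1)
        for name, e in zip(["a", "b", "c"], expected):
            assert df.loc[name, "coefficient"] == pytest.approx(e, abs=0.02)

    def test_collinear_inputs_flagged(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=50)
        X = np.column_stack([x, 2.0 * x + 1e-12 * rng.normal(size=50), rng.normal(size=50)])
        df = sensitivity(X, x)
        assert df["collinear"].all()

    def test_underdetermined_rejected(self):
        with pytest.raises(ValueError):
            sensitivity(np.ones((3, 4)) + np.eye(3, 4), np.ones(3))


class TestCompareBoneModels:
    def _summary(self, mean, name="q"):
        return aggregate_samples(np.array([mean]), angles=np.arange(len(mean)),
                                 quantity=name)

    def test_identical_is_zero(self):
        a = self._summary([1.0, 2.0, 3.0])
        b = self._summary([1.0, 2.0, 3.0])
        assert compare_bone_models(a, b) == 0.0

    def test_uniform_six_percent(self):
        a = self._summary([10.0, 20.0, 5.0])
        b = self._summary([10.6, 21.2, 5.3])
        assert compare_bone_models(a, b) == pytest.approx(6.0)

    def test_randomized_matches_formula(self):
        rng = np.random.default_rng(13)
        x = rng.uniform(1, 10, size=7)
        y = rng.uniform(1, 10, size=7)
        expected = float(np.mean(np.abs(x - y) / np.abs(x)) * 100)
        assert compare_bone_models(
            self._summary(x), self._summary(y)
        ) == pytest.approx(expected)

    def test_mismatched_quantities_rejected(self):
        a = self._summary([1.0], "a")
        b = self._summary([1.0], "b")
        with pytest.raises(ValueError):
            compare_bone_models(a, b)
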