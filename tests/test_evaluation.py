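"""Metrics (MSE, r^2, R^2, zero-line score) against independent oracles."""

import numpy as np
import pandas as pd
import pytest

from kin2emg.evaluation import (
    UndefinedMetricError,
    aggregate,
    median_mad,
    mse,
    r2_determination,
    r_squared,
    score_trial,
    zero_line_score,
)


# -- independent loop-based oracles ----------------------------------------


def _mse_oracle(y, x):
    return sum((yi - xi) ** 2 for yi, xi in zip(y, x)) / len(y)


def _r2_corr_oracle(y, x):
    ym = sum(y) / len(y)
    xm = sum(x) / len(x)
    num = sum((xi - xm) * (yi - ym) for xi, yi in zip(x, y))
    den = (
        sum((xi - xm) ** 2 for xi in x) * sum((yi - ym) ** 2 for yi in y)
    ) ** 0.5
    return (num / den) ** 2


def _r2_det_oracle(y, x):
    ym = sum(y) / len(y)
    return 1 - sum((yi - xi) ** 2 for yi, xi in zip(y, x)) / sum(
        (yi - ym) ** 2 for yi in y
    )


def _zs_oracle(y, x):
    return 100 * (1 - sum((yi - xi) ** 2 for yi, xi in zip(y, x)) / sum(yi**2 for yi in y))


class TestWorkedExamples:
    def test_mse(self):
        assert mse([1, 2, 3], [1, 2, 3]) == 0.0
        assert mse([1, 2, 3], [1, 2, 5]) == pytest.approx(4 / 3)
        y = np.array([0.3, 1.1, -0.4])
        assert mse(y, y + 0.25) == pytest.approx(0.0625)

    def test_r_squared(self):
        y = np.array([1.0, 2.0, 4.0])
        assert r_squared(y, y) == pytest.approx(1.0)
        assert r_squared(y, -y) == pytest.approx(1.0)
        with pytest.raises(UndefinedMetricError):
            r_squared(y, np.full(3, 2.0))

    def test_r2_determination(self):
        y = np.array([1.0, 2.0, 3.0])
        assert r2_determination(y, y) == pytest.approx(1.0)
        assert r2_determination(y, np.full(3, 2.0)) == pytest.approx(0.0)
        assert r2_determination(y, y[::-1]) == pytest.approx(-3.0)
        with pytest.raises(UndefinedMetricError):
            r2_determination(np.full(3, 1.0), y)

    def test_zero_line_score(self):
        y = np.array([1.0, 0.0, 1.0, 0.0])
        assert zero_line_score(y, y) == pytest.approx(100.0)
        assert zero_line_score(y, np.zeros(4)) == pytest.approx(0.0)
        assert zero_line_score(y, y / 2) == pytest.approx(75.0)
        with pytest.raises(UndefinedMetricError):
            zero_line_score(np.zeros(4), y)


class TestOracleEquivalence:
    def test_all_metrics_match_loop_oracles(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            n = int(rng.integers(3, 40))
            y = rng.standard_normal(n) + 1.0
            x = rng.standard_normal(n)
            assert mse(y, x) == pytest.approx(_mse_oracle(y, x), abs=1e-12)
            assert r_squared(y, x) == pytest.approx(_r2_corr_oracle(y, x), abs=1e-12)
            assert r2_determination(y, x) == pytest.approx(
                _r2_det_oracle(y, x), abs=1e-12
            )
            assert zero_line_score(y, x) == pytest.approx(_zs_oracle(y, x), abs=1e-10)

    def test_zs_equals_r2_when_mean_is_zero(self):
        rng = np.random.default_rng(8)
        y = rng.standard_normal(100)
        y -= y.mean()
        x = rng.standard_normal(100)
        assert zero_line_score(y, x) == pytest.approx(100 * r2_determination(y, x))

    def test_zs_r2_algebraic_relation(self):
        # Zs/100 = 1 - (1 - R^2) * sum (y - ybar)^2 / sum y^2
        rng = np.random.default_rng(9)
        y = np.abs(rng.standard_normal(50)) + 0.1
        x = rng.standard_normal(50)
        r2 = r2_determination(y, x)
        lhs = zero_line_score(y, x) / 100
        rhs = 1 - (1 - r2) * np.sum((y - y.mean()) ** 2) / np.sum(y**2)
        assert lhs == pytest.approx(rhs, abs=1e-12)

    def test_error_scaling_monotonicity(self):
        rng = np.random.default_rng(10)
        y = np.abs(rng.standard_normal(60)) + 0.2
        x = y + 0.3 * rng.standard_normal(60)
        for k in (1.5, 2.0, 4.0):
            xk = y + k * (x - y)
            assert zero_line_score(y, xk) < zero_line_score(y, x)
            assert r2_determination(y, xk) < r2_determination(y, x)
            assert mse(y, xk) > mse(y, x)


class TestScoreTrial:
    def test_identical_matrices_perfect(self):
        y = np.abs(np.random.default_rng(0).standard_normal((30, 8)))
        s = score_trial(y, y)
        assert s["mse"] == 0.0
        assert s["r2"] == pytest.approx(1.0)
        assert s["R2"] == pytest.approx(1.0)
        assert s["Zs"] == pytest.approx(100.0)

    def test_pooled_score_between_per_channel_scores(self):
        rng = np.random.default_rng(1)
        y = np.column_stack([np.abs(rng.standard_normal(50)) + 0.1] * 2)
        x = np.column_stack([y[:, 0], np.zeros(50)])  # perfect + silent channel
        pooled = score_trial(y, x)["Zs"]
        per_channel = [zero_line_score(y[:, c], x[:, c]) for c in range(2)]
        assert min(per_channel) < pooled < max(per_channel)

    def test_undefined_metric_reported_missing(self):
        y = np.zeros((10, 2))
        s = score_trial(y, y)
        assert np.isnan(s["Zs"])
        assert s["mse"] == 0.0

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            score_trial(np.zeros((3, 8)), np.zeros((4, 8)))


class TestAggregate:
    @staticmethod
    def _tidy(values, **fixed):
        rows = []
        for i, v in enumerate(values):
            row = {
                "subject": 1,
                "condition": "1seq_0elbow",
                "dataset": "test",
                "movement": f"m{i}",
                "run": 0,
                "metric": "Zs",
                "value": v,
            }
            row.update(fixed)
            rows.append(row)
        return pd.DataFrame(rows)

    def test_single_report(self):
        out = aggregate(self._tidy([42.0]), level="condition")
        assert out["median"].iloc[0] == 42.0
        assert out["mad"].iloc[0] == 0.0

    def test_median_and_mad(self):
        assert median_mad([10, 20, 90]) == (20.0, 10.0)

    def test_median_robust_to_duplicate_of_median(self):
        med1, _ = median_mad([10, 20, 90])
        med2, _ = median_mad([10, 20, 20, 90])
        assert med1 == med2 == 20.0

    def test_runs_collapse_before_movements(self):
        # movement A has runs (0, 100) -> median 50; movement B has run 30
        df = pd.DataFrame(
            [
                dict(subject=1, condition="c", dataset="test", movement="A", run=0,
                     metric="Zs", value=0.0),
                dict(subject=1, condition="c", dataset="test", movement="A", run=1,
                     metric="Zs", value=100.0),
                dict(subject=1, condition="c", dataset="test", movement="B", run=0,
                     metric="Zs", value=30.0),
            ]
        )
        out = aggregate(df, level="subject")
        assert out["median"].iloc[0] == pytest.approx(40.0)  # median(50, 30)

    def test_missing_values_excluded_with_warning(self):
        df = self._tidy([50.0, np.nan])
        with pytest.warns(UserWarning, match="missing"):
            out = aggregate(df, level="condition")
        assert out["median"].iloc[0] == 50.0
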