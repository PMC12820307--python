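"""Evaluation metrics and median/MAD aggregation.

Four complementary metrics compare a predicted activation sequence x
against the recorded one y: the mean squared error, the squared Pearson
correlation r^2, the coefficient of determination R^2, and the zero-line
score

    Z_s = 100 * (1 - sum (y_i - x_i)^2 / sum y_i^2),

an R^2 variant baselined at zero rather than at the signal mean — the
natural reference for non-negative EMG envelopes that rest at zero. Z_s is
100 for a perfect prediction, 0 for predicting all zeros, and negative
when the prediction is worse than silence.

Trial scores pool the full time-by-channel matrix; summaries take medians
(over runs, then movements, then subjects) with the median absolute
deviation of the final step as the dispersion measure.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd


class UndefinedMetricError(ValueError):
    """Metric undefined for this input (e.g. constant or all-zero series)."""


def _check_pair(y, x):
    y = np.asarray(y, dtype=float).ravel()
    x = np.asarray(x, dtype=float).ravel()
    if y.shape != x.shape:
        raise ValueError("length mismatch between original and predicted data")
    if y.size == 0:
        raise ValueError("empty input")
    return y, x


def mse(y, x) -> float:
    """Mean squared error between original y and predicted x."""
    y, x = _check_pair(y, x)
    return float(np.mean((y - x) ** 2))


def r_squared(y, x) -> float:
    """Squared Pearson correlation between prediction and data, in [0, 1]."""
    y, x = _check_pair(y, x)
    yc = y - y.mean()
    xc = x - x.mean()
    denom = np.sqrt(np.sum(xc**2) * np.sum(yc**2))
    if denom == 0:
        raise UndefinedMetricError("constant series: correlation undefined")
    r = float(np.sum(xc * yc) / denom)
    return min(r * r, 1.0)


def r2_determination(y, x) -> float:
    """Coefficient of determination; negative when worse than predicting the mean."""
    y, x = _check_pair(y, x)
    ss_tot = np.sum((y - y.mean()) ** 2)
    if ss_tot == 0:
        raise UndefinedMetricError("constant original data: R^2 undefined")
    return float(1.0 - np.sum((y - x) ** 2) / ss_tot)


def zero_line_score(y, x) -> float:
    """Zero-baselined score on the 0-100 scale (100 = perfect, 0 = silence)."""
    y, x = _check_pair(y, x)
    ss_zero = np.sum(y**2)
    if ss_zero == 0:
        raise UndefinedMetricError("all-zero original data: zero-line score undefined")
    return float(100.0 * (1.0 - np.sum((y - x) ** 2) / ss_zero))


METRICS = ("mse", "r2", "R2", "Zs")


def score_trial(y_matrix: np.ndarray, x_matrix: np.ndarray) -> dict:
    """All four metrics on the flattened time-by-channel pairs of one trial.

    Undefined metrics are reported as NaN (recorded as missing, never
    coerced to zero).
    """
    y = np.asarray(y_matrix, dtype=float)
    x = np.asarray(x_matrix, dtype=float)
    if y.shape != x.shape:
        raise ValueError(f"shape mismatch {y.shape} vs {x.shape}")
    out = {}
    for name, fn in (
        ("mse", mse),
        ("r2", r_squared),
        ("R2", r2_determination),
        ("Zs", zero_line_score),
    ):
        try:
            out[name] = fn(y.ravel(), x.ravel())
        except UndefinedMetricError:
            out[name] = float("nan")
    return out


def median_mad(values) -> tuple:
    """Median and median absolute deviation of a 1-D collection."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size == 0:
        return float("nan"), float("nan")
    med = float(np.median(v))
    return med, float(np.median(np.abs(v - med)))


#: aggregation order: runs are collapsed first, then movements, then subjects
_LEVELS = {
    "movement": ["subject", "condition", "dataset", "movement"],
    "subject": ["subject", "condition", "dataset"],
    "condition": ["condition", "dataset"],
}


def aggregate(reports: pd.DataFrame, level: str = "condition") -> pd.DataFrame:
    """Hierarchical median aggregation of a tidy score table.

    ``reports`` has columns subject, condition, dataset, movement, run,
    metric, value. Scores are first medianed over runs per movement, then
    over movements per subject, then (for ``level="condition"``) over
    subjects; the MAD reported is that of the values entering the final
    median. Groups that are entirely missing are excluded with a warning.
    """
    if level not in _LEVELS:
        raise ValueError(f"bad level {level!r}")
    df = reports.dropna(subset=["value"])
    if len(df) < len(reports):
        warnings.warn("missing metric values excluded from aggregation", stacklevel=2)

    per_movement = (
        df.groupby(["subject", "condition", "dataset", "movement", "metric"])["value"]
        .median()
        .reset_index()
    )
    if level == "movement":
        grouped = per_movement.groupby(_LEVELS[level] + ["metric"])["value"]
        out = grouped.agg(
            median="median", mad=lambda v: median_mad(v)[1], n="count"
        ).reset_index()
        return out
    per_subject = (
        per_movement.groupby(["subject", "condition", "dataset", "metric"])["value"]
        .median()
        .reset_index()
    )
    grouped = per_subject.groupby(_LEVELS[level] + ["metric"])["value"]
    out = grouped.agg(
        median="median", mad=lambda v: median_mad(v)[1], n="count"
    ).reset_index()
    return out
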