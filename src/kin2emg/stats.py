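"""Paired across-subject statistics for condition comparisons.

Zero-line scores are bounded above by 100, which left-skews their
distribution (a gain from 80 to 90 means more than one from 70 to 80). The
scores are therefore passed through Fisher's z-transformation,
``arctanh(Zs / 100)``, before differencing. Normality of the per-subject
differences is gated with the Shapiro-Wilk test (suited to small samples):
if it passes, a two-sided paired t-test is used; otherwise the Wilcoxon
signed-rank test. Effect size is Cohen's d for paired designs,
``mean(diff) / sd(diff)`` with the n-1 sample standard deviation, which
satisfies d = |t| / sqrt(n) exactly for the t branch.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


class DegenerateComparisonError(ValueError):
    """Zero-variance paired differences: test and effect size undefined."""


_CLIP = 100.0 - 1e-6


def fisher_z(zs_score):
    """Variance-stabilizing transform of zero-line scores.

    ``arctanh(Zs / 100)``, strictly increasing on (-100, 100). Scores at or
    beyond the bounds are clipped to ``+/-(100 - 1e-6)`` with a warning so
    the transform stays finite.
    """
    z = np.asarray(zs_score, dtype=float)
    if np.any(z >= 100.0) or np.any(z <= -100.0):
        warnings.warn(
            "zero-line score at/beyond +/-100 clipped before Fisher transform",
            stacklevel=2,
        )
    z = np.clip(z, -_CLIP, _CLIP)
    out = np.arctanh(z / 100.0)
    return float(out) if np.isscalar(zs_score) else out


def cohens_d(diff) -> float:
    """Paired-design Cohen's d: mean over n-1 sample standard deviation."""
    d = np.asarray(diff, dtype=float)
    sd = d.std(ddof=1)
    if sd == 0:
        raise DegenerateComparisonError("zero-variance differences")
    return float(d.mean() / sd)


@dataclass
class StatResult:
    """Outcome of one paired condition comparison across subjects."""

    comparison: str
    n_subjects: int
    test: str  # "paired_t" | "wilcoxon"
    statistic: float
    p_value: float
    cohens_d: float
    shapiro_p: float
    transform_applied: bool


def paired_compare(
    scores_a,
    scores_b,
    alpha: float = 0.05,
    comparison: str = "",
    transform: bool = True,
) -> StatResult:
    """Paired comparison of two conditions' per-subject summary scores.

    ``scores_a`` and ``scores_b`` hold one summary zero-line score per
    subject (same subject order). Both are Fisher-z transformed, the
    Shapiro-Wilk test gates on the differences at ``alpha``, and the paired
    t-test (or Wilcoxon signed-rank on the gate failing) is run two-sided.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("need equal-length 1-D per-subject score vectors")
    if a.size < 3:
        raise ValueError("need at least 3 subjects for a paired test")
    if transform:
        a, b = fisher_z(a), fisher_z(b)
    diff = a - b
    if np.allclose(diff.std(ddof=1), 0.0):
        raise DegenerateComparisonError("zero-variance differences")
    shapiro_p = float(sps.shapiro(diff).pvalue)
    if shapiro_p >= alpha:
        res = sps.ttest_rel(a, b)
        test = "paired_t"
    else:
        res = sps.wilcoxon(a, b)
        test = "wilcoxon"
    return StatResult(
        comparison=comparison,
        n_subjects=int(a.size),
        test=test,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        cohens_d=cohens_d(diff),
        shapiro_p=shapiro_p,
        transform_applied=transform,
    )
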