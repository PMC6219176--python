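"""Reliability and agreement statistics.

The growth-standard screen treats the three published formula sets as
three "raters" scoring the same subjects (GA values), and asks how
consistent their ratings are.  The statistic is the single-rating,
consistency, two-way random-effects intraclass correlation ICC(C,1),

    ICC(C,1) = (MS_subjects - MS_error) / (MS_subjects + (k-1) MS_error),

from the two-way ANOVA decomposition of an n x k complete ratings matrix.
The consistency form ignores rater-specific constant offsets; the
absolute-agreement variant ICC(A,1) is provided as an alternative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DegenerateInputError, ValidationFailure


@dataclass(frozen=True)
class RatingsMatrix:
    """Complete n subjects x k raters grid (no missing cells)."""

    values: np.ndarray
    rater_labels: tuple[str, ...] = ()

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 2:
            raise ValidationFailure("ratings must be a 2-D subjects x raters grid")
        n, k = values.shape
        if n < 3 or k < 2:
            raise ValidationFailure(
                f"ratings need >= 3 subjects and >= 2 raters, got {n} x {k}"
            )
        if not np.isfinite(values).all():
            raise ValidationFailure("ratings contain missing or non-finite cells")
        if self.rater_labels and len(self.rater_labels) != k:
            raise ValidationFailure("rater_labels length must match rater count")


def _anova_mean_squares(matrix: RatingsMatrix):
    values = matrix.values
    n, k = values.shape
    grand = values.mean()
    subject_means = values.mean(axis=1)
    rater_means = values.mean(axis=0)
    ms_subjects = k * np.sum((subject_means - grand) ** 2) / (n - 1)
    ms_raters = n * np.sum((rater_means - grand) ** 2) / (k - 1)
    resid = values - subject_means[:, None] - rater_means[None, :] + grand
    ms_error = np.sum(resid**2) / ((n - 1) * (k - 1))
    return ms_subjects, ms_raters, ms_error


def icc_consistency_single(matrix: RatingsMatrix) -> float:
    """ICC(C,1): two-way random effects, single rating, consistency."""
    if not isinstance(matrix, RatingsMatrix):
        matrix = RatingsMatrix(np.asarray(matrix))
    ms_subjects, _, ms_error = _anova_mean_squares(matrix)
    k = matrix.values.shape[1]
    denom = ms_subjects + (k - 1) * ms_error
    if denom <= 0 or np.isclose(ms_subjects, 0.0):
        raise DegenerateInputError(
            "no between-subject variance; ICC undefined for a constant matrix"
        )
    return float((ms_subjects - ms_error) / denom)


def icc_agreement_single(matrix: RatingsMatrix) -> float:
    """ICC(A,1): absolute agreement variant (rater offsets count as error)."""
    if not isinstance(matrix, RatingsMatrix):
        matrix = RatingsMatrix(np.asarray(matrix))
    ms_subjects, ms_raters, ms_error = _anova_mean_squares(matrix)
    n, k = matrix.values.shape
    denom = ms_subjects + (k - 1) * ms_error + k * (ms_raters - ms_error) / n
    if denom <= 0 or np.isclose(ms_subjects, 0.0):
        raise DegenerateInputError(
            "no between-subject variance; ICC undefined for a constant matrix"
        )
    return float((ms_subjects - ms_error) / denom)


def interclass_r(x, y) -> tuple[float, float]:
    """Pearson product-moment correlation with its two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationFailure("interclass_r expects two equal-length 1-D sequences")
    if x.size < 3:
        raise ValidationFailure("interclass_r needs at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("constant input; correlation undefined")
    result = stats.pearsonr(x, y)
    return float(result.statistic), float(result.pvalue)


def within_pct(actual, estimate, pct: float = 10.0) -> float:
    """Fraction of pairs with |actual - estimate| <= (pct/100) * actual.

    The boundary is inclusive: an estimate exactly ``pct`` percent away
    still counts as within.
    """
    actual = np.asarray(actual, dtype=float)
    estimate = np.asarray(estimate, dtype=float)
    if actual.shape != estimate.shape or actual.size < 1:
        raise ValidationFailure("within_pct expects equal-length non-empty sequences")
    if np.any(actual <= 0):
        raise ValidationFailure("actual values must be strictly positive")
    hits = np.abs(actual - estimate) <= (pct / 100.0) * actual
    return float(hits.mean())
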