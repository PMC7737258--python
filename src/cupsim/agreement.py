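"""Agreement statistics: two-way random-effects absolute-agreement ICC and
Pearson correlation.

The intraclass correlation follows the two-way random-effects,
absolute-agreement, single-measure definition (ICC(2,1) in the
Shrout-Fleiss taxonomy, ICC(A,1) in McGraw-Wong): subjects and raters are
both random draws, and systematic rater shifts count as disagreement.  From
the two-way ANOVA mean squares (rows = subjects, columns = raters),

    ICC(2,1) = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n) .

The confidence interval uses the McGraw-Wong F-based construction with
Satterthwaite degrees of freedom; the p-value tests ICC = 0 via
F = MSR / MSE on (n-1, (n-1)(k-1)) degrees of freedom.  The average-measure
form ICC(2,k) is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ParameterError

__all__ = ["RatingsMatrix", "ICCResult", "icc_two_way_random_absolute", "pearson"]


@dataclass(frozen=True)
class RatingsMatrix:
    """n_subjects x k_raters matrix of measurements with no missing cells."""

    values: np.ndarray
    rater_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ParameterError("ratings must be a 2-D matrix")
        n, k = v.shape
        if n < 3 or k < 2:
            raise ParameterError(
                f"need >= 3 subjects and >= 2 raters, got {n} x {k}"
            )
        if not np.all(np.isfinite(v)):
            raise ParameterError("ratings contain missing/non-finite cells")
        if self.rater_labels and len(self.rater_labels) != k:
            raise ParameterError("rater_labels length does not match columns")
        object.__setattr__(self, "values", v)

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def k_raters(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class ICCResult:
    """ICC point estimate with CI, p-value and the underlying mean squares."""

    icc: float
    ci_low: float
    ci_high: float
    p_value: float
    ms_rows: float
    ms_cols: float
    ms_error: float
    n_subjects: int
    k_raters: int
    average_measure: bool = False


def _anova_mean_squares(x: np.ndarray) -> tuple[float, float, float]:
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * float(((row_means - grand) ** 2).sum())
    ss_cols = n * float(((col_means - grand) ** 2).sum())
    ss_total = float(((x - grand) ** 2).sum())
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = max(ss_err, 0.0) / ((n - 1) * (k - 1))
    return msr, msc, mse


def icc_two_way_random_absolute(
    m: RatingsMatrix | np.ndarray,
    average_measure: bool = False,
    ci: float = 0.95,
) -> ICCResult:
    """Absolute-agreement ICC from a two-way random-effects model.

    Parameters
    ----------
    m:
        Ratings matrix (subjects x raters).
    average_measure:
        If True, report ICC(2,k) — reliability of the k-rater mean — instead
        of the single-measure ICC(2,1).
    ci:
        Confidence level of the interval (default 95%).
    """
    if not isinstance(m, RatingsMatrix):
        m = RatingsMatrix(np.asarray(m, dtype=float))
    x = m.values
    n, k = x.shape
    msr, msc, mse = _anova_mean_squares(x)
    if msr <= 0 and msc <= 0 and mse <= 0:
        raise ParameterError("zero total variance: ICC undefined")
    denom_single = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom_single == 0:
        raise ParameterError("degenerate ANOVA decomposition: ICC undefined")
    icc1 = (msr - mse) / denom_single

    # McGraw & Wong F-based interval for ICC(A,1)
    alpha = 1.0 - ci
    if icc1 >= 1.0:  # perfect agreement: interval collapses
        lo1 = hi1 = 1.0
    else:
        a = k * icc1 / (n * (1.0 - icc1))
        b = 1.0 + k * icc1 * (n - 1) / (n * (1.0 - icc1))
        num_v = (a * msc + b * mse) ** 2
        den_v = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        v = num_v / den_v if den_v > 0 else (n - 1) * (k - 1)
        f_l = stats.f.ppf(1.0 - alpha / 2.0, n - 1, v)
        f_u = stats.f.ppf(1.0 - alpha / 2.0, v, n - 1)
        lo1 = n * (msr - f_l * mse) / (
            f_l * (k * msc + (k * n - k - n) * mse) + n * msr
        )
        hi1 = n * (f_u * msr - mse) / (
            k * msc + (k * n - k - n) * mse + n * f_u * msr
        )
    # F test of ICC = 0
    if mse > 0:
        f_stat = msr / mse
        p = float(stats.f.sf(f_stat, n - 1, (n - 1) * (k - 1)))
    else:
        p = 0.0

    if average_measure:
        def spearman_brown(r: float) -> float:
            return 1.0 if r >= 1.0 else k * r / (1.0 + (k - 1) * r)

        icc_val, lo, hi = (spearman_brown(r) for r in (icc1, lo1, hi1))
    else:
        icc_val, lo, hi = icc1, lo1, hi1
    lo = min(lo, icc_val)
    hi = max(hi, icc_val)
    return ICCResult(
        icc=float(icc_val), ci_low=float(lo), ci_high=float(hi), p_value=p,
        ms_rows=msr, ms_cols=msc, ms_error=mse,
        n_subjects=n, k_raters=k, average_measure=average_measure,
    )


def pearson(x, y) -> tuple[float, float]:
    """Sample Pearson correlation and two-sided t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ParameterError("x and y must be 1-D of equal length")
    if x.size < 3:
        raise ParameterError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ParameterError("zero variance: correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
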