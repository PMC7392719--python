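"""Method-comparison statistics: Pearson r, Bland-Altman, single-measure ICCs.

Bland-Altman limits of agreement use the classical fixed 1.96 multiplier on
the SD of paired differences (n-1 denominator); differences are oriented as
``second method - first method`` throughout.  Intraclass correlation
coefficients are the Shrout-Fleiss single-measure forms: ICC(1,1) from the
one-way random ANOVA and ICC(2,1) from the two-way random ANOVA.  Negative
ICC estimates are reported as-is, never clipped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import InsufficientDataError, InvalidParameterError, UndefinedStatisticError

__all__ = [
    "ICC_MODELS",
    "BlandAltman",
    "AgreementReport",
    "pearson",
    "bland_altman",
    "icc_single",
    "compare_methods",
]

ICC_MODELS = ("one_way_single", "two_way_random_single")


@dataclass
class BlandAltman:
    """Bias and 95% limits of agreement for paired differences (y - x)."""

    bias: float
    loa_low: float
    loa_high: float
    sd_diff: float
    n: int


@dataclass
class AgreementReport:
    """Cross-method agreement summary for one measured quantity."""

    n: int
    pearson_r: float
    bias: float
    loa_low: float
    loa_high: float
    icc: float
    icc_model: str

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "pearson_r": self.pearson_r,
            "bias": self.bias,
            "loa_low": self.loa_low,
            "loa_high": self.loa_high,
            "icc": self.icc,
            "icc_model": self.icc_model,
        }


def _paired(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise InvalidParameterError("x and y must have equal length")
    return x, y


def pearson(x, y) -> float:
    """Product-moment correlation of two paired samples (n >= 3)."""
    x, y = _paired(x, y)
    if len(x) < 3:
        raise InsufficientDataError("pearson requires at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedStatisticError("correlation undefined for zero-variance input")
    return float(stats.pearsonr(x, y).statistic)


def bland_altman(x, y) -> BlandAltman:
    """Bland-Altman agreement of method B (``y``) against method A (``x``).

    d = y - x; bias = mean(d); limits of agreement = bias -/+ 1.96 * SD(d).
    """
    x, y = _paired(x, y)
    n = len(x)
    if n < 2:
        raise InsufficientDataError("bland_altman requires at least 2 pairs")
    d = y - x
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return BlandAltman(bias, bias - 1.96 * sd, bias + 1.96 * sd, sd, n)


def icc_single(ratings, model: str = "two_way_random_single") -> float:
    """Single-measure intraclass correlation of a subjects x raters matrix.

    ``one_way_single`` (ICC(1,1)):  (MSB - MSW) / (MSB + (k-1) MSW)
    ``two_way_random_single`` (ICC(2,1)):
        (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

    with MSB/MSW the between/within-subject mean squares of the one-way
    ANOVA and MSR/MSC/MSE the row (subject), column (rater) and residual
    mean squares of the two-way decomposition.
    """
    if model not in ICC_MODELS:
        raise InvalidParameterError(f"model must be one of {ICC_MODELS}, got {model!r}")
    m = np.asarray(ratings, dtype=float)
    if m.ndim != 2:
        raise InvalidParameterError("ratings must be a 2-D subjects x raters matrix")
    if np.isnan(m).any():
        raise InvalidParameterError("ratings must have no missing cells")
    n, k = m.shape
    if n < 5:
        raise InsufficientDataError("icc_single requires at least 5 subjects")
    if k < 2:
        raise InsufficientDataError("icc_single requires at least 2 raters")

    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ss_rows = k * float(((row_means - grand) ** 2).sum())
    ss_cols = n * float(((col_means - grand) ** 2).sum())
    ss_total = float(((m - grand) ** 2).sum())

    if model == "one_way_single":
        msb = ss_rows / (n - 1)
        ss_within = ss_total - ss_rows
        msw = ss_within / (n * (k - 1))
        denom = msb + (k - 1) * msw
        if denom == 0:
            raise UndefinedStatisticError("ICC undefined: zero total variance")
        return float((msb - msw) / denom)

    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        raise UndefinedStatisticError("ICC undefined: zero total variance")
    return float((msr - mse) / denom)


def compare_methods(x, y, icc_model: str = "two_way_random_single") -> AgreementReport:
    """Full agreement report of method ``y`` against method ``x``.

    Combines Pearson correlation, Bland-Altman bias/limits (y - x) and the
    single-measure ICC of the n x 2 ratings matrix [x, y].  Where r or the
    ICC is undefined for the data (zero variance, too few subjects) the
    report carries NaN instead of raising, so a degenerate comparison still
    yields its bias and limits.
    """
    x, y = _paired(x, y)
    ba = bland_altman(x, y)
    try:
        r = pearson(x, y)
    except (InsufficientDataError, UndefinedStatisticError):
        r = float("nan")
    try:
        icc = icc_single(np.column_stack([x, y]), icc_model)
    except (InsufficientDataError, UndefinedStatisticError):
        icc = float("nan")
    return AgreementReport(
        n=len(x),
        pearson_r=r,
        bias=ba.bias,
        loa_low=ba.loa_low,
        loa_high=ba.loa_high,
        icc=icc,
        icc_model=icc_model,
    )
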