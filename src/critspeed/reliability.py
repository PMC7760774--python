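"""Agreement and consistency statistics for paired measurements.

Typical error (TE), coefficient of variation (CV%), intraclass
correlation (two-way mixed, consistency, single measure), Pearson
correlation, and the paired t-test — the toolkit used to judge whether
a field-predicted VO2max can stand in for the lab-measured one.

TE follows the within-pair convention: the SD of the paired differences
divided by sqrt(2), i.e. the error attributable to one measurement when
both carry independent error of equal size. A regression SEE (df =
n - k - 1) converts to the same scale through a degrees-of-freedom
correction, see :func:`te_from_see`.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class ReliabilityReport:
    te: float
    cv_percent: float
    icc: float
    pearson_r: float
    pearson_p: float
    paired_t: float
    paired_p: float
    n: int
    ci_te_lower: float
    ci_te_upper: float

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def _paired(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    return x, y


def typical_error(x, y) -> float:
    """SD of the paired differences divided by sqrt(2)."""
    x, y = _paired(x, y)
    if x.size < 2:
        raise ValueError("need at least 2 pairs")
    return float(np.std(x - y, ddof=1) / math.sqrt(2.0))


def te_from_see(see: float, n: int, k: int) -> float:
    """Typical error implied by a regression SEE.

    The SEE uses df = n - k - 1; rescaling to the df = n - 1 residual SD
    and dividing by sqrt(2) puts it on the within-pair TE scale:
    ``te = see * sqrt((n - k - 1) / (n - 1)) / sqrt(2)``.
    """
    if n <= k + 1:
        raise ValueError("need n > k + 1 for positive residual df")
    if see < 0:
        raise ValueError("see must be >= 0")
    return see * math.sqrt((n - k - 1) / (n - 1)) / math.sqrt(2.0)


def te_confidence_interval(te: float, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Chi-square CI for the typical error (interval on the diff variance)."""
    if n < 2:
        raise ValueError("need at least 2 pairs")
    df = n - 1
    alpha = 1.0 - conf
    lower = te * math.sqrt(df / stats.chi2.ppf(1 - alpha / 2, df))
    upper = te * math.sqrt(df / stats.chi2.ppf(alpha / 2, df))
    return lower, upper


def cv_percent(x, y, method: str = "log") -> float:
    """Coefficient of variation of the paired differences, in percent.

    ``linear``: 100 * TE / grand mean. ``log``: TE of the natural-log
    data back-transformed, 100 * (exp(TE_ln) - 1), which expresses a
    multiplicative error and is the default.
    """
    x, y = _paired(x, y)
    if method == "linear":
        grand = float(np.concatenate([x, y]).mean())
        if grand == 0:
            raise ValueError("grand mean is zero; linear CV undefined")
        return 100.0 * typical_error(x, y) / grand
    if method == "log":
        if np.any(x <= 0) or np.any(y <= 0):
            raise ValueError("log-method CV needs strictly positive data")
        return 100.0 * (math.exp(typical_error(np.log(x), np.log(y))) - 1.0)
    raise ValueError(f"unknown CV method {method!r}")


def icc_consistency(x, y) -> float:
    """ICC(3,1): two-way mixed effects, consistency, single measure.

    From the two-way repeated-measures decomposition with k = 2 raters:
    ``(MS_rows - MS_error) / (MS_rows + MS_error)``. Fixed offsets
    between the two columns do not lower it.
    """
    x, y = _paired(x, y)
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    data = np.column_stack([x, y])
    k = 2
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * float(((row_means - grand) ** 2).sum())
    ss_cols = n * float(((col_means - grand) ** 2).sum())
    ss_total = float(((data - grand) ** 2).sum())
    ss_err = ss_total - ss_rows - ss_cols
    ms_rows = ss_rows / (n - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    if ms_rows <= 0:
        raise ValueError(
            "zero between-subject variance: ICC undefined for this sample"
        )
    return (ms_rows - ms_err) / (ms_rows + (k - 1) * ms_err)


def pearson_r(x, y) -> tuple[float, float]:
    """Product-moment correlation with its two-sided p (t transform, n-2 df)."""
    x, y = _paired(x, y)
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance input")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def paired_t(x, y) -> tuple[float, float]:
    """Paired t-test; t = mean(d) / (SD(d)/sqrt(n)), two-sided p with n-1 df.

    A zero-variance difference vector is degenerate: t is 0 with p = 1
    when the means agree exactly, and undefined (nan) otherwise.
    """
    x, y = _paired(x, y)
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = x - y
    sd = float(np.std(d, ddof=1))
    mean = float(d.mean())
    if sd == 0.0:
        if mean == 0.0:
            return 0.0, 1.0
        return float("nan"), float("nan")
    t = mean / (sd / math.sqrt(n))
    p = 2.0 * float(stats.t.sf(abs(t), n - 1))
    return t, p


def reliability_report(x, y, cv_method: str = "log") -> ReliabilityReport:
    """All agreement statistics for one pair of measurement columns."""
    x, y = _paired(x, y)
    te = typical_error(x, y)
    lo, hi = te_confidence_interval(te, x.size)
    r, rp = pearson_r(x, y)
    t, p = paired_t(x, y)
    return ReliabilityReport(
        te=te,
        cv_percent=cv_percent(x, y, method=cv_method),
        icc=icc_consistency(x, y),
        pearson_r=r,
        pearson_p=rp,
        paired_t=t,
        paired_p=p,
        n=int(x.size),
        ci_te_lower=lo,
        ci_te_upper=hi,
    )
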