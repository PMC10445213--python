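"""Test-retest reliability statistics: ICC(A,2) and Bland-Altman agreement.

The intraclass correlation implemented here is the two-way, absolute-
agreement, average-measures coefficient for k raters (sessions), usually
written ICC(A,k).  With mean squares from the two-way subject x session
decomposition (MSR rows, MSC columns, MSE residual) the point estimate is

    ICC(A,k) = (MSR - MSE) / (MSR + (MSC - MSE) / n)

and the 95% CI follows the F-based construction of McGraw & Wong: the
single-measures interval is computed on Satterthwaite-approximated degrees
of freedom and stepped up to average measures via Spearman-Brown.  This is
the construction used by the standard R/Python reliability packages, so
results are directly comparable with published ICC tables.

Bland-Altman statistics quantify *absolute* agreement: the bias (mean
session1 - session2 difference), its t-based 95% CI, the limits of
agreement bias +/- 1.96 sd(d), their classical standard error sd*sqrt(3/n),
and the slope of regressing the difference on the pair mean (proportional
bias), with a two-sided p-value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "ICCResult",
    "BlandAltmanResult",
    "icc_a2",
    "classify_icc",
    "bland_altman",
    "reliability_report",
]


@dataclass(frozen=True)
class ICCResult:
    estimate: float
    ci_low: float
    ci_high: float
    n: int
    k: int
    classification: str


@dataclass(frozen=True)
class BlandAltmanResult:
    bias: float
    bias_ci_low: float
    bias_ci_high: float
    loa_low: float
    loa_high: float
    loa_se: float
    slope: float
    slope_p: float


def _as_table(table) -> np.ndarray:
    X = np.asarray(table, dtype=float)
    if X.ndim != 2 or X.shape[1] != 2:
        raise ValueError(f"expected an n x 2 matrix, got shape {X.shape}")
    if np.isnan(X).any():
        raise ValueError("table contains missing cells; complete-case tables required")
    return X


def _icc_a2_core(X: np.ndarray, alpha: float = 0.05):
    """Vectorised ICC(A,k) with CI on a (reps, n, k) stack of tables.

    Returns (estimate, ci_low, ci_high) arrays of shape (reps,).
    """
    reps, n, k = X.shape
    mean_r = X.mean(axis=2)
    mean_c = X.mean(axis=1)
    gm = X.mean(axis=(1, 2))
    msr = k * ((mean_r - gm[:, None]) ** 2).sum(axis=1) / (n - 1)
    msc = n * ((mean_c - gm[:, None]) ** 2).sum(axis=1) / (k - 1)
    sse = ((X - mean_r[:, :, None] - mean_c[:, None, :] + gm[:, None, None]) ** 2).sum(axis=(1, 2))
    mse = sse / ((n - 1) * (k - 1))

    denom_k = msr + (msc - mse) / n
    with np.errstate(divide="ignore", invalid="ignore"):
        est_k = np.where(denom_k != 0, (msr - mse) / denom_k, np.nan)
        # single-measures estimate, needed for the CI degrees of freedom
        est_1 = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
        fj = msc / mse
        b = n * (1 + (k - 1) * est_1) - k * est_1
        v = ((n - 1) * (k - 1)) * (k * est_1 * fj + b) ** 2 / ((n - 1) * k**2 * est_1**2 * fj**2 + b**2)
        f_lo = sps.f.ppf(1 - alpha / 2, n - 1, v)
        f_hi = sps.f.ppf(1 - alpha / 2, v, n - 1)
        l1 = n * (msr - f_lo * mse) / (f_lo * (k * msc + (k * n - k - n) * mse) + n * msr)
        u1 = n * (f_hi * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f_hi * msr)
        lo = l1 * k / (1 + l1 * (k - 1))
        hi = u1 * k / (1 + u1 * (k - 1))
    return est_k, lo, hi


def icc_a2(table, alpha: float = 0.05) -> ICCResult:
    """ICC(A,2) with F-based 95% CI and qualitative classification.

    Parameters
    ----------
    table
        n x 2 array-like, one row per subject, columns = sessions.
    """
    X = _as_table(table)
    n = X.shape[0]
    if n < 3:
        raise ValueError(f"ICC requires at least 3 subjects, got {n}")
    if np.allclose(X.var(), 0):
        raise ValueError("degenerate table: zero total variance")
    est, lo, hi = _icc_a2_core(X[None, :, :], alpha=alpha)
    est, lo, hi = float(est[0]), float(lo[0]), float(hi[0])
    # perfect agreement: MSC = MSE = 0 makes the CI arithmetic 0/0
    if not np.isfinite(lo) or not np.isfinite(hi):
        lo = min(lo, est) if np.isfinite(lo) else est
        hi = max(hi, est) if np.isfinite(hi) else est
    lo, hi = min(lo, est), max(hi, est)
    return ICCResult(est, lo, hi, n=n, k=2, classification=classify_icc(est))


def classify_icc(estimate: float) -> str:
    """Qualitative ICC class: excellent (>0.80), good (0.60-0.80],
    moderate (0.40-0.60], poor (<=0.40).

    Boundaries are assigned to the lower class, consistent with the strict
    inequality in "excellent (>0.80)".
    """
    if estimate > 0.80:
        return "excellent"
    if estimate > 0.60:
        return "good"
    if estimate > 0.40:
        return "moderate"
    return "poor"


def bland_altman(table, alpha: float = 0.05) -> BlandAltmanResult:
    """Bland-Altman agreement statistics on an n x 2 (session1, session2) table.

    Differences are session1 - session2, so positive bias means larger
    measures in session one.
    """
    X = _as_table(table)
    n = X.shape[0]
    if n < 3:
        raise ValueError(f"Bland-Altman requires at least 3 subjects, got {n}")
    d = X[:, 0] - X[:, 1]
    m = X.mean(axis=1)
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    tcrit = float(sps.t.ppf(1 - alpha / 2, n - 1))
    half = tcrit * sd / np.sqrt(n)
    loa_se = sd * np.sqrt(3.0 / n)
    if np.allclose(m.var(), 0):
        slope, slope_p = np.nan, np.nan
    else:
        fit = sps.linregress(m, d)
        slope, slope_p = float(fit.slope), float(fit.pvalue)
        if sd == 0.0:  # constant difference: slope is exactly 0, not noise
            slope, slope_p = 0.0, 1.0
    return BlandAltmanResult(
        bias=bias,
        bias_ci_low=bias - half,
        bias_ci_high=bias + half,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        loa_se=float(loa_se),
        slope=slope,
        slope_p=slope_p,
    )


def _stars(p: float) -> str:
    if not np.isfinite(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def reliability_report(tables) -> "pd.DataFrame":
    """Build the full reliability table over scores and conditions.

    Parameters
    ----------
    tables
        Mapping ``(score, part, instruction) -> n x 2 array-like`` (one
        complete subjects-by-sessions table per cell), e.g. the output of
        :func:`trailgaze.scores.condition_tables`.

    Returns
    -------
    DataFrame with one row per score x part x instruction: descriptive
    statistics per session, Bland-Altman bias [CI], LOAs (SE), slope with
    significance stars, and ICC [CI] with classification.
    """
    import pandas as pd

    if not tables:
        raise ValueError("no condition tables supplied")
    rows = []
    for (score, part, instruction), table in tables.items():
        X = _as_table(table)
        ba = bland_altman(X)
        icc = icc_a2(X)
        rows.append(
            {
                "score": score,
                "part": part,
                "instruction": instruction,
                "n": X.shape[0],
                "mean_s1": X[:, 0].mean(),
                "sd_s1": X[:, 0].std(ddof=1),
                "mean_s2": X[:, 1].mean(),
                "sd_s2": X[:, 1].std(ddof=1),
                "bias": ba.bias,
                "bias_ci_low": ba.bias_ci_low,
                "bias_ci_high": ba.bias_ci_high,
                "loa_low": ba.loa_low,
                "loa_high": ba.loa_high,
                "loa_se": ba.loa_se,
                "slope": ba.slope,
                "slope_p": ba.slope_p,
                "slope_sig": _stars(ba.slope_p),
                "icc": icc.estimate,
                "icc_ci_low": icc.ci_low,
                "icc_ci_high": icc.ci_high,
                "icc_class": icc.classification,
            }
        )
    return pd.DataFrame(rows)
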