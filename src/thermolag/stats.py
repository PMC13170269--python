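"""Performance metric, tradeoff regression, slope comparison, and t-tests.

The performance of a strain in regime ``x`` is ``P_x = t_ref / t_x``: the
time it takes to reach a fixed OD threshold under reference conditions
(30 degC growth) divided by the time under the regime of interest (growth at
35 degC, or recovery at 30 degC after a heat shock).  P = 1 means no
impairment, P = 0.5 means the strain took twice as long.  The tradeoff
between thermal regimes is summarized by an OLS fit of one performance on
the other across strains, and two cohorts' tradeoff slopes are compared via
the group-by-covariate interaction of an analysis of covariance (ANCOVA).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "PerformanceRecord",
    "TradeoffFit",
    "SlopeComparison",
    "TwoSampleTest",
    "ReplicateSummary",
    "performance",
    "fit_tradeoff",
    "compare_slopes_ancova",
    "two_sample_t",
    "summarize_replicates",
]


@dataclass(frozen=True)
class PerformanceRecord:
    """P_x = t_ref / t_cond for one strain in one regime.

    ``performance`` is ``None`` (with a ``reason``) when the strain never
    reached the threshold in the regime of interest.
    """

    strain: str
    condition: str
    t_ref_h: float
    t_cond_h: float | None
    performance: float | None
    reason: str | None = None


def performance(
    t_ref_h: float,
    t_cond_h: float | None,
    strain: str = "",
    condition: str = "",
) -> PerformanceRecord:
    """Time-to-threshold ratio P = t_ref / t_cond.

    A missing or non-finite ``t_cond_h`` (threshold never reached) yields a
    record with ``performance=None`` and a reason code instead of an error,
    so missingness can propagate to the regression stage and be dropped
    pairwise there.
    """
    if t_ref_h is None or not np.isfinite(t_ref_h) or t_ref_h <= 0:
        raise ValueError("t_ref_h must be a positive finite time")
    if t_cond_h is None or not np.isfinite(t_cond_h):
        return PerformanceRecord(
            strain=strain,
            condition=condition,
            t_ref_h=float(t_ref_h),
            t_cond_h=None,
            performance=None,
            reason="threshold_not_reached",
        )
    if t_cond_h <= 0:
        raise ValueError("t_cond_h must be positive")
    return PerformanceRecord(
        strain=strain,
        condition=condition,
        t_ref_h=float(t_ref_h),
        t_cond_h=float(t_cond_h),
        performance=float(t_ref_h) / float(t_cond_h),
    )


@dataclass
class TradeoffFit:
    """OLS line through (P_HS, P_35) points across strains."""

    slope: float
    intercept: float
    r2: float
    n: int
    residuals: np.ndarray


def fit_tradeoff(
    x: Sequence[float] | np.ndarray, y: Sequence[float] | np.ndarray
) -> TradeoffFit:
    """Ordinary least squares of y on x with pairwise deletion of missing pairs.

    ``r2 = 1 - SSE/SST``; a constant y gives slope 0 and r2 = 0 by the
    ``SST = 0`` convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = int(x.size)
    if n < 3:
        raise ValueError(f"need at least 3 complete pairs, got {n}")
    if np.ptp(x) == 0:
        raise ValueError("x has zero variance; slope undefined")
    res = sps.linregress(x, y)
    slope, intercept = float(res.slope), float(res.intercept)
    residuals = y - (intercept + slope * x)
    sst = float(((y - y.mean()) ** 2).sum())
    r2 = 0.0 if sst == 0 else 1.0 - float((residuals**2).sum()) / sst
    return TradeoffFit(
        slope=slope,
        intercept=intercept,
        r2=min(max(r2, 0.0), 1.0),
        n=n,
        residuals=residuals,
    )


@dataclass
class SlopeComparison:
    """ANCOVA interaction test between two cohorts' tradeoff slopes.

    The pooled model is ``y = b0 + b1 x + b2 g + b3 (x g)`` with ``g = 0``
    for group A and ``g = 1`` for group B, so ``interaction_estimate =
    slope_b - slope_a``.  ``statistic`` is the t value on ``b3`` with
    ``df = n_total - 4`` residual degrees of freedom (the single-df
    interaction F test is its square).
    """

    slope_a: float
    slope_b: float
    interaction_estimate: float
    statistic: float
    df: int
    p_value: float
    flags: tuple[str, ...] = ()


def compare_slopes_ancova(
    group_a: tuple[Sequence[float], Sequence[float]],
    group_b: tuple[Sequence[float], Sequence[float]],
) -> SlopeComparison:
    """Test whether two cohorts share a tradeoff slope.

    Fits the pooled interaction model by OLS and reports the two-sided t
    test on the interaction term.  Per-group slopes are reported from
    separate fits (they coincide with ``b1`` and ``b1 + b3`` of the pooled
    model).  A residual variance of exactly zero (noiseless data) yields
    ``p = 1`` when the slopes agree and ``p = 0`` with an infinite-t flag
    when they differ.
    """
    fit_a = fit_tradeoff(*group_a)
    fit_b = fit_tradeoff(*group_b)

    xa = np.asarray(group_a[0], dtype=float)
    ya = np.asarray(group_a[1], dtype=float)
    xb = np.asarray(group_b[0], dtype=float)
    yb = np.asarray(group_b[1], dtype=float)
    keep_a = np.isfinite(xa) & np.isfinite(ya)
    keep_b = np.isfinite(xb) & np.isfinite(yb)
    xa, ya, xb, yb = xa[keep_a], ya[keep_a], xb[keep_b], yb[keep_b]

    x = np.concatenate([xa, xb])
    y = np.concatenate([ya, yb])
    g = np.concatenate([np.zeros_like(xa), np.ones_like(xb)])
    design = np.column_stack([np.ones_like(x), x, g, x * g])
    result = sm.OLS(y, design).fit()
    b3 = float(result.params[3])
    df = int(result.df_resid)

    scale = max(1.0, float((y**2).sum()))
    flags: tuple[str, ...] = ()
    if result.ssr <= 1e-12 * scale:
        # Noiseless data: the interaction is either exactly zero or
        # infinitely significant.
        if abs(b3) <= 1e-9 * max(1.0, abs(fit_a.slope)):
            statistic, p_value = 0.0, 1.0
        else:
            statistic = float(np.inf) if b3 > 0 else float(-np.inf)
            p_value = 0.0
            flags = ("infinite_t",)
    else:
        statistic = float(result.tvalues[3])
        p_value = float(result.pvalues[3])

    return SlopeComparison(
        slope_a=fit_a.slope,
        slope_b=fit_b.slope,
        interaction_estimate=b3,
        statistic=statistic,
        df=df,
        p_value=p_value,
        flags=flags,
    )


@dataclass
class TwoSampleTest:
    """Two-sided two-sample t-test result."""

    t_statistic: float
    df: float
    p_value: float
    mean_difference: float
    pooled_sd: float
    flags: tuple[str, ...] = ()


def two_sample_t(
    a: Sequence[float] | np.ndarray,
    b: Sequence[float] | np.ndarray,
    equal_var: bool = True,
) -> TwoSampleTest:
    """Student's t-test (pooled equal-variance by default; Welch optional).

    Degenerate inputs with zero pooled variance return t = 0, p = 1 when the
    means agree, and an infinite-t flag with p = 0 when they differ.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise ValueError("each sample needs at least 2 observations")
    mean_diff = float(a.mean() - b.mean())
    va = float(a.var(ddof=1))
    vb = float(b.var(ddof=1))

    if equal_var:
        df: float = na + nb - 2
        sp2 = ((na - 1) * va + (nb - 1) * vb) / df
        pooled_sd = float(np.sqrt(sp2))
        se = pooled_sd * np.sqrt(1.0 / na + 1.0 / nb)
    else:
        se2 = va / na + vb / nb
        se = float(np.sqrt(se2))
        if se2 > 0:
            df = se2**2 / (
                (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
            )
        else:
            df = na + nb - 2
        pooled_sd = float(np.sqrt((va + vb) / 2.0))

    if se == 0:
        if mean_diff == 0:
            return TwoSampleTest(0.0, df, 1.0, mean_diff, pooled_sd)
        t_stat = float(np.inf) if mean_diff > 0 else float(-np.inf)
        return TwoSampleTest(
            t_stat, df, 0.0, mean_diff, pooled_sd, flags=("infinite_t",)
        )
    t_stat = mean_diff / se
    p = 2.0 * float(sps.t.sf(abs(t_stat), df))
    return TwoSampleTest(float(t_stat), df, p, mean_diff, pooled_sd)


@dataclass(frozen=True)
class ReplicateSummary:
    """Mean +/- SEM of biological replicates (SEM missing at n = 1)."""

    mean: float
    sem: float | None
    n: int


def summarize_replicates(values: Sequence[float] | np.ndarray) -> ReplicateSummary:
    """Mean and standard error (sample sd / sqrt(n)) of replicate values."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    n = int(v.size)
    if n < 1:
        raise ValueError("need at least one finite value")
    sem = float(v.std(ddof=1) / np.sqrt(n)) if n > 1 else None
    return ReplicateSummary(mean=float(v.mean()), sem=sem, n=n)
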