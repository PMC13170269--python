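"""Viable-count estimation, kill-curve fitting, and death-only growth.

Spot-plating data (colony counts at known dilution and plated volume) are
converted to CFU/mL, summarized as survival fractions, and optionally fitted
with a log-linear inactivation model with an optional shoulder (a duration
before death begins).  The death-only expectation answers the question "what
would the post-shock growth curve look like if heat killed a fraction
``1 - S`` of cells and did nothing else?": the surviving inoculum ``S * od0``
grows under the untreated strain's fitted exponential law, which delays the
apparent lag by exactly ``t_d * log2(1/S)`` doublings-worth of time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .growth import (
    OD_FLOOR,
    GrowthCurve,
    GrowthFit,
    UndefinedLagError,
    estimate_lag,
)

__all__ = [
    "CfuObservation",
    "KillCurvePoint",
    "SurvivalEstimate",
    "KillCurveFit",
    "DeathOnlyExpectation",
    "LagAttribution",
    "cfu_from_spot",
    "spot_detection_limit",
    "survival_fraction",
    "fit_kill_curve",
    "expected_growth_death_only",
    "lag_attribution",
]


def cfu_from_spot(
    colonies: int, dilution_factor: float, plated_volume_ul: float
) -> float:
    """Viable density (CFU/mL) from one spotted dilution.

    ``cfu/mL = colonies * dilution_factor * (1000 / plated_volume_ul)``.
    Zero colonies return 0.0; the corresponding detection limit is given by
    :func:`spot_detection_limit`.
    """
    if colonies < 0:
        raise ValueError("colonies must be nonnegative")
    if dilution_factor < 1:
        raise ValueError("dilution_factor must be >= 1")
    if plated_volume_ul <= 0:
        raise ValueError("plated_volume_ul must be positive")
    return colonies * dilution_factor * (1000.0 / plated_volume_ul)


def spot_detection_limit(dilution_factor: float, plated_volume_ul: float) -> float:
    """CFU/mL corresponding to a single colony at this dilution and volume."""
    return cfu_from_spot(1, dilution_factor, plated_volume_ul)


@dataclass
class KillCurvePoint:
    """One spot-plating observation at a given heat-shock duration."""

    duration_min: float
    colonies: int
    dilution_factor: float
    plated_volume_ul: float
    replicate: int = 1
    cfu_per_ml: float = field(init=False)
    below_detection: bool = field(init=False)

    def __post_init__(self) -> None:
        if self.duration_min < 0:
            raise ValueError("duration_min must be nonnegative")
        self.cfu_per_ml = cfu_from_spot(
            self.colonies, self.dilution_factor, self.plated_volume_ul
        )
        self.below_detection = self.colonies == 0

    @property
    def detection_limit_cfu_per_ml(self) -> float:
        return spot_detection_limit(self.dilution_factor, self.plated_volume_ul)


@dataclass(frozen=True)
class CfuObservation:
    """A bare (duration, viable density) observation.

    :func:`fit_kill_curve` accepts any object exposing ``duration_min`` and
    ``cfu_per_ml``; this is the minimal such record, for callers that have
    densities rather than raw spot counts.
    """

    duration_min: float
    cfu_per_ml: float


@dataclass
class SurvivalEstimate:
    """Survival fraction S = CFU_after / CFU_before, with replicate SEM.

    S > 1 is retained (counting noise can push the ratio above one) but
    flagged, so downstream statistics see the raw value while simulations
    clamp it.
    """

    survival_fraction: float
    cfu_before: float
    cfu_after: float
    se: float | None
    n: int
    flags: tuple[str, ...] = ()

    @property
    def fold_loss(self) -> float:
        return 1.0 / self.survival_fraction


def survival_fraction(
    cfu_after: float | Sequence[float],
    cfu_before: float | Sequence[float],
) -> SurvivalEstimate:
    """Survival from paired before/after viable densities.

    Scalars give a single ratio; equal-length replicate vectors are paired,
    ratios computed per replicate, and summarized as mean +/- SEM.
    """
    after = np.atleast_1d(np.asarray(cfu_after, dtype=float))
    before = np.atleast_1d(np.asarray(cfu_before, dtype=float))
    if after.shape != before.shape:
        raise ValueError("cfu_after and cfu_before must pair up one-to-one")
    if np.any(before <= 0):
        raise ValueError("cfu_before must be positive")
    if np.any(after < 0):
        raise ValueError("cfu_after must be nonnegative")
    ratios = after / before
    n = int(ratios.size)
    s = float(ratios.mean())
    se = float(ratios.std(ddof=1) / np.sqrt(n)) if n > 1 else None
    flags = ("survival_gt_one",) if s > 1 else ()
    return SurvivalEstimate(
        survival_fraction=s,
        cfu_before=float(before.mean()),
        cfu_after=float(after.mean()),
        se=se,
        n=n,
        flags=flags,
    )


@dataclass
class KillCurveFit:
    """Log-linear inactivation fit with an optional shoulder.

    ``ln N(t)`` is flat at ``ln n0`` for ``t < shoulder_min`` and declines
    with slope ``-k_per_min`` for ``t >= shoulder_min``.
    """

    k_per_min: float
    shoulder_min: float
    n0_cfu_per_ml: float
    sse: float
    survival_by_duration: dict[float, float]
    n_used: int
    excluded: tuple[float, ...] = ()


def fit_kill_curve(points: Iterable[KillCurvePoint]) -> KillCurveFit:
    """Fit rate and shoulder by exhaustive breakpoint search.

    For each candidate shoulder ``s`` (every observed duration short of the
    longest), the continuous hinge model ``ln N(t) = ln n0 - k (t - s)_+``
    is fitted by OLS in its two parameters ``(ln n0, k)``; the breakpoint
    minimizing the residual sum of squares wins, ties going to the smallest
    shoulder, so a pure log-linear decline reports shoulder 0.  Zero-CFU
    points cannot enter the log fit and are excluded with a warning.
    """
    pts = list(points)
    usable = [p for p in pts if p.cfu_per_ml > 0]
    excluded = tuple(sorted({p.duration_min for p in pts if p.cfu_per_ml <= 0}))
    if excluded:
        warnings.warn(
            f"excluding zero-count kill-curve points at durations {excluded}",
            stacklevel=2,
        )
    t = np.array([p.duration_min for p in usable], dtype=float)
    y = np.log([p.cfu_per_ml for p in usable])
    durations = np.unique(t)
    if durations.size < 3:
        raise ValueError("need at least 3 distinct usable durations")
    if durations[0] != 0:
        raise ValueError("kill curve must include duration 0 (untreated)")

    best: tuple[float, float, float, float] | None = None  # sse, s, k, n0
    for s in durations[:-1]:
        hinge = np.maximum(t - s, 0.0)
        design = np.column_stack([np.ones_like(t), hinge])
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ beta
        sse = float(resid @ resid)
        if best is None or sse < best[0] - 1e-12:
            best = (sse, float(s), -float(beta[1]), float(np.exp(beta[0])))

    assert best is not None
    sse, shoulder, k, n0 = best

    mean_by_duration = {float(d): float(np.exp(y[t == d]).mean()) for d in durations}
    ref = mean_by_duration[0.0]
    survival = {d: v / ref for d, v in mean_by_duration.items()}
    return KillCurveFit(
        k_per_min=k,
        shoulder_min=shoulder,
        n0_cfu_per_ml=n0,
        sse=sse,
        survival_by_duration=survival,
        n_used=len(usable),
        excluded=excluded,
    )


@dataclass
class DeathOnlyExpectation:
    """Expected post-shock growth if killing were the only effect.

    ``lag_shift_h = doubling_time_h * log2(1/S)``: the surviving fraction
    needs exactly that many extra doubling times to regain the lost biomass,
    so the expected curve is the untreated curve delayed by ``lag_shift_h``
    throughout the exponential phase.
    """

    expected_curve: GrowthCurve
    lag_shift_h: float
    survival_used: float
    flags: tuple[str, ...] = ()


def expected_growth_death_only(
    reference_fit: GrowthFit,
    reference_curve: GrowthCurve,
    survival: float,
) -> DeathOnlyExpectation:
    """Simulate growth of the surviving inoculum under the untreated law.

    The expectation sits at ``S * od_start`` through the untreated lag, then
    grows exponentially at the untreated ``mu_max``, capped at the reference
    curve's plateau (killing does not change carrying capacity).  Survival
    values above 1 are clamped to 1 with a warning; the raw value is kept in
    ``survival_used``'s flag trail.
    """
    if survival <= 0:
        raise ValueError("survival must be positive")
    flags: tuple[str, ...] = ()
    s = float(survival)
    if s > 1:
        warnings.warn(
            f"survival {s:g} > 1 clamped to 1 for the death-only simulation",
            stacklevel=2,
        )
        s = 1.0
        flags = ("survival_clamped",)
    if not reference_fit.is_growth:
        raise UndefinedLagError(
            "death-only expectation needs a reference fit with mu_max > 0"
        )
    lag = (
        reference_fit.lag_h
        if reference_fit.lag_h is not None
        else estimate_lag(reference_fit, reference_curve)
    )
    mu = reference_fit.mu_max_per_h
    od_start = float(reference_curve.od[0])
    plateau = float(reference_curve.od.max())
    t = reference_curve.time_h
    grow = s * od_start * np.exp(mu * np.maximum(t - lag, 0.0))
    od = np.maximum(np.minimum(grow, plateau), OD_FLOOR)
    lag_shift = reference_fit.doubling_time_h * float(np.log2(1.0 / s))
    curve = GrowthCurve(
        time_h=t.copy(),
        od=od,
        meta=reference_curve.meta,
        blank_od_applied=reference_curve.blank_od_applied,
    )
    return DeathOnlyExpectation(
        expected_curve=curve,
        lag_shift_h=lag_shift,
        survival_used=s,
        flags=flags,
    )


@dataclass
class LagAttribution:
    """Split of an observed lag increase into killing vs everything else."""

    death_component_h: float
    unexplained_component_h: float


def lag_attribution(
    observed_lag_shift_h: float,
    survival: float,
    doubling_time_h: float,
) -> LagAttribution:
    """Partition an observed lag shift into the death-only component and the rest.

    The death component is ``t_d * log2(1/S)``; whatever remains is
    physiological recovery (damage repair, stress response) and may be
    negative, which is reported as-is.
    """
    if doubling_time_h <= 0:
        raise ValueError("doubling_time_h must be positive")
    if not 0 < survival <= 1:
        raise ValueError("survival must lie in (0, 1]")
    death = doubling_time_h * float(np.log2(1.0 / survival))
    return LagAttribution(
        death_component_h=death,
        unexplained_component_h=observed_lag_shift_h - death,
    )
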