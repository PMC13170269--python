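"""Growth-curve kinetics from optical-density (OD) time series.

The central quantities are the maximum specific growth rate ``mu_max``, the
lag time ``lambda``, and the time to reach a fixed OD threshold.  ``mu_max``
is estimated by a sliding-window log-linear fit: among all contiguous sample
windows spanning at least ``min_window_h`` hours whose end lies at least
``min_elapsed_h`` hours after the first sample, the window with the largest
ordinary-least-squares slope of ln(OD) on time defines the maximum growth
rate.  Extrapolating that fitted line back to the starting OD gives the lag
time, and the doubling time is ``ln 2 / mu_max``.

No parametric whole-curve model (Gompertz, Baranyi, Richards) is assumed by
the fitting procedure; the logistic kernel in :func:`logistic_od` exists only
as a simulation primitive for generating curves with known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "OD_FLOOR",
    "CurveMeta",
    "GrowthCurve",
    "GrowthFit",
    "DegenerateCurveError",
    "NoWindowError",
    "UndefinedLagError",
    "ThresholdNotReachedError",
    "logistic_od",
    "preprocess",
    "fit_max_growth_rate",
    "estimate_lag",
    "fit_growth",
    "time_to_threshold",
]

#: Floor applied to blank-subtracted OD values; keeps ln(OD) finite.
OD_FLOOR = 1e-4

_LN2 = float(np.log(2.0))
_TIME_TOL = 1e-9


class DegenerateCurveError(ValueError):
    """Raised when a curve carries no usable signal (all values at floor)."""


class NoWindowError(ValueError):
    """Raised when no contiguous window satisfies the span/elapsed rules."""


class UndefinedLagError(ValueError):
    """Raised when lag is requested for a fit with non-positive growth rate."""


class ThresholdNotReachedError(ValueError):
    """Raised when a curve never attains the requested OD threshold.

    Carries ``max_od``, the largest OD the curve reached, so callers can
    report the shortfall and mark the derived performance as missing.
    """

    def __init__(self, message: str, max_od: float):
        super().__init__(message)
        self.max_od = float(max_od)


@dataclass(frozen=True)
class CurveMeta:
    """Plate-map metadata for one well."""

    well: str = ""
    strain: str = ""
    condition: str = ""
    replicate: int = 1
    carbon_source: str = "methanol"


@dataclass
class GrowthCurve:
    """One well's OD-vs-time trace.

    ``time_h`` must be strictly increasing and nonnegative; ``od`` is the raw
    or blank-subtracted optical density.  ``blank_od_applied`` records the
    blank already subtracted by :func:`preprocess` (0 for raw curves).
    """

    time_h: np.ndarray
    od: np.ndarray
    meta: CurveMeta = field(default_factory=CurveMeta)
    blank_od_applied: float = 0.0

    def __post_init__(self) -> None:
        self.time_h = np.asarray(self.time_h, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        if self.time_h.ndim != 1 or self.time_h.shape != self.od.shape:
            raise ValueError("time_h and od must be 1-D arrays of equal length")
        if self.time_h.size < 2:
            raise ValueError("a growth curve needs at least two samples")
        if np.any(self.time_h < 0):
            raise ValueError("time grid must be nonnegative")
        if np.any(np.diff(self.time_h) <= 0):
            raise ValueError("time grid must be strictly increasing")
        if not np.all(np.isfinite(self.od)):
            raise ValueError("od contains non-finite values")

    def __len__(self) -> int:
        return int(self.time_h.size)

    @property
    def duration_h(self) -> float:
        return float(self.time_h[-1] - self.time_h[0])


@dataclass
class GrowthFit:
    """Result of the max-slope-window fit for one curve.

    ``mu_max_per_h`` may be non-positive for non-growing curves, in which
    case the ``"non_growth"`` flag is set, ``doubling_time_h`` is infinite
    and the lag is undefined.  ``intercept_ln_od`` is the intercept of the
    fitted ln(OD)-vs-time line, used for the lag extrapolation.
    """

    mu_max_per_h: float
    doubling_time_h: float
    intercept_ln_od: float
    window_start_h: float
    window_end_h: float
    window_r2: float
    n_window: int
    lag_h: float | None = None
    flags: tuple[str, ...] = ()

    @property
    def is_growth(self) -> bool:
        return self.mu_max_per_h > 0


def logistic_od(
    times: Sequence[float] | np.ndarray,
    *,
    od_baseline: float,
    od_inoculum: float,
    lag_h: float,
    mu_per_h: float,
    capacity_od: float,
) -> np.ndarray:
    """Noiseless three-phase growth law: flat lag, then logistic growth.

    For ``t < lag_h`` the biomass sits at ``od_inoculum`` above baseline;
    afterwards it follows the logistic solution with rate ``mu_per_h`` and
    carrying capacity ``capacity_od`` (both above baseline).  Written in the
    ``K / (1 + ((K - x0)/x0) e^{-mu dt})`` form to avoid overflow at large
    ``mu * dt``.
    """
    t = np.asarray(times, dtype=float)
    if od_inoculum <= 0:
        raise ValueError("od_inoculum must be positive")
    if capacity_od <= od_inoculum:
        raise ValueError("capacity_od must exceed od_inoculum")
    if mu_per_h < 0 or lag_h < 0:
        raise ValueError("mu_per_h and lag_h must be nonnegative")
    dt = np.maximum(t - lag_h, 0.0)
    x0, cap = float(od_inoculum), float(capacity_od)
    x = cap / (1.0 + ((cap - x0) / x0) * np.exp(-mu_per_h * dt))
    return od_baseline + x


def preprocess(curve: GrowthCurve, blank_od: float = 0.0) -> GrowthCurve:
    """Subtract the blank OD and floor the result at :data:`OD_FLOOR`.

    Raises :class:`DegenerateCurveError` if every point ends up at the floor
    (no signal above blank anywhere).
    """
    if blank_od < 0:
        raise ValueError("blank_od must be nonnegative")
    od = np.maximum(curve.od - blank_od, OD_FLOOR)
    if np.all(od <= OD_FLOOR):
        raise DegenerateCurveError(
            f"well {curve.meta.well or '<unnamed>'}: all OD values at or below "
            f"the floor after subtracting blank {blank_od:g}"
        )
    return GrowthCurve(
        time_h=curve.time_h.copy(),
        od=od,
        meta=curve.meta,
        blank_od_applied=curve.blank_od_applied + float(blank_od),
    )


def _window_sums(values: np.ndarray) -> np.ndarray:
    return np.concatenate([[0.0], np.cumsum(values)])


def fit_max_growth_rate(
    curve: GrowthCurve,
    min_window_h: float = 3.0,
    min_elapsed_h: float = 6.0,
    min_window_r2: float = 0.95,
) -> GrowthFit:
    """Find the contiguous window with the steepest ln(OD)-vs-time slope.

    Every contiguous run of samples spanning at least ``min_window_h`` hours
    and ending at least ``min_elapsed_h`` hours after the first sample is
    fitted by ordinary least squares in ln(OD) space; the largest slope is
    the maximum growth rate.  Ties (within a 1e-9 relative tolerance) are
    broken by earliest window start, then shortest span, which makes the
    result deterministic on noiseless single-phase curves.

    Windows whose log-linear fit has R-squared below ``min_window_r2`` are
    disqualified: near the detection limit, read noise in log space can
    produce steep but meaningless slopes, and a genuine exponential window
    is close to perfectly log-linear.  If no admissible window qualifies
    (e.g. a non-growing well) the quality gate is dropped.  Set
    ``min_window_r2=0`` to disable it.

    A non-positive maximum slope is reported with the ``"non_growth"`` flag
    rather than raised.
    """
    t = curve.time_h
    y = np.log(curve.od)
    n = t.size
    if n < 4:
        raise NoWindowError("need at least 4 samples to fit a window")
    if t[-1] - t[0] + _TIME_TOL < min_elapsed_h:
        raise NoWindowError(
            f"curve spans {t[-1] - t[0]:g} h but windows must end at least "
            f"{min_elapsed_h:g} h after the first sample"
        )

    i_all, j_all = np.triu_indices(n, k=1)
    span = t[j_all] - t[i_all]
    admissible = (span + _TIME_TOL >= min_window_h) & (
        t[j_all] + _TIME_TOL >= t[0] + min_elapsed_h
    )
    if not np.any(admissible):
        raise NoWindowError(
            f"no contiguous window spans at least {min_window_h:g} h and ends "
            f"at least {min_elapsed_h:g} h after the first sample"
        )
    i = i_all[admissible]
    j = j_all[admissible]
    span = span[admissible]

    cs_t = _window_sums(t)
    cs_y = _window_sums(y)
    cs_tt = _window_sums(t * t)
    cs_ty = _window_sums(t * y)
    cs_yy = _window_sums(y * y)

    m = (j - i + 1).astype(float)
    s_t = cs_t[j + 1] - cs_t[i]
    s_y = cs_y[j + 1] - cs_y[i]
    s_tt = cs_tt[j + 1] - cs_tt[i]
    s_ty = cs_ty[j + 1] - cs_ty[i]
    s_yy = cs_yy[j + 1] - cs_yy[i]

    var_t = m * s_tt - s_t * s_t
    var_y = m * s_yy - s_y * s_y
    cov_ty = m * s_ty - s_t * s_y
    slope = cov_ty / var_t
    with np.errstate(divide="ignore", invalid="ignore"):
        r2_all = np.where(
            var_y > 1e-300, cov_ty**2 / (var_t * var_y), 1.0
        )

    qualified = r2_all >= min_window_r2
    pool = np.flatnonzero(qualified) if np.any(qualified) else np.arange(slope.size)
    best = float(slope[pool].max())
    tol = 1e-9 * max(1.0, abs(best))
    cand = pool[slope[pool] >= best - tol]
    order = np.lexsort((span[cand], t[i[cand]]))
    pick = int(cand[order[0]])

    mu = float(slope[pick])
    intercept = float((s_y[pick] - slope[pick] * s_t[pick]) / m[pick])
    r2 = float(min(max(r2_all[pick], 0.0), 1.0))

    flags: tuple[str, ...] = () if mu > 0 else ("non_growth",)
    return GrowthFit(
        mu_max_per_h=mu,
        doubling_time_h=_LN2 / mu if mu > 0 else float("inf"),
        intercept_ln_od=intercept,
        window_start_h=float(t[i[pick]]),
        window_end_h=float(t[j[pick]]),
        window_r2=r2,
        n_window=int(m[pick]),
        flags=flags,
    )


def estimate_lag(fit: GrowthFit, curve: GrowthCurve) -> float:
    """Lag time from extrapolating the max-slope line to the starting OD.

    The fitted line ``ln OD = intercept + mu t`` intersects the starting OD
    at ``t = (ln od_start - intercept) / mu``.  Negative lags are reported
    as-is: clamping them would bias comparisons between fast- and
    slow-starting strains.
    """
    if not fit.is_growth:
        raise UndefinedLagError("lag is undefined when mu_max <= 0")
    od_start = float(curve.od[0])
    return (np.log(od_start) - fit.intercept_ln_od) / fit.mu_max_per_h


def fit_growth(
    curve: GrowthCurve,
    min_window_h: float = 3.0,
    min_elapsed_h: float = 6.0,
    min_window_r2: float = 0.95,
) -> GrowthFit:
    """Convenience wrapper: max-slope fit with the lag filled in."""
    fit = fit_max_growth_rate(curve, min_window_h, min_elapsed_h, min_window_r2)
    if fit.is_growth:
        return replace(fit, lag_h=estimate_lag(fit, curve))
    return replace(fit, flags=fit.flags + ("lag_undefined",))


def time_to_threshold(
    curve: GrowthCurve,
    od_threshold: float,
    interpolation: str = "log-linear",
) -> float:
    """First time the curve reaches ``od_threshold``.

    An exact sample hit returns that sample's time; otherwise the crossing is
    interpolated between the bracketing samples, by default linearly in
    ln(OD) vs time (exact for exponential growth through the crossing).
    ``interpolation="linear"`` switches to plain linear-OD interpolation for
    sensitivity checks.
    """
    if interpolation not in ("log-linear", "linear"):
        raise ValueError(f"unknown interpolation mode {interpolation!r}")
    if od_threshold <= 0:
        raise ValueError("od_threshold must be positive")
    od = curve.od
    if od[0] > od_threshold:
        raise ValueError(
            f"threshold {od_threshold:g} lies below the initial OD {od[0]:g}"
        )
    reached = np.flatnonzero(od >= od_threshold)
    if reached.size == 0:
        raise ThresholdNotReachedError(
            f"threshold {od_threshold:g} never reached (max OD {od.max():g})",
            max_od=od.max(),
        )
    k = int(reached[0])
    if od[k] == od_threshold or k == 0:
        return float(curve.time_h[k])
    t0, t1 = curve.time_h[k - 1], curve.time_h[k]
    if interpolation == "log-linear":
        frac = (np.log(od_threshold) - np.log(od[k - 1])) / (
            np.log(od[k]) - np.log(od[k - 1])
        )
    else:
        frac = (od_threshold - od[k - 1]) / (od[k] - od[k - 1])
    return float(t0 + frac * (t1 - t0))
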