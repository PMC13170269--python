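"""Synthetic plate-reader and spot-plating data with known ground truth.

Three generators stand in for the wet-lab inputs so every pipeline stage can
be validated end to end:

* :func:`simulate_growth_curve` - three-phase OD curves (flat lag,
  logistic growth, saturation) with additive Gaussian read noise;
* :func:`simulate_kill_curve` - log-linear inactivation with an optional
  shoulder, optionally Poisson-sampled into spot-plating colony counts;
* :func:`generate_tradeoff_cohort` - a cohort of strains whose heat-shock
  and elevated-temperature performances lie on a prescribed line with
  Gaussian scatter, realized as growth curves in three regimes whose
  times-to-threshold encode those performances exactly (up to grid
  interpolation).

Lag is implemented as a hard time shift and performance is embedded by
shifting lag at fixed growth rate, so ground truth is unambiguous for
recovery tests.  All randomness flows from one seeded generator per call.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import io as tlio
from .growth import OD_FLOOR, CurveMeta, GrowthCurve, logistic_od
from .viability import KillCurvePoint

__all__ = [
    "GrowthModelParams",
    "KillModelParams",
    "TradeoffCohortParams",
    "SimulatedKillCurve",
    "CohortStrain",
    "TradeoffCohort",
    "simulate_growth_curve",
    "default_time_grid",
    "simulate_kill_curve",
    "generate_tradeoff_cohort",
    "write_plate_tables",
]

#: Smallest performance a cohort strain can be assigned after noise.
PERFORMANCE_FLOOR = 0.05


@dataclass(frozen=True)
class GrowthModelParams:
    """Ground-truth parameters of one simulated growth curve.

    Defaults emulate an untreated methylotroph culture at its growth
    optimum: a short lag, a ~3.3 h doubling time (mu = 0.21 per hour), a
    plateau near OD 1, and plate-reader noise of a few milli-OD.
    """

    od_baseline: float = 0.04
    od_inoculum: float = 0.01
    lag_h: float = 1.0
    mu_per_h: float = 0.21
    capacity_od: float = 1.0
    noise_sd: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if self.od_inoculum <= 0:
            raise ValueError("od_inoculum must be positive")
        if self.capacity_od <= self.od_inoculum:
            raise ValueError("capacity_od must exceed od_inoculum")
        if self.mu_per_h < 0 or self.lag_h < 0 or self.noise_sd < 0:
            raise ValueError("mu_per_h, lag_h and noise_sd must be nonnegative")
        if self.od_baseline < 0:
            raise ValueError("od_baseline must be nonnegative")


def default_time_grid(duration_h: float = 48.0, dt_h: float = 0.25) -> np.ndarray:
    """Sampling grid of a typical multi-day plate-reader run (15-min reads)."""
    n = int(round(duration_h / dt_h))
    return np.linspace(0.0, n * dt_h, n + 1)


def simulate_growth_curve(
    params: GrowthModelParams,
    times: Sequence[float] | np.ndarray,
    meta: CurveMeta = CurveMeta(),
    rng: np.random.Generator | None = None,
) -> GrowthCurve:
    """One noisy OD trace on the given ascending hour grid.

    The mean follows :func:`thermolag.growth.logistic_od`; additive Gaussian
    noise with sd ``noise_sd`` is applied and the result floored at
    :data:`thermolag.growth.OD_FLOOR`.  Deterministic given ``params.seed``
    (or the supplied generator).
    """
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or t.size < 2:
        raise ValueError("times must be a 1-D grid with at least two points")
    if np.any(t < 0) or np.any(np.diff(t) <= 0):
        raise ValueError("times must be nonnegative and strictly increasing")
    mean = logistic_od(
        t,
        od_baseline=params.od_baseline,
        od_inoculum=params.od_inoculum,
        lag_h=params.lag_h,
        mu_per_h=params.mu_per_h,
        capacity_od=params.capacity_od,
    )
    if params.noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(params.seed)
        od = mean + rng.normal(0.0, params.noise_sd, size=t.size)
    else:
        od = mean
    return GrowthCurve(time_h=t, od=np.maximum(od, OD_FLOOR), meta=meta)


@dataclass(frozen=True)
class KillModelParams:
    """Ground truth for a heat-shock inactivation curve.

    Defaults emulate a stationary-phase culture near 1e9 CFU/mL whose
    viability halves in roughly 5-6 min at the lethal temperature.
    """

    n0_cfu_per_ml: float = 1e9
    shoulder_min: float = 0.0
    k_per_min: float = 0.12
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n0_cfu_per_ml <= 0:
            raise ValueError("n0_cfu_per_ml must be positive")
        if self.shoulder_min < 0 or self.k_per_min < 0:
            raise ValueError("shoulder_min and k_per_min must be nonnegative")


@dataclass
class SimulatedKillCurve:
    """True viable densities per duration, plus optional sampled spot counts."""

    durations_min: np.ndarray
    cfu_per_ml: np.ndarray
    points: list[KillCurvePoint] = field(default_factory=list)
    seed: int = 0


def kill_mean_cfu(params: KillModelParams, durations: np.ndarray) -> np.ndarray:
    """Mean viable density: flat until the shoulder, exponential decay after."""
    excess = np.maximum(durations - params.shoulder_min, 0.0)
    return params.n0_cfu_per_ml * np.exp(-params.k_per_min * excess)


def simulate_kill_curve(
    params: KillModelParams,
    durations: Sequence[float] | np.ndarray,
    dilution_factors: Sequence[float] | float | None = None,
    plated_volume_ul: float = 10.0,
    n_replicates: int = 3,
) -> SimulatedKillCurve:
    """Viable counts over heat-shock durations, optionally spot-sampled.

    With ``dilution_factors`` given (scalar, or one per duration), colony
    counts are Poisson draws of the expected colonies per spot,
    ``cfu/mL * plated_volume / dilution``, for each of ``n_replicates``
    replicates.  Deterministic given ``params.seed``.
    """
    d = np.asarray(durations, dtype=float)
    if np.any(d < 0):
        raise ValueError("durations must be nonnegative")
    mean = kill_mean_cfu(params, d)
    result = SimulatedKillCurve(
        durations_min=d, cfu_per_ml=mean, seed=params.seed
    )
    if dilution_factors is None:
        return result
    dilutions = np.broadcast_to(
        np.asarray(dilution_factors, dtype=float), d.shape
    )
    rng = np.random.default_rng(params.seed)
    for duration, cfu, dilution in zip(d, mean, dilutions):
        expected = cfu / dilution * (plated_volume_ul / 1000.0)
        for rep in range(1, n_replicates + 1):
            result.points.append(
                KillCurvePoint(
                    duration_min=float(duration),
                    colonies=int(rng.poisson(expected)),
                    dilution_factor=float(dilution),
                    plated_volume_ul=plated_volume_ul,
                    replicate=rep,
                )
            )
    return result


@dataclass(frozen=True)
class TradeoffCohortParams:
    """Ground truth for a cohort with a prescribed performance tradeoff.

    Heat-shock performances P_HS are uniform on [phs_low, phs_high]; the
    elevated-temperature performance is ``P_35 = beta0 + beta1 * P_HS``
    plus Gaussian scatter, floored at a small positive value.  Each strain
    gets growth curves in three regimes (reference 30 degC, 35 degC,
    post-shock 30 degC) built from a shared logistic kernel whose lag is
    shifted so the time-to-threshold equals ``t_ref_h / P``.

    Defaults emulate the evolved-isolate cohort: 14 strains, slope -2.5,
    three replicates, mu = 0.21 per hour, reference time-to-threshold 20 h.
    """

    n_strains: int = 14
    beta0: float = 2.2
    beta1: float = -2.5
    phs_low: float = 0.3
    phs_high: float = 0.7
    noise_sd: float = 0.05
    t_ref_h: float = 20.0
    seed: int = 0
    # Curve-shape parameters shared by every strain and regime.
    od_baseline: float = 0.05
    od_inoculum: float = 0.01
    mu_per_h: float = 0.21
    capacity_od: float = 1.0
    od_threshold: float = 0.1
    dt_h: float = 0.25
    od_noise_sd: float = 0.0
    n_replicates: int = 3

    def __post_init__(self) -> None:
        if self.n_strains < 3:
            raise ValueError("n_strains must be at least 3")
        if self.phs_low <= 0 or self.phs_high <= self.phs_low:
            raise ValueError("need 0 < phs_low < phs_high")
        if self.noise_sd < 0 or self.od_noise_sd < 0:
            raise ValueError("noise levels must be nonnegative")
        if self.t_ref_h <= 0:
            raise ValueError("t_ref_h must be positive")
        if not self.od_inoculum < self.od_threshold < self.capacity_od:
            raise ValueError(
                "od_threshold must lie between od_inoculum and capacity_od"
            )
        if self.mu_per_h <= 0:
            raise ValueError("mu_per_h must be positive")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be at least 1")


@dataclass
class CohortStrain:
    """Ground truth and simulated curves for one cohort member."""

    strain: str
    p_hs: float
    p_35: float
    t_ref_h: float
    t_hs_h: float
    t_35_h: float
    curves: list[GrowthCurve]


@dataclass
class TradeoffCohort:
    """A generated cohort plus its ground-truth sidecar."""

    params: TradeoffCohortParams
    strains: list[CohortStrain]
    od_threshold: float
    clamp_events: list[str] = field(default_factory=list)

    def curves(self) -> list[GrowthCurve]:
        return [c for s in self.strains for c in s.curves]

    def truth_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "strain": s.strain,
                    "p_hs": s.p_hs,
                    "p_35": s.p_35,
                    "t_ref_h": s.t_ref_h,
                    "t_hs_h": s.t_hs_h,
                    "t_35_h": s.t_35_h,
                }
                for s in self.strains
            ]
        )


def _time_to_threshold_from_lag_end(params: TradeoffCohortParams) -> float:
    """Closed-form time for the logistic kernel to climb from x0 to threshold."""
    x0, cap, thr = params.od_inoculum, params.capacity_od, params.od_threshold
    return float(
        np.log(thr * (cap - x0) / (x0 * (cap - thr))) / params.mu_per_h
    )


def generate_tradeoff_cohort(params: TradeoffCohortParams) -> TradeoffCohort:
    """Sample a cohort and realize its performances as growth curves.

    A performance P in regime x means time-to-threshold ``t_x = t_ref / P``;
    the curve's lag is set to ``t_x - tau`` where ``tau`` is the (closed
    form) climb time from inoculum to threshold.  Lags that would be
    negative are clamped to zero and logged, as are performance values
    pushed below the positive floor by noise.  Running the fitting pipeline
    on the emitted curves recovers each performance to within one grid
    interpolation step.
    """
    rng = np.random.default_rng(params.seed)
    p_hs = rng.uniform(params.phs_low, params.phs_high, params.n_strains)
    p_35 = params.beta0 + params.beta1 * p_hs + rng.normal(
        0.0, params.noise_sd, params.n_strains
    )
    clamp_events: list[str] = []
    for idx in np.flatnonzero(p_35 < PERFORMANCE_FLOOR):
        clamp_events.append(
            f"strain S{idx + 1:02d}: p_35 {p_35[idx]:.4f} clamped to "
            f"{PERFORMANCE_FLOOR}"
        )
    p_35 = np.maximum(p_35, PERFORMANCE_FLOOR)

    tau = _time_to_threshold_from_lag_end(params)
    conditions = {
        tlio.COND_REFERENCE: np.full(params.n_strains, params.t_ref_h),
        tlio.COND_HEATSHOCK: params.t_ref_h / p_hs,
        tlio.COND_ELEVATED: params.t_ref_h / p_35,
    }
    t_end = max(float(np.max(t)) for t in conditions.values()) + 6.0
    times = default_time_grid(duration_h=t_end, dt_h=params.dt_h)

    strains: list[CohortStrain] = []
    for idx in range(params.n_strains):
        name = f"S{idx + 1:02d}"
        curves: list[GrowthCurve] = []
        for condition, t_cond in conditions.items():
            lag = float(t_cond[idx]) - tau
            if lag < 0:
                clamp_events.append(
                    f"strain {name} {condition}: lag {lag:.3f} h clamped to 0"
                )
                lag = 0.0
            for rep in range(1, params.n_replicates + 1):
                gp = GrowthModelParams(
                    od_baseline=params.od_baseline,
                    od_inoculum=params.od_inoculum,
                    lag_h=lag,
                    mu_per_h=params.mu_per_h,
                    capacity_od=params.capacity_od,
                    noise_sd=params.od_noise_sd,
                    seed=params.seed,
                )
                curves.append(
                    simulate_growth_curve(
                        gp,
                        times,
                        meta=CurveMeta(
                            strain=name,
                            condition=condition,
                            replicate=rep,
                        ),
                        rng=rng,
                    )
                )
        strains.append(
            CohortStrain(
                strain=name,
                p_hs=float(p_hs[idx]),
                p_35=float(p_35[idx]),
                t_ref_h=float(conditions[tlio.COND_REFERENCE][idx]),
                t_hs_h=float(conditions[tlio.COND_HEATSHOCK][idx]),
                t_35_h=float(conditions[tlio.COND_ELEVATED][idx]),
                curves=curves,
            )
        )
    return TradeoffCohort(
        params=params,
        strains=strains,
        od_threshold=params.od_threshold,
        clamp_events=clamp_events,
    )


def _assign_wells(curves: Sequence[GrowthCurve]) -> list[GrowthCurve]:
    """Give unlabelled curves sequential well names (A1, B1, ... H1, A2, ...)."""
    out = []
    for idx, curve in enumerate(curves):
        meta = curve.meta
        if not meta.well:
            well = f"{chr(ord('A') + idx % 8)}{idx // 8 + 1}"
            meta = CurveMeta(
                well=well,
                strain=meta.strain,
                condition=meta.condition,
                replicate=meta.replicate,
                carbon_source=meta.carbon_source,
            )
        out.append(
            GrowthCurve(
                time_h=curve.time_h,
                od=curve.od,
                meta=meta,
                blank_od_applied=curve.blank_od_applied,
            )
        )
    return out


def write_plate_tables(
    curves: Sequence[GrowthCurve],
    directory: str | os.PathLike,
    od_name: str = "od_long.csv",
    map_name: str = "plate_map.csv",
) -> tuple[Path, Path]:
    """Write curves as the OD CSV + plate-map CSV pair the pipeline reads.

    Curves without well labels are assigned sequential ones first.  The
    write/read round trip through :mod:`thermolag.io` is lossless up to
    CSV float formatting.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    od_path = directory / od_name
    map_path = directory / map_name
    tlio.write_curves(_assign_wells(curves), od_path, map_path)
    return od_path, map_path
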