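"""End-to-end pipeline stages over the table formats, plus run manifests.

Each ``run_*`` function reads the pipeline's plain-text inputs, executes one
analysis stage, writes its TSV outputs plus a ``manifest.json`` (config,
seed, input checksums, package version), and returns the result frames.
The CLI in :mod:`thermolag.cli` is a thin wrapper over these functions.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as tlio
from .growth import (
    DegenerateCurveError,
    GrowthCurve,
    NoWindowError,
    ThresholdNotReachedError,
    fit_growth,
    preprocess,
    time_to_threshold,
)
from .simulate import (
    GrowthModelParams,
    KillModelParams,
    TradeoffCohortParams,
    default_time_grid,
    generate_tradeoff_cohort,
    simulate_growth_curve,
    simulate_kill_curve,
    write_plate_tables,
)
from .stats import (
    compare_slopes_ancova,
    fit_tradeoff,
    performance,
    summarize_replicates,
)
from .transfer import (
    DILUTION_CONVENTION,
    TransferScheme,
    cumulative_generations,
    generations_per_cycle,
)
from .viability import (
    expected_growth_death_only,
    fit_kill_curve,
    lag_attribution,
    survival_fraction,
)

__all__ = [
    "PipelineConfig",
    "run_simulate",
    "run_fit",
    "run_performance",
    "run_tradeoff",
    "run_killcurve",
    "run_transfer",
]

logger = logging.getLogger("thermolag")


@dataclass
class PipelineConfig:
    """Run-wide settings shared by the pipeline stages.

    ``od_threshold`` is the (blank-subtracted) OD whose crossing time
    defines performance; left unset it defaults to half the median fitted
    plateau of the reference-condition wells, a mid-curve choice robust to
    plateau noise.  ``interpolation`` selects how the crossing is
    interpolated between samples.
    """

    od_threshold: float | None = None
    blank_od: float = 0.0
    min_window_h: float = 3.0
    min_elapsed_h: float = 6.0
    min_window_r2: float = 0.95
    reference_condition: str = tlio.COND_REFERENCE
    interpolation: str = "log-linear"
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.od_threshold is not None and self.od_threshold <= self.blank_od:
            if self.od_threshold <= 0:
                raise ValueError("od_threshold must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.interpolation not in ("log-linear", "linear"):
            raise ValueError("interpolation must be 'log-linear' or 'linear'")

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path: str | os.PathLike) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    out_dir: Path,
    config: PipelineConfig,
    inputs: dict[str, str | os.PathLike],
    extra: dict | None = None,
) -> Path:
    """Record config hash, seed, input checksums and version for the run."""
    from . import __version__

    config_dict = config.to_dict()
    config_hash = hashlib.sha256(
        json.dumps(config_dict, sort_keys=True).encode()
    ).hexdigest()
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": config_dict,
        "config_sha256": config_hash,
        "inputs": {name: _sha256(p) for name, p in inputs.items()},
    }
    if extra:
        manifest.update(extra)
    path = out_dir / "manifest.json"
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path


def _resolve_threshold(
    config: PipelineConfig, curves: list[GrowthCurve]
) -> float:
    if config.od_threshold is not None:
        return float(config.od_threshold)
    ref = [
        c for c in curves if c.meta.condition == config.reference_condition
    ]
    if not ref:
        raise ValueError(
            f"cannot auto-pick a threshold: no wells in reference condition "
            f"{config.reference_condition!r}"
        )
    plateau = float(np.median([c.od.max() for c in ref]))
    threshold = 0.5 * plateau
    logger.info(
        "auto threshold: half the median reference plateau = %.4g", threshold
    )
    return threshold


# ---------------------------------------------------------------------------
# simulate


def run_simulate(
    scenario: str,
    out_dir: str | os.PathLike,
    config: PipelineConfig | None = None,
    **overrides,
) -> dict[str, Path]:
    """Write synthetic inputs plus a ground-truth sidecar for a scenario.

    ``scenario`` is one of ``growth`` (a few replicate growth curves),
    ``killcurve`` (spot-plating counts over shock durations) or
    ``tradeoff-cohort`` (strains x regimes x replicates with a prescribed
    performance tradeoff).  ``overrides`` set fields of the scenario's
    parameter dataclass; the seed defaults to the config seed.
    """
    config = config or PipelineConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    overrides.setdefault("seed", config.seed)
    written: dict[str, Path] = {}

    if scenario == "growth":
        n_replicates = int(overrides.pop("n_replicates", 3))
        params = GrowthModelParams(**overrides)
        rng = np.random.default_rng(params.seed)
        times = default_time_grid()
        from .growth import CurveMeta

        curves = [
            simulate_growth_curve(
                params,
                times,
                meta=CurveMeta(
                    strain="WT", condition=tlio.COND_REFERENCE, replicate=rep
                ),
                rng=rng,
            )
            for rep in range(1, n_replicates + 1)
        ]
        od_path, map_path = write_plate_tables(curves, out)
        truth = pd.DataFrame([dataclasses.asdict(params)])
        truth_path = out / "truth_growth.tsv"
        truth.to_csv(truth_path, sep="\t", index=False)
        written = {"od": od_path, "map": map_path, "truth": truth_path}

    elif scenario == "killcurve":
        durations = overrides.pop("durations", [0.0, 1.0, 2.5, 5.0, 10.0, 15.0, 20.0])
        dilutions = overrides.pop("dilution_factors", 1e4)
        params = KillModelParams(**overrides)
        sim = simulate_kill_curve(params, durations, dilution_factors=dilutions)
        kill_path = out / "kill_counts.csv"
        tlio.write_kill_table(sim.points, kill_path)
        truth = pd.DataFrame(
            {
                "duration_min": sim.durations_min,
                "true_cfu_per_ml": sim.cfu_per_ml,
            }
        )
        truth["k_per_min"] = params.k_per_min
        truth["shoulder_min"] = params.shoulder_min
        truth_path = out / "truth_killcurve.tsv"
        truth.to_csv(truth_path, sep="\t", index=False)
        written = {"kill": kill_path, "truth": truth_path}

    elif scenario == "tradeoff-cohort":
        params = TradeoffCohortParams(**overrides)
        cohort = generate_tradeoff_cohort(params)
        od_path, map_path = write_plate_tables(cohort.curves(), out)
        truth_path = out / "truth_cohort.tsv"
        cohort.truth_table().to_csv(truth_path, sep="\t", index=False)
        for event in cohort.clamp_events:
            logger.warning("clamp: %s", event)
        written = {"od": od_path, "map": map_path, "truth": truth_path}

    else:
        raise ValueError(
            f"unknown scenario {scenario!r}; expected growth, killcurve or "
            "tradeoff-cohort"
        )

    write_manifest(out, config, {}, extra={"scenario": scenario})
    return written


# ---------------------------------------------------------------------------
# fit


def fit_wells(
    curves: list[GrowthCurve], config: PipelineConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-well growth fits and threshold crossings.

    Wells whose fit fails (degenerate signal, no admissible window) stay in
    the output with NaN estimates and a flag; wells that never reach the
    threshold get a NaN crossing with reason ``threshold_not_reached``.
    """
    threshold = _resolve_threshold(config, curves)
    fit_rows = []
    crossing_rows = []
    for curve in curves:
        meta = curve.meta
        base = {
            "well": meta.well,
            "strain": meta.strain,
            "condition": meta.condition,
            "replicate": meta.replicate,
        }
        try:
            pre = preprocess(curve, config.blank_od)
        except DegenerateCurveError as err:
            logger.warning("well %s: %s", meta.well, err)
            fit_rows.append({**base, "flags": "degenerate"})
            crossing_rows.append(
                {
                    **base,
                    "od_threshold": threshold,
                    "t_threshold_h": np.nan,
                    "reason": "degenerate",
                }
            )
            continue
        try:
            fit = fit_growth(
                pre, config.min_window_h, config.min_elapsed_h, config.min_window_r2
            )
            fit_rows.append(
                {
                    **base,
                    "mu_max_per_h": fit.mu_max_per_h,
                    "lag_h": fit.lag_h,
                    "doubling_time_h": fit.doubling_time_h,
                    "window_start_h": fit.window_start_h,
                    "window_end_h": fit.window_end_h,
                    "window_r2": fit.window_r2,
                    "flags": ";".join(fit.flags),
                }
            )
            if fit.flags:
                logger.warning(
                    "well %s flagged: %s", meta.well, ";".join(fit.flags)
                )
        except NoWindowError as err:
            logger.warning("well %s: %s", meta.well, err)
            fit_rows.append({**base, "flags": "no_window"})
        try:
            t_cross = time_to_threshold(pre, threshold, config.interpolation)
            crossing_rows.append(
                {
                    **base,
                    "od_threshold": threshold,
                    "t_threshold_h": t_cross,
                    "reason": "",
                }
            )
        except ThresholdNotReachedError as err:
            logger.warning("well %s: %s", meta.well, err)
            crossing_rows.append(
                {
                    **base,
                    "od_threshold": threshold,
                    "t_threshold_h": np.nan,
                    "reason": "threshold_not_reached",
                }
            )
    fit_columns = [
        "well",
        "strain",
        "condition",
        "replicate",
        "mu_max_per_h",
        "lag_h",
        "doubling_time_h",
        "window_start_h",
        "window_end_h",
        "window_r2",
        "flags",
    ]
    fits = pd.DataFrame(fit_rows).reindex(columns=fit_columns)
    crossings = pd.DataFrame(crossing_rows)
    return fits, crossings


def run_fit(
    od_csv: str | os.PathLike,
    map_csv: str | os.PathLike,
    out_dir: str | os.PathLike,
    config: PipelineConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fit every mapped well and write ``fits.tsv`` + ``crossings.tsv``."""
    config = config or PipelineConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    curves = tlio.read_curves(od_csv, map_csv)
    fits, crossings = fit_wells(curves, config)
    fits.to_csv(out / "fits.tsv", sep="\t", index=False)
    crossings.to_csv(out / "crossings.tsv", sep="\t", index=False)
    write_manifest(out, config, {"od": od_csv, "map": map_csv})
    return fits, crossings


# ---------------------------------------------------------------------------
# performance and tradeoff


def performance_from_crossings(
    crossings: pd.DataFrame, reference_condition: str = tlio.COND_REFERENCE
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-replicate and per-strain performance tables.

    Each replicate's crossing time in a non-reference condition is divided
    into the same replicate's reference time (ratio first, average after);
    per-strain summaries are mean +/- SEM over replicate performances.
    Strains lacking a reference crossing are excluded with a warning.
    """
    ref = crossings[crossings["condition"] == reference_condition]
    ref_times = ref.set_index(["strain", "replicate"])["t_threshold_h"]
    rows = []
    for row in crossings.itertuples():
        if row.condition == reference_condition:
            continue
        key = (row.strain, row.replicate)
        if key not in ref_times.index or not np.isfinite(ref_times[key]):
            logger.warning(
                "strain %s replicate %s: no reference crossing; excluded",
                row.strain,
                row.replicate,
            )
            continue
        record = performance(
            float(ref_times[key]),
            float(row.t_threshold_h)
            if np.isfinite(row.t_threshold_h)
            else None,
            strain=row.strain,
            condition=row.condition,
        )
        rows.append(
            {
                "strain": record.strain,
                "condition": record.condition,
                "replicate": row.replicate,
                "t_ref_h": record.t_ref_h,
                "t_cond_h": record.t_cond_h,
                "performance": record.performance,
                "reason": record.reason or "",
            }
        )
    per_replicate = pd.DataFrame(
        rows,
        columns=[
            "strain",
            "condition",
            "replicate",
            "t_ref_h",
            "t_cond_h",
            "performance",
            "reason",
        ],
    )
    summaries = []
    for (strain, condition), group in per_replicate.groupby(
        ["strain", "condition"], sort=True
    ):
        values = group["performance"].to_numpy(dtype=float)
        values = values[np.isfinite(values)]
        if values.size == 0:
            summaries.append(
                {
                    "strain": strain,
                    "condition": condition,
                    "performance_mean": np.nan,
                    "performance_sem": np.nan,
                    "n": 0,
                }
            )
            continue
        summary = summarize_replicates(values)
        summaries.append(
            {
                "strain": strain,
                "condition": condition,
                "performance_mean": summary.mean,
                "performance_sem": summary.sem if summary.sem is not None else np.nan,
                "n": summary.n,
            }
        )
    per_strain = pd.DataFrame(
        summaries,
        columns=["strain", "condition", "performance_mean", "performance_sem", "n"],
    )
    return per_replicate, per_strain


def run_performance(
    crossings_tsv: str | os.PathLike,
    out_dir: str | os.PathLike,
    config: PipelineConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Compute performance tables from a crossings TSV."""
    config = config or PipelineConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    crossings = pd.read_csv(crossings_tsv, sep="\t")
    per_replicate, per_strain = performance_from_crossings(
        crossings, config.reference_condition
    )
    per_replicate.to_csv(out / "performance_replicates.tsv", sep="\t", index=False)
    per_strain.to_csv(out / "performance.tsv", sep="\t", index=False)
    write_manifest(out, config, {"crossings": crossings_tsv})
    return per_replicate, per_strain


def tradeoff_points(per_strain: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Per-strain (P_HS, P_35) pairs from the per-strain performance table."""
    wide = per_strain.pivot(
        index="strain", columns="condition", values="performance_mean"
    )
    for cond in (tlio.COND_HEATSHOCK, tlio.COND_ELEVATED):
        if cond not in wide.columns:
            raise ValueError(f"performance table lacks condition {cond!r}")
    return (
        wide[tlio.COND_HEATSHOCK].to_numpy(dtype=float),
        wide[tlio.COND_ELEVATED].to_numpy(dtype=float),
    )


def run_tradeoff(
    crossings_tsv: str | os.PathLike,
    out_dir: str | os.PathLike,
    config: PipelineConfig | None = None,
    crossings_tsv_b: str | os.PathLike | None = None,
) -> dict:
    """Fit the tradeoff line(s) and, with two cohorts, compare their slopes.

    Returns a dict with the per-cohort ``TradeoffFit`` values and, when a
    second crossings table is supplied, the ANCOVA ``SlopeComparison``.
    Writes ``tradeoff.tsv`` (one row per cohort) and ``ancova.tsv``.
    """
    config = config or PipelineConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    inputs: dict[str, str | os.PathLike] = {"crossings_a": crossings_tsv}
    cohorts = {"a": pd.read_csv(crossings_tsv, sep="\t")}
    if crossings_tsv_b is not None:
        cohorts["b"] = pd.read_csv(crossings_tsv_b, sep="\t")
        inputs["crossings_b"] = crossings_tsv_b

    points = {}
    fits = {}
    rows = []
    for label, crossings in cohorts.items():
        _, per_strain = performance_from_crossings(
            crossings, config.reference_condition
        )
        x, y = tradeoff_points(per_strain)
        points[label] = (x, y)
        fit = fit_tradeoff(x, y)
        fits[label] = fit
        rows.append(
            {
                "cohort": label,
                "slope": fit.slope,
                "intercept": fit.intercept,
                "r2": fit.r2,
                "n": fit.n,
            }
        )
    pd.DataFrame(rows).to_csv(out / "tradeoff.tsv", sep="\t", index=False)

    result: dict = {"fits": fits}
    if "b" in points:
        comparison = compare_slopes_ancova(points["a"], points["b"])
        result["ancova"] = comparison
        pd.DataFrame(
            [
                {
                    "slope_a": comparison.slope_a,
                    "slope_b": comparison.slope_b,
                    "interaction_estimate": comparison.interaction_estimate,
                    "t_statistic": comparison.statistic,
                    "df": comparison.df,
                    "p_value": comparison.p_value,
                    "significant_at_alpha": comparison.p_value < config.alpha,
                }
            ]
        ).to_csv(out / "ancova.tsv", sep="\t", index=False)
    write_manifest(out, config, inputs)
    return result


# ---------------------------------------------------------------------------
# kill curve


def run_killcurve(
    kill_csv: str | os.PathLike,
    out_dir: str | os.PathLike,
    config: PipelineConfig | None = None,
    od_csv: str | os.PathLike | None = None,
    map_csv: str | os.PathLike | None = None,
    reference_well: str | None = None,
    shock_duration_min: float = 5.0,
    observed_lag_shift_h: float | None = None,
) -> dict:
    """Survival per duration, inactivation fit, and the death-only expectation.

    Writes ``survival.tsv`` (mean CFU +/- SEM and survival per duration) and,
    when a reference growth curve is supplied, ``expected_curve.csv`` -- the
    growth expected after the shock if killing at ``shock_duration_min`` were
    its only effect -- plus a lag attribution when an observed post-shock lag
    shift is given.
    """
    config = config or PipelineConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    points = tlio.read_kill_table(kill_csv)
    durations = sorted({p.duration_min for p in points})
    if 0.0 not in durations:
        raise ValueError("kill-curve table must include duration 0 (untreated)")

    rows = []
    cfu_by_duration = {}
    for d in durations:
        cfus = np.array(
            [p.cfu_per_ml for p in points if p.duration_min == d], dtype=float
        )
        cfu_by_duration[d] = cfus
        summary = summarize_replicates(cfus)
        rows.append(
            {
                "duration_min": d,
                "cfu_per_ml_mean": summary.mean,
                "cfu_per_ml_sem": summary.sem if summary.sem is not None else np.nan,
                "n": summary.n,
            }
        )
    survival_table = pd.DataFrame(rows)
    before = cfu_by_duration[0.0]
    survivals = []
    for d in durations:
        after = cfu_by_duration[d]
        if after.size == before.size:
            est = survival_fraction(after, before)
        else:
            est = survival_fraction(after.mean(), before.mean())
        survivals.append(est.survival_fraction)
    survival_table["survival_fraction"] = survivals
    kill_fit = fit_kill_curve(points)
    survival_table.to_csv(out / "survival.tsv", sep="\t", index=False)

    result: dict = {"survival": survival_table, "kill_fit": kill_fit}
    inputs: dict[str, str | os.PathLike] = {"kill": kill_csv}

    if od_csv is not None and map_csv is not None:
        curves = tlio.read_curves(od_csv, map_csv)
        if reference_well is not None:
            matches = [c for c in curves if c.meta.well == reference_well]
            if not matches:
                raise ValueError(f"reference well {reference_well!r} not found")
            reference = matches[0]
        else:
            reference = curves[0]
        pre = preprocess(reference, config.blank_od)
        fit = fit_growth(
                pre, config.min_window_h, config.min_elapsed_h, config.min_window_r2
            )
        nearest = min(durations, key=lambda d: abs(d - shock_duration_min))
        s_shock = kill_fit.survival_by_duration.get(
            nearest, survivals[durations.index(nearest)]
        )
        expectation = expected_growth_death_only(fit, pre, s_shock)
        frame = pd.DataFrame(
            {
                "well": expectation.expected_curve.meta.well,
                "time_h": expectation.expected_curve.time_h,
                "od": expectation.expected_curve.od,
            }
        )
        frame.to_csv(out / "expected_curve.csv", index=False)
        result["expectation"] = expectation
        inputs["od"] = od_csv
        inputs["map"] = map_csv
        if observed_lag_shift_h is not None:
            attribution = lag_attribution(
                observed_lag_shift_h,
                min(expectation.survival_used, 1.0),
                fit.doubling_time_h,
            )
            result["lag_attribution"] = attribution
            pd.DataFrame(
                [
                    {
                        "observed_lag_shift_h": observed_lag_shift_h,
                        "death_component_h": attribution.death_component_h,
                        "unexplained_component_h": attribution.unexplained_component_h,
                    }
                ]
            ).to_csv(out / "lag_attribution.tsv", sep="\t", index=False)

    write_manifest(out, config, inputs)
    return result


# ---------------------------------------------------------------------------
# transfer


def run_transfer(
    scheme: TransferScheme,
    out_dir: str | os.PathLike,
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """One-row generation-accounting table for a serial-transfer scheme."""
    config = config or PipelineConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    per_cycle = generations_per_cycle(scheme)
    frame = pd.DataFrame(
        [
            {
                "v_fresh_ml": scheme.v_fresh_ml,
                "v_transfer_ul": scheme.v_transfer_ul,
                "survival": scheme.survival,
                "n_cycles": scheme.n_cycles,
                "dilution_convention": DILUTION_CONVENTION,
                "dilution_generations": per_cycle.dilution_generations,
                "killing_generations": per_cycle.killing_generations,
                "generations_per_cycle": per_cycle.total,
                "cumulative_generations": cumulative_generations(scheme),
            }
        ]
    )
    frame.to_csv(out / "generations.tsv", sep="\t", index=False)
    write_manifest(out, config, {})
    return frame
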