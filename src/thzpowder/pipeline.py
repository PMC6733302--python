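"""End-to-end driver: simulate → process → calibrate → predict → map →
correlate.

The pipeline reproduces the study protocol on synthetic data: for one
material, several independent runs each sweep the compaction stages;
every (run, stage) scan is reduced to a mean refractive index; the
pooled (n̄_p, ϱ̄_r) points fit one calibration line per material; the
fitted line predicts stage densities, which are correlated with
simulated off-line fill weights; finally a post-dosing scan is mapped
rotation-by-rotation and the dip-site segments located.

All randomness funnels through one seeded generator: the run seed
spawns per-stage scan seeds, caliper-noise seeds and weighing-noise
seeds, so identical configuration + seed reproduces byte-identical
outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as tio
from .calibration import CalibrationResults, DensityCalibration
from .mapping import (
    CorrelationResult,
    DensityMap,
    HoleSegment,
    angular_density_profile,
    build_density_map,
    correlate_density_weight,
    detect_hole_segments,
    stage_summary,
)
from .optics import (
    RING_HEIGHT_MM,
    SENSOR_BLOCK_HEIGHT_MM,
    invert_reflection,
    nominal_relative_density,
    average_fill_height,
)
from .signal import (
    AngularProfile,
    DEFAULT_DATUM_THRESHOLD,
    DEFAULT_FILTER_WINDOW,
    DEFAULT_MAX_ROTATIONS,
    DEFAULT_N_BINS,
    ReflectionSeries,
    Rotations,
    bin_angular,
    compute_reflection_series,
    detect_rotations,
    moving_average,
)
from .simulate import (
    DEFAULT_STAGE_PRESSURES,
    apply_dosing,
    make_density_field,
    synthesize_fill_weights,
    synthesize_scan,
)
from .specs import (
    ContainerGeometry,
    DensityField,
    DosingEvent,
    ScanConfig,
    geometric_hole_width,
    material_from_dict,
)

__all__ = [
    "PipelineError",
    "PipelineResult",
    "default_config",
    "run_pipeline",
    "process_scan",
]

DEFAULT_CALIPER_NOISE_SD_MM = 0.1


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def default_config(material: str = "Lactohale 200", seed: int = 1) -> dict:
    """Demo configuration mirroring the study conditions."""
    return {
        "material": {"name": material},
        "geometry": {},
        "scan": {
            "acquisition_rate": 15.0,
            # effective rate inferred from the acquisition covering about
            # 8.5 rotations in 133 s; the nominal motor setting is 4 rpm
            "rotation_speed": 3.83,
            "n_waveforms": 2000,
            "time_window": 45.0,
            "noise_sigma": 0.0015,
        },
        "stages": {
            "pressures": list(DEFAULT_STAGE_PRESSURES),
            "n_runs": 3,
            "heterogeneity_amp": 0.01,
        },
        "processing": {
            "filter_window": DEFAULT_FILTER_WINDOW,
            "datum_threshold": DEFAULT_DATUM_THRESHOLD,
            "n_bins": DEFAULT_N_BINS,
            "max_rotations": DEFAULT_MAX_ROTATIONS,
            "artifact_angles": [],
        },
        "dosing": {
            # "auto": refilled holes sit at the loose bulk-density ratio,
            # so the deficit is 1 - bulk_ratio / compacted-stage density
            "deficit": "auto",
            "hole_width": None,  # geometric default from dosator diameter
            "positions": None,  # eight evenly spaced sites
            "stage": "last",  # dose the bed after the final compression
            "depth_threshold": 0.015,  # above the heterogeneity amplitude
            "map_bins": DEFAULT_N_BINS,
        },
        "weights": {
            "dosator_diameter_mm": 3.4,
            "chamber_length_mm": 5.0,
            "efficiency": 1.5,
            "noise_sd_mg": 0.8,
        },
        "caliper_noise_sd_mm": DEFAULT_CALIPER_NOISE_SD_MM,
        "seed": seed,
    }


def process_scan(
    scan,
    reference,
    gate=None,
    filter_window: int = DEFAULT_FILTER_WINDOW,
    datum_threshold: float = DEFAULT_DATUM_THRESHOLD,
    n_bins: int = DEFAULT_N_BINS,
    max_rotations: int | None = DEFAULT_MAX_ROTATIONS,
    origin_deg: float = 0.0,
) -> tuple[ReflectionSeries, Rotations, AngularProfile]:
    """Raw scan → registered, filtered, angularly binned r-profile.

    Returns the reflection series (with datum mask and rotation ids),
    the detected rotations, and the per-bin mean reflection coefficient
    averaged over the first ``max_rotations`` complete rotations.
    """
    series = compute_reflection_series(scan, reference, gate=gate)
    rotations = detect_rotations(series, datum_threshold=datum_threshold)
    filtered = moving_average(series.r, window=filter_window,
                              mask=series.datum_mask)
    n_use = rotations.n_complete
    if max_rotations is not None:
        n_use = min(n_use, max_rotations)
    profile = bin_angular(series, rotations, n_bins=n_bins,
                          use_rotations=range(n_use), values=filtered,
                          origin_deg=origin_deg)
    return series, rotations, profile


@dataclass
class PipelineResult:
    """Everything one pipeline run produces."""

    material: str
    calibration: CalibrationResults
    calibration_points: pd.DataFrame  # run, stage, n_p_mean, rho_r_nominal
    predicted_densities: pd.DataFrame  # stage, rho_r_pred (run-averaged)
    weights: pd.DataFrame
    weight_summaries: pd.DataFrame  # stage, mean_mg, sd_mg, rsd_percent
    correlation: CorrelationResult
    density_profile: AngularProfile  # post-dosing, density units
    density_map: DensityMap
    hole_segments: list[HoleSegment]
    seed: int
    config: dict
    output_dir: Path | None = None


def _caliper_displacements(fill_height_mm: float, sd_mm: float,
                           rng: np.random.Generator) -> np.ndarray:
    stack = fill_height_mm + RING_HEIGHT_MM + SENSOR_BLOCK_HEIGHT_MM
    return stack + rng.normal(0.0, sd_mm, size=8)


def run_pipeline(config: dict, out_dir=None, seed: int | None = None
                 ) -> PipelineResult:
    """Execute the full synthetic study described by ``config``.

    Deterministic for a given (config, seed); any stage failure raises
    :class:`PipelineError` naming the stage.  When ``out_dir`` is given,
    all tables, the persisted model and a provenance record (config
    hash, seed) are written there.
    """
    cfg = dict(config)
    if seed is not None:
        cfg["seed"] = int(seed)
    root_seed = int(cfg.get("seed", 0))
    rng = np.random.default_rng(root_seed)

    def child_seed() -> int:
        return int(rng.integers(0, 2**31 - 1))

    stage_name = "configure"
    try:
        material = material_from_dict(cfg["material"])
        geometry = ContainerGeometry(**cfg.get("geometry", {}))
        scan_cfg = dict(cfg.get("scan", {}))
        stages_cfg = cfg.get("stages", {})
        proc = cfg.get("processing", {})
        dosing_cfg = cfg.get("dosing", {})
        weights_cfg = cfg.get("weights", {})
        pressures = list(stages_cfg.get("pressures", DEFAULT_STAGE_PRESSURES))
        n_runs = int(stages_cfg.get("n_runs", 3))
        het = float(stages_cfg.get("heterogeneity_amp", 0.01))
        caliper_sd = float(cfg.get("caliper_noise_sd_mm",
                                   DEFAULT_CALIPER_NOISE_SD_MM))
        proc_kwargs = dict(
            gate=tuple(proc["gate"]) if proc.get("gate") else None,
            filter_window=int(proc.get("filter_window", DEFAULT_FILTER_WINDOW)),
            datum_threshold=float(proc.get("datum_threshold",
                                           DEFAULT_DATUM_THRESHOLD)),
            n_bins=int(proc.get("n_bins", DEFAULT_N_BINS)),
            max_rotations=proc.get("max_rotations", DEFAULT_MAX_ROTATIONS),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise PipelineError(f"stage '{stage_name}' failed: {exc}") from exc

    def guard(name):
        stage = name

        class _Guard:
            def __enter__(self):
                return None

            def __exit__(self, exc_type, exc, tb):
                if exc is not None and not isinstance(exc, PipelineError):
                    raise PipelineError(
                        f"stage '{stage}' failed: {exc}") from exc
                return False

        return _Guard()

    # ---- simulate + process every (run, stage) scan -> calibration points
    points = []
    run_fields: list[list[DensityField]] = []
    with guard("simulate/process"):
        for run in range(n_runs):
            fields = make_density_field(
                material, geometry, stage_pressures=pressures,
                heterogeneity_amp=het, seed=child_seed())
            run_fields.append(fields)
            cal_rng = np.random.default_rng(child_seed())
            for s, field in enumerate(fields):
                sc = ScanConfig(**scan_cfg, seed=child_seed())
                scan, reference = synthesize_scan(field, material, geometry, sc)
                _, _, profile = process_scan(scan, reference, **proc_kwargs)
                np_profile = profile.map_values(
                    lambda v: invert_reflection(v, geometry.container_index))
                n_p_mean = np_profile.mean
                h_true = (1000.0 * material.mass
                          / (geometry.annulus_area_mm2 * field.mean
                             * material.true_density))
                disp = _caliper_displacements(h_true, caliper_sd, cal_rng)
                h_bar = average_fill_height(disp)
                rho_nominal = nominal_relative_density(
                    material.mass, geometry.annulus_area_mm2, h_bar,
                    material.true_density)
                points.append({"run": run, "stage": s, "n_p_mean": n_p_mean,
                               "rho_r_nominal": rho_nominal})
    points_df = pd.DataFrame(points)

    # ---- fit one calibration model per material (all runs pooled)
    with guard("calibrate"):
        results = DensityCalibration(
            points_df["n_p_mean"], points_df["rho_r_nominal"],
            material=material.name).fit()

    # ---- predict stage densities, run-averaged (equal weight per run)
    with guard("predict"):
        pred = (points_df.assign(
            rho_r_pred=results.predict(points_df["n_p_mean"].to_numpy(),
                                       warn_extrapolation=False))
            .groupby("stage", as_index=False)["rho_r_pred"].mean())

    # ---- synthetic off-line fill weights and per-stage summaries
    with guard("weights"):
        hole_width = dosing_cfg.get("hole_width") or geometric_hole_width(
            float(weights_cfg.get("dosator_diameter_mm", 3.4)), geometry)
        deficit_cfg = dosing_cfg.get("deficit", "auto")
        event_kwargs = dict(
            hole_density_deficit=(0.0 if deficit_cfg in (None, "auto")
                                  else float(deficit_cfg)),
            hole_width=float(hole_width))
        if dosing_cfg.get("positions"):
            event_kwargs["positions"] = np.asarray(dosing_cfg["positions"],
                                                   dtype=float)
        event = DosingEvent(**event_kwargs)
        weights = synthesize_fill_weights(
            run_fields[0], event, material,
            dosator_diameter_mm=float(weights_cfg.get("dosator_diameter_mm",
                                                      3.4)),
            chamber_length_mm=float(weights_cfg.get("chamber_length_mm", 5.0)),
            efficiency=float(weights_cfg.get("efficiency", 1.5)),
            weight_noise_sd_mg=float(weights_cfg.get("noise_sd_mg", 0.8)),
            seed=child_seed())
        summaries = []
        for s, grp in weights.groupby("stage", sort=True):
            summ = stage_summary(grp)
            summaries.append({"stage": s, "mean_mg": summ.mean_mg,
                              "sd_mg": summ.sd_mg,
                              "rsd_percent": summ.rsd_percent, "n": summ.n})
        summaries_df = pd.DataFrame(summaries)

    # ---- correlate predicted densities with mean fill weights
    with guard("correlate"):
        merged = pred.merge(summaries_df, on="stage")
        correlation = correlate_density_weight(
            merged["rho_r_pred"].to_numpy(), merged["mean_mg"].to_numpy(),
            material=material.name)

    # ---- post-dosing map, angular profile and hole segments
    with guard("map/holes"):
        stage_sel = dosing_cfg.get("stage", "last")
        if stage_sel in (None, "last"):
            stage_sel = len(run_fields[0]) - 1
        bed = run_fields[0][int(stage_sel)]
        if deficit_cfg in (None, "auto"):
            # refilled holes hold loose powder near the bulk-density ratio
            deficit = max(0.0, 1.0 - material.bulk_relative_density / bed.mean)
            event = dataclasses.replace(event, hole_density_deficit=deficit)
        dosed = apply_dosing(bed, event)
        sc = ScanConfig(**scan_cfg, seed=child_seed())
        scan, reference = synthesize_scan(dosed, material, geometry, sc)
        map_bins = int(dosing_cfg.get("map_bins", 225))
        series, rotations, _ = process_scan(
            scan, reference, **{**proc_kwargs, "n_bins": map_bins})
        filtered = moving_average(series.r,
                                  window=proc_kwargs["filter_window"],
                                  mask=series.datum_mask)
        artifact = [tuple(a) for a in proc.get("artifact_angles", [])]
        dmap = build_density_map(
            series, results, rotations,
            container_index=geometry.container_index, n_bins=map_bins,
            values=filtered, artifact_angles=artifact,
            origin_deg=geometry.datum_angle)
        profile = angular_density_profile(dmap)
        segments = detect_hole_segments(
            profile, depth_threshold=float(
                dosing_cfg.get("depth_threshold", 0.01)))

    result = PipelineResult(
        material=material.name,
        calibration=results,
        calibration_points=points_df,
        predicted_densities=pred,
        weights=weights,
        weight_summaries=summaries_df,
        correlation=correlation,
        density_profile=profile,
        density_map=dmap,
        hole_segments=segments,
        seed=root_seed,
        config=cfg,
        output_dir=Path(out_dir) if out_dir else None,
    )
    if out_dir:
        with guard("write-outputs"):
            _write_outputs(result, Path(out_dir), run_fields[0])
    return result


def _write_outputs(res: PipelineResult, out: Path,
                   truth_fields: list[DensityField]) -> None:
    out.mkdir(parents=True, exist_ok=True)
    tio.write_model_yaml(out / "calibration_model.yaml", res.calibration)
    res.calibration_points.to_csv(out / "calibration_points.csv", index=False)
    res.predicted_densities.to_csv(out / "predicted_densities.csv",
                                   index=False)
    tio.write_weights_csv(out / "fill_weights.csv", res.weights)
    res.weight_summaries.to_csv(out / "weight_summaries.csv", index=False)
    pd.DataFrame([dataclasses.asdict(s) for s in res.hole_segments]).to_csv(
        out / "hole_segments.csv", index=False)
    tio.write_profile_csv(out / "density_profile.csv", res.density_profile,
                          value_name="relative_density")
    tio.write_map_csv(out / "density_map.csv", res.density_map)
    tio.write_density_fields_csv(out / "ground_truth_fields.csv", truth_fields)
    corr = res.correlation
    pd.DataFrame(corr.stage_means,
                 columns=["rho_r_pred", "mean_weight_mg"]).assign(
        slope=corr.slope, intercept=corr.intercept,
        r_squared=corr.r_squared).to_csv(out / "correlation.csv", index=False)
    provenance = {
        "config_hash": tio.config_hash(res.config),
        "seed": res.seed,
        "material": res.material,
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2))
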