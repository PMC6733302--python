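"""Synthetic study generator.

Emulates the rotating-container reflection experiment end to end:
ground-truth angular density fields over a series of compaction stages,
the continuously acquired terahertz waveform sequence (with copper-datum
passages and additive amplitude noise), and the off-line capsule
fill-weight tables from eight dosator dip sites.

Forward model
-------------
* index–density law: ``n_p(θ) = 1 + (n_s − 1)·ϱ_r(θ)`` — the simplest
  effective-medium form that is linear in density, equals 1 in vacuum
  and the solid index ``n_s`` at full density;
* interface amplitude: Fresnel coefficient at the container/powder
  interface times the reference (copper) amplitude, plus iid Gaussian
  noise with sd ``noise_sigma`` in reflection-coefficient units;
* datum: measurements whose container angle falls on the copper strip
  return a near-total reflection of sign opposite to the powder
  interface;
* each trace is a scaled canonical single-cycle pulse (Ricker wavelet)
  on the 45 ps delay axis — the analysis only consumes the gated peak
  amplitude, so no propagation optics is modelled.

Compaction is a prescribed density increment per stage: the stage-mean
relative density relaxes exponentially in applied pressure from the
bulk-density ratio towards the tapped-density ratio.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .optics import fresnel_reflection
from .signal import ScanSequence, Waveform
from .specs import (
    ContainerGeometry,
    DensityField,
    DosingEvent,
    MaterialSpec,
    ScanConfig,
)

__all__ = [
    "make_density_field",
    "apply_dosing",
    "synthesize_scan",
    "synthesize_fill_weights",
    "ricker_pulse",
    "index_from_density",
    "density_from_index",
]

#: pressure scale (kPa) of the exponential compaction law
DEFAULT_PRESSURE_SCALE_KPA = 10.0
#: default stage pressures: five compression stages up to the 8 kPa
#: scale at which the excipients' compressibility is characterised
DEFAULT_STAGE_PRESSURES = (0.0, 2.0, 4.0, 6.0, 8.0)
#: dosator geometry of the static sampling tool
DEFAULT_DOSATOR_DIAMETER_MM = 3.4
DEFAULT_CHAMBER_LENGTH_MM = 5.0
#: fraction of the nominal chamber volume × bulk density actually
#: retained as the plug; >1 because the 1:2 pre-compression draws in
#: more than one chamber volume of loose powder
DEFAULT_FILL_EFFICIENCY = 1.5
DEFAULT_WEIGHT_NOISE_SD_MG = 0.8

_PULSE_CENTER_FRACTION = 0.5
_PULSE_WIDTH_PS = 0.8
_N_SAMPLES = 301


def index_from_density(relative_density, solid_index: float):
    """Effective refractive index from relative density (linear law)."""
    return 1.0 + (solid_index - 1.0) * np.asarray(relative_density, dtype=float)


def density_from_index(n_p, solid_index: float):
    """Inverse of :func:`index_from_density`."""
    return (np.asarray(n_p, dtype=float) - 1.0) / (solid_index - 1.0)


def _stage_mean_density(
    material: MaterialSpec, pressure_kpa: float, pressure_scale_kpa: float
) -> float:
    lo = material.bulk_relative_density
    hi = material.tapped_relative_density
    return lo + (hi - lo) * (1.0 - np.exp(-pressure_kpa / pressure_scale_kpa))


def make_density_field(
    material: MaterialSpec,
    geometry: ContainerGeometry,
    stage_pressures: Sequence[float] = DEFAULT_STAGE_PRESSURES,
    heterogeneity_amp: float = 0.01,
    seed: int = 0,
    n_cells: int = 360,
    pressure_scale_kpa: float = DEFAULT_PRESSURE_SCALE_KPA,
) -> list[DensityField]:
    """Ground-truth density fields for a series of compaction stages.

    One field per stage.  The stage mean starts at the bulk/true density
    ratio at zero pressure and increases monotonically with pressure
    towards the tapped/true ratio.  A smooth angular heterogeneity
    pattern (low-order Fourier modes with seeded random phases, peak
    amplitude ``heterogeneity_amp`` in absolute density units) is drawn
    once and superimposed on every stage — it models the same imperfect
    bed observed through successive compressions.

    Raises
    ------
    ValueError
        If pressures decrease, or the heterogeneity would push any
        density outside (0, 1).
    """
    pressures = np.asarray(stage_pressures, dtype=float)
    if pressures.size < 1:
        raise ValueError("need at least one stage pressure")
    if np.any(np.diff(pressures) < 0):
        raise ValueError("stage pressures must be non-decreasing")
    if heterogeneity_amp < 0:
        raise ValueError("heterogeneity amplitude must be non-negative")

    angle_grid = np.arange(n_cells) * 360.0 / n_cells
    theta = np.radians(angle_grid)
    rng = np.random.default_rng(seed)
    pattern = np.zeros(n_cells)
    if heterogeneity_amp > 0:
        weights = rng.uniform(0.3, 1.0, size=3)
        phases = rng.uniform(0, 2 * np.pi, size=3)
        for m, (w, ph) in enumerate(zip(weights, phases), start=1):
            pattern += w * np.cos(m * theta + ph)
        pattern *= heterogeneity_amp / np.max(np.abs(pattern))

    fields = []
    for s, p in enumerate(pressures):
        mean = _stage_mean_density(material, p, pressure_scale_kpa)
        rho = mean + pattern
        if np.any(rho <= 0) or np.any(rho >= 1):
            raise ValueError(
                f"heterogeneity amplitude {heterogeneity_amp} pushes stage {s} "
                "density outside (0, 1)"
            )
        fields.append(DensityField(angle_grid.copy(), rho, stage_label=s))
    return fields


def _hole_intervals(event: DosingEvent) -> list[tuple[float, float]]:
    half = event.hole_width / 2.0
    return [(float(np.mod(p - half, 360.0)), float(np.mod(p + half, 360.0)))
            for p in event.positions]


def _in_arc(angles: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Membership of angles (deg) in the circular arc [lo, hi)."""
    a = np.mod(angles, 360.0)
    if lo <= hi:
        return (a >= lo) & (a < hi)
    return (a >= lo) | (a < hi)  # wraps through 0°


def apply_dosing(field: DensityField, event: DosingEvent) -> DensityField:
    """Depress the density inside each dosator hole segment.

    Returns a new field with the density multiplied by
    ``1 − hole_density_deficit`` inside every hole arc (wrap-around arcs
    handled); the bed is unchanged elsewhere.  Overlapping holes are
    rejected — the physical dip sites are disjoint.
    """
    arcs = _hole_intervals(event)
    covered = np.zeros(field.n_cells, dtype=bool)
    out = field.copy()
    for lo, hi in arcs:
        sel = _in_arc(field.angle_grid, lo, hi)
        if np.any(covered & sel):
            raise ValueError("dosing holes overlap")
        covered |= sel
        out.relative_density[sel] *= 1.0 - event.hole_density_deficit
    return out


def ricker_pulse(delay_ps: np.ndarray, center_ps: float,
                 width_ps: float = _PULSE_WIDTH_PS) -> np.ndarray:
    """Canonical single-cycle pulse shape with unit peak amplitude."""
    u = (delay_ps - center_ps) / width_ps
    return (1.0 - u**2) * np.exp(-0.5 * u**2)


def synthesize_scan(
    field: DensityField,
    material: MaterialSpec,
    geometry: ContainerGeometry,
    config: ScanConfig,
) -> tuple[ScanSequence, Waveform]:
    """Simulate one continuous acquisition over the rotating container.

    Returns the waveform sequence and the noiseless copper reference
    waveform (reflection coefficient −1, acquired prior to the scan).
    """
    delay = np.linspace(0.0, config.time_window, _N_SAMPLES)
    pulse = ricker_pulse(delay, _PULSE_CENTER_FRACTION * config.time_window)

    theta = config.measurement_angles()
    rho = field.density_at(theta)
    n_p = index_from_density(rho, material.solid_refractive_index)
    r = fresnel_reflection(n_p, geometry.container_index)

    on_datum = geometry.in_datum(theta)
    r = np.where(on_datum, -1.0, r)

    rng = np.random.default_rng(config.seed)
    if config.noise_sigma > 0:
        r = r + rng.normal(0.0, config.noise_sigma, size=r.size)

    # copper reference: reflection coefficient −1 on unit incident amplitude
    reference = Waveform(delay, -pulse, index=-1)
    amplitudes = r[:, None] * pulse[None, :]
    scan = ScanSequence(
        delay=delay,
        amplitudes=amplitudes,
        acquisition_rate=config.acquisition_rate,
        rotation_speed=config.rotation_speed,
    )
    return scan, reference


def synthesize_fill_weights(
    fields: DensityField | Sequence[DensityField],
    event: DosingEvent,
    material: MaterialSpec,
    dosator_diameter_mm: float = DEFAULT_DOSATOR_DIAMETER_MM,
    chamber_length_mm: float = DEFAULT_CHAMBER_LENGTH_MM,
    efficiency: float = DEFAULT_FILL_EFFICIENCY,
    weight_noise_sd_mg: float = DEFAULT_WEIGHT_NOISE_SD_MG,
    seed: int = 0,
    on_negative: str = "raise",
) -> pd.DataFrame:
    """Off-line fill-weight table for the eight dip sites per stage.

    The plug mass at site ``p`` is the local relative density times the
    true density times the dosing-chamber volume, scaled by the fill
    ``efficiency`` (>1 reflects pre-compression drawing in more than one
    chamber volume of loose powder), plus Gaussian weighing noise.
    Because 1 g·cm⁻³ equals 1 mg·mm⁻³ the weight in mg is direct.

    Returns a DataFrame with columns ``stage``, ``position`` (M01–M08)
    and ``weight_mg``; ``on_negative`` chooses between rejecting
    (``"raise"``) and redrawing (``"resample"``) negative noise draws.
    """
    if efficiency <= 0:
        raise ValueError("efficiency must be positive")
    if weight_noise_sd_mg < 0:
        raise ValueError("weight noise sd must be non-negative")
    if on_negative not in ("raise", "resample"):
        raise ValueError("on_negative must be 'raise' or 'resample'")
    if isinstance(fields, DensityField):
        fields = [fields]

    chamber_volume_mm3 = np.pi / 4.0 * dosator_diameter_mm**2 * chamber_length_mm
    rng = np.random.default_rng(seed)
    rows = []
    for f in fields:
        rho = f.density_at(event.positions)
        base = rho * material.true_density * chamber_volume_mm3 * efficiency
        noise = rng.normal(0.0, weight_noise_sd_mg, size=base.size)
        w = base + noise
        for _ in range(100):
            bad = w <= 0
            if not bad.any():
                break
            if on_negative == "raise":
                raise ValueError("generated a non-positive fill weight")
            w[bad] = base[bad] + rng.normal(0.0, weight_noise_sd_mg,
                                            size=int(bad.sum()))
        else:
            raise ValueError("could not resample positive fill weights")
        for label, weight in zip(event.labels, w):
            rows.append({"stage": f.stage_label, "position": label,
                         "weight_mg": float(weight)})
    return pd.DataFrame(rows, columns=["stage", "position", "weight_mg"])
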