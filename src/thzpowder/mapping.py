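"""Angle-resolved density maps, dosing-hole heterogeneity, and the
density–fill-weight correlation.

A :class:`DensityMap` holds relative density per (rotation, angular bin)
— each row is one container revolution binned on its own, converted from
reflection coefficient to refractive index and through a fitted
calibration to density.  Column means give the rotation-averaged
angular density profile; contiguous below-baseline runs in that profile
locate the dosator dip sites; stage-mean densities are correlated with
off-line fill weights by a least-squares line.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .calibration import CalibrationResults
from .optics import invert_reflection
from .signal import (
    AngularProfile,
    DEFAULT_N_BINS,
    ReflectionSeries,
    Rotations,
    bin_angular,
)

__all__ = [
    "DensityMap",
    "FillWeightRecord",
    "HoleSegment",
    "StageSummary",
    "CorrelationResult",
    "DensityWeightModel",
    "build_density_map",
    "angular_density_profile",
    "detect_hole_segments",
    "stage_summary",
    "correlate_density_weight",
]


@dataclass
class DensityMap:
    """Relative density per (rotation row, angular bin column).

    NaN marks bins with no contributing measurement in that rotation;
    ``artifact_mask`` flags whole columns (e.g. a container artefact at
    a fixed angle) for exclusion from every summary statistic.
    """

    values: np.ndarray  # (n_rotations, n_bins)
    bin_centers: np.ndarray
    rotation_ids: np.ndarray
    artifact_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.bin_centers = np.asarray(self.bin_centers, dtype=float)
        self.rotation_ids = np.asarray(self.rotation_ids, dtype=int)
        if self.values.ndim != 2 or self.values.shape[1] != self.bin_centers.size:
            raise ValueError("values must be (n_rotations, n_bins)")
        if self.rotation_ids.size != self.values.shape[0]:
            raise ValueError("one rotation id per row required")
        if self.artifact_mask is None:
            self.artifact_mask = np.zeros(self.bin_centers.size, dtype=bool)
        else:
            self.artifact_mask = np.asarray(self.artifact_mask, dtype=bool)
            if self.artifact_mask.size != self.bin_centers.size:
                raise ValueError("artifact mask must have one flag per bin")

    @property
    def n_rotations(self) -> int:
        return self.values.shape[0]

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    def masked_values(self) -> np.ndarray:
        """Values with artifact columns forced to NaN."""
        out = self.values.copy()
        out[:, self.artifact_mask] = np.nan
        return out

    @property
    def grand_mean(self) -> float:
        """Mean over all unmasked, populated cells."""
        v = self.masked_values()
        if not np.isfinite(v).any():
            raise ValueError("map has no unmasked values")
        return float(np.nanmean(v))

    def row_profile(self, row: int) -> AngularProfile:
        v = self.masked_values()[row]
        return AngularProfile(
            bin_centers=self.bin_centers.copy(),
            value=v,
            n_contributing=np.isfinite(v).astype(int),
        )


@dataclass
class FillWeightRecord:
    """One weighed capsule: gross, tare and net mass in mg."""

    stage: int
    position: str
    gross_mg: float
    tare_mg: float

    def __post_init__(self) -> None:
        if self.net_mg < 0:
            raise ValueError("net weight must be non-negative (gross >= tare)")

    @property
    def net_mg(self) -> float:
        return self.gross_mg - self.tare_mg


@dataclass
class HoleSegment:
    """One contiguous below-baseline arc of the density profile."""

    start_deg: float
    end_deg: float  # may be < start_deg when the arc wraps through 0°
    mean_deficit: float

    @property
    def center_deg(self) -> float:
        span = np.mod(self.end_deg - self.start_deg, 360.0)
        return float(np.mod(self.start_deg + span / 2.0, 360.0))


@dataclass
class StageSummary:
    """Fill-weight statistics of one compression stage."""

    mean_mg: float
    sd_mg: float
    rsd_percent: float
    n: int


@dataclass
class CorrelationResult:
    """Least-squares line linking stage-mean density to fill weight."""

    material: str | None
    slope: float  # mg per unit relative density
    intercept: float  # mg
    r_squared: float
    stage_means: list[tuple[float, float]]  # (mean ϱ̄_r, mean weight mg)

    def summary(self) -> str:
        label = self.material or "<unlabelled>"
        lines = [
            "Density–fill-weight correlation",
            "=" * 44,
            f"material:   {label}",
            f"n stages:   {len(self.stage_means)}",
            f"slope:      {self.slope:+.2f} mg per unit relative density",
            f"intercept:  {self.intercept:+.2f} mg",
            f"R-squared:  {self.r_squared:.4f}",
        ]
        return "\n".join(lines)


class DensityWeightModel:
    """Model object pairing stage-mean densities with mean fill weights.

    ``fit()`` regresses weight on density (least squares) and returns a
    :class:`CorrelationResult`.
    """

    def __init__(self, stage_densities, stage_weights,
                 material: str | None = None):
        d = np.asarray(stage_densities, dtype=float)
        w = np.asarray(stage_weights, dtype=float)
        if d.shape != w.shape or d.ndim != 1:
            raise ValueError("densities and weights must be equal-length 1-D")
        if d.size < 2:
            raise ValueError("need at least two stages")
        if np.ptp(d) == 0:
            raise ValueError("degenerate: stage densities are constant")
        self.densities = d
        self.weights = w
        self.material = material

    def fit(self) -> CorrelationResult:
        res = stats.linregress(self.densities, self.weights)
        return CorrelationResult(
            material=self.material,
            slope=float(res.slope),
            intercept=float(res.intercept),
            r_squared=float(res.rvalue**2),
            stage_means=list(zip(self.densities.tolist(),
                                 self.weights.tolist())),
        )


def build_density_map(
    series: ReflectionSeries,
    results: CalibrationResults,
    rotations: Rotations,
    solid_index: float | None = None,
    container_index: float = 1.54,
    n_bins: int = DEFAULT_N_BINS,
    use_rotations: Sequence[int] | None = None,
    values: np.ndarray | None = None,
    artifact_angles: Sequence[tuple[float, float]] = (),
    origin_deg: float = 0.0,
) -> DensityMap:
    """Rotation-by-rotation relative-density map from a reflection series.

    Each selected complete rotation is binned to ``n_bins`` on its own,
    the bin-mean reflection coefficients are inverted to refractive
    index, and the fitted calibration converts index to density.
    ``artifact_angles`` lists (start°, end°) arcs to mask (e.g. a known
    container artefact); masked columns are excluded from all summaries.

    ``solid_index`` is unused by the conversion itself (the calibration
    line absorbs the index–density law) and accepted only for API
    symmetry with the simulator.
    """
    if use_rotations is None:
        use_rotations = range(rotations.n_complete)
    use = list(use_rotations)
    if not use:
        raise ValueError("need at least one complete rotation")
    rows = []
    centers = None
    for k in use:
        prof = bin_angular(series, rotations, n_bins=n_bins,
                           use_rotations=[k], values=values,
                           origin_deg=origin_deg)
        centers = prof.bin_centers
        row = np.full(n_bins, np.nan)
        v = prof.valid
        n_p = invert_reflection(prof.value[v], container_index)
        row[v] = results.predict(n_p, warn_extrapolation=False)
        rows.append(row)
    assert centers is not None
    mask = np.zeros(n_bins, dtype=bool)
    for lo, hi in artifact_angles:
        a = np.mod(centers, 360.0)
        lo, hi = np.mod(lo, 360.0), np.mod(hi, 360.0)
        mask |= ((a >= lo) & (a < hi)) if lo <= hi else ((a >= lo) | (a < hi))
    return DensityMap(
        values=np.vstack(rows),
        bin_centers=centers,
        rotation_ids=np.asarray(use, dtype=int),
        artifact_mask=mask,
    )


def angular_density_profile(dmap: DensityMap) -> AngularProfile:
    """Rotation-averaged density versus container angle.

    Unmasked column means across rotations; all-masked or never-
    populated columns surface as NaN with a zero count.
    """
    v = dmap.masked_values()
    counts = np.isfinite(v).sum(axis=0)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, np.nansum(v, axis=0) / np.maximum(counts, 1),
                         np.nan)
    return AngularProfile(bin_centers=dmap.bin_centers.copy(), value=means,
                          n_contributing=counts)


def detect_hole_segments(
    profile: AngularProfile,
    baseline: str | float = "median",
    depth_threshold: float = 0.01,
) -> list[HoleSegment]:
    """Locate contiguous below-baseline arcs (dosator dip sites).

    A bin belongs to a hole when its density falls below
    ``baseline − depth_threshold``; adjacent hole bins merge into one
    segment, including across the 0°/360° wrap.  The default baseline is
    the profile median — robust while the depressed segments cover a
    minority of bins.  Returns an empty list when nothing dips below.
    """
    if isinstance(baseline, str):
        if baseline != "median":
            raise ValueError("baseline must be 'median' or a number")
        base = float(np.nanmedian(profile.value[profile.valid]))
    else:
        base = float(baseline)
    v = profile.value
    below = profile.valid & (v < base - depth_threshold)
    if not below.any():
        return []
    n = profile.n_bins
    half_width = 180.0 / n
    # contiguous runs on the circle
    starts = np.flatnonzero(below & ~np.roll(below, 1))
    if starts.size == 0:  # every bin below: one full-circle segment
        return [HoleSegment(0.0, 360.0, float(base - np.nanmean(v[below])))]
    segments = []
    for s in starts:
        e = s
        while below[(e + 1) % n]:
            e = e + 1  # may exceed n-1; indexes taken mod n
            if e - s >= n:
                break
        idx = np.mod(np.arange(s, e + 1), n)
        segments.append(
            HoleSegment(
                start_deg=float(profile.bin_centers[s] - half_width),
                end_deg=float(np.mod(profile.bin_centers[idx[-1]] + half_width,
                                     360.0)),
                mean_deficit=float(base - np.nanmean(v[idx])),
            )
        )
    return segments


def stage_summary(weights) -> StageSummary:
    """Mean, sample sd and RSD% of the fill weights of one stage.

    Accepts an array of net weights in mg, a DataFrame with a
    ``weight_mg`` column, or a sequence of :class:`FillWeightRecord`.
    """
    if isinstance(weights, pd.DataFrame):
        w = weights["weight_mg"].to_numpy(dtype=float)
    elif len(weights) and isinstance(weights[0], FillWeightRecord):
        w = np.array([rec.net_mg for rec in weights], dtype=float)
    else:
        w = np.asarray(weights, dtype=float)
    if w.size < 2:
        raise ValueError("need at least two weight records")
    mean = float(w.mean())
    sd = float(w.std(ddof=1))
    return StageSummary(mean_mg=mean, sd_mg=sd,
                        rsd_percent=100.0 * sd / mean, n=int(w.size))


def correlate_density_weight(
    stage_densities, stage_weights, material: str | None = None
) -> CorrelationResult:
    """Least-squares line ``weight = α + β·ϱ̄_r`` over stage means."""
    return DensityWeightModel(stage_densities, stage_weights,
                              material=material).fit()


def plot_density_map(dmap: DensityMap, path=None, ax=None):
    """Render the rotation × angle density map as a heat map.

    Requires matplotlib (optional dependency); returns the axes.
    """
    import matplotlib
    if path is not None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3.2))
    im = ax.pcolormesh(
        np.append(dmap.bin_centers - 180.0 / dmap.n_bins, 360.0),
        np.arange(dmap.n_rotations + 1),
        dmap.masked_values(),
        shading="flat",
    )
    ax.set_xlabel("container angle (deg)")
    ax.set_ylabel("rotation")
    ax.figure.colorbar(im, ax=ax, label="relative density")
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
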