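"""Domain parameter objects: materials, container geometry, scan setup,
density fields and dosing events.

These are frozen (or nearly frozen) value objects validated on
construction; everything downstream — the simulator, the signal chain,
the calibration — consumes them rather than loose keyword soup.

Three inhalation-grade α-lactose monohydrate excipients are bundled as
presets (bulk/tapped/true density, and the powder mass that fills the
annular container to a 10 mm layer at bulk density).  The solid
refractive index of pore-free α-lactose monohydrate at terahertz
frequencies is a simulator assumption (1.78), not a measured property of
these presets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .optics import annulus_area

__all__ = [
    "MaterialSpec",
    "ContainerGeometry",
    "ScanConfig",
    "DensityField",
    "DosingEvent",
    "LACTOHALE_100",
    "LACTOHALE_200",
    "LACTOHALE_220",
    "MATERIALS",
    "DEFAULT_GEOMETRY",
    "geometric_hole_width",
]


@dataclass(frozen=True)
class MaterialSpec:
    """A powder and the container charge made from it.

    Densities in g·cm⁻³; ``mass`` in g is the charge that fills the
    annular container to the nominal layer height at bulk density.
    ``solid_refractive_index`` is the terahertz index of the pore-free
    solid, the upper anchor of the effective-medium index–density law.
    """

    name: str
    bulk_density: float
    tapped_density: float
    true_density: float
    solid_refractive_index: float
    mass: float

    def __post_init__(self) -> None:
        if not 0 < self.bulk_density <= self.tapped_density <= self.true_density:
            raise ValueError(
                "require 0 < bulk <= tapped <= true density, got "
                f"{self.bulk_density}/{self.tapped_density}/{self.true_density}"
            )
        if self.solid_refractive_index <= 1:
            raise ValueError("solid refractive index must exceed 1")
        if self.mass <= 0:
            raise ValueError("mass must be positive")

    @property
    def bulk_relative_density(self) -> float:
        """Relative density of the loosely settled powder."""
        return self.bulk_density / self.true_density

    @property
    def tapped_relative_density(self) -> float:
        """Relative density after tapping rearrangement."""
        return self.tapped_density / self.true_density


@dataclass(frozen=True)
class ContainerGeometry:
    """Rotary annular container with a copper datum strip.

    Lengths in mm, angles in degrees.  The datum strip sits on the
    outside of the container at ``datum_angle`` and spans
    ``datum_width`` degrees; it returns a near-total reflection once per
    revolution and anchors the angular registration.
    """

    outer_diameter: float = 138.0
    inner_diameter: float = 78.0
    interior_height: float = 45.0
    layer_height: float = 10.0
    container_index: float = 1.54
    datum_angle: float = 0.0
    datum_width: float = 8.0

    def __post_init__(self) -> None:
        if not self.outer_diameter > self.inner_diameter > 0:
            raise ValueError("require outer_diameter > inner_diameter > 0")
        if not 0 < self.layer_height <= self.interior_height:
            raise ValueError("require 0 < layer_height <= interior_height")
        if self.container_index <= 1:
            raise ValueError("container index must exceed 1")
        if not 0 < self.datum_width < 360:
            raise ValueError("datum width must lie in (0, 360) degrees")

    @property
    def annulus_area_mm2(self) -> float:
        return annulus_area(self.outer_diameter, self.inner_diameter)

    @property
    def mid_annulus_radius_mm(self) -> float:
        return (self.outer_diameter + self.inner_diameter) / 4.0

    def in_datum(self, angle_deg) -> np.ndarray:
        """Boolean mask: does each angle fall on the datum strip?"""
        rel = np.mod(np.asarray(angle_deg, dtype=float) - self.datum_angle, 360.0)
        return rel < self.datum_width


def geometric_hole_width(
    dosator_diameter_mm: float, geometry: ContainerGeometry
) -> float:
    """Angular footprint (degrees) of a dosator nozzle at mid-annulus radius."""
    if dosator_diameter_mm <= 0:
        raise ValueError("dosator diameter must be positive")
    return float(np.degrees(dosator_diameter_mm / geometry.mid_annulus_radius_mm))


@dataclass(frozen=True)
class ScanConfig:
    """Acquisition settings for one continuous rotating-container scan."""

    acquisition_rate: float = 15.0  # waveforms per second
    rotation_speed: float = 4.0  # container revolutions per minute
    n_waveforms: int = 2000
    time_window: float = 45.0  # optical delay span, ps
    noise_sigma: float = 0.0015  # additive sd, reflection-coefficient units
    seed: int = 0

    def __post_init__(self) -> None:
        if self.acquisition_rate <= 0 or self.rotation_speed <= 0:
            raise ValueError("rates must be positive")
        if self.n_waveforms < 1:
            raise ValueError("need at least one waveform")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be non-negative")

    @property
    def total_time_s(self) -> float:
        return self.n_waveforms / self.acquisition_rate

    @property
    def degrees_per_sample(self) -> float:
        return 360.0 * self.rotation_speed / 60.0 / self.acquisition_rate

    @property
    def rotations_covered(self) -> float:
        """Container revolutions spanned by the full acquisition."""
        return self.total_time_s * self.rotation_speed / 60.0

    def measurement_angles(self) -> np.ndarray:
        """Container angle (degrees, mod 360) at each acquisition instant."""
        i = np.arange(self.n_waveforms)
        return np.mod(i * self.degrees_per_sample, 360.0)


@dataclass
class DensityField:
    """Relative density of the powder bed versus container angle.

    ``angle_grid`` holds the left edges of uniform cells covering
    [0°, 360°); the field is piecewise constant on those cells, which is
    the resolution at which the angular analysis operates.
    """

    angle_grid: np.ndarray
    relative_density: np.ndarray
    stage_label: int = 0

    def __post_init__(self) -> None:
        self.angle_grid = np.asarray(self.angle_grid, dtype=float)
        self.relative_density = np.asarray(self.relative_density, dtype=float)
        if self.angle_grid.shape != self.relative_density.shape:
            raise ValueError("angle grid and density must have equal shapes")
        if self.angle_grid.ndim != 1 or self.angle_grid.size < 1:
            raise ValueError("angle grid must be a non-empty 1-D array")
        widths = np.diff(self.angle_grid)
        if self.angle_grid[0] != 0.0 or (widths.size and not np.allclose(
            widths, 360.0 / self.angle_grid.size
        )):
            raise ValueError("angle grid must uniformly cover [0, 360)")
        if np.any(self.relative_density <= 0) or np.any(self.relative_density >= 1):
            raise ValueError("relative density must lie strictly in (0, 1)")

    @property
    def n_cells(self) -> int:
        return self.angle_grid.size

    @property
    def cell_width(self) -> float:
        return 360.0 / self.n_cells

    def density_at(self, angle_deg) -> np.ndarray:
        """Piecewise-constant lookup of density at arbitrary angles.

        A tiny positive nudge (1e-9 cells) makes samples that sit
        exactly on a cell edge resolve deterministically to that cell
        despite floating-point representation of the angles.
        """
        pos = np.mod(angle_deg, 360.0) / self.cell_width
        idx = np.floor(pos + 1e-9).astype(int)
        idx = np.clip(idx, 0, self.n_cells - 1)
        return self.relative_density[idx]

    @property
    def mean(self) -> float:
        return float(self.relative_density.mean())

    def copy(self) -> "DensityField":
        return DensityField(
            self.angle_grid.copy(), self.relative_density.copy(), self.stage_label
        )


def _default_positions() -> np.ndarray:
    # eight dip sites, evenly spaced, offset away from the datum strip
    return 22.5 + 45.0 * np.arange(8)


@dataclass
class DosingEvent:
    """Eight dosator dips into the rotating bed (sites M01–M08).

    After the container rotates past the scraper the holes refill with
    loose powder, leaving each site at a fractionally lower density:
    density inside a hole is multiplied by ``1 - hole_density_deficit``.
    The default deficit of 0.12 is the gap between a bed compacted to
    ~0.46 relative density and refilled loose powder near the bulk
    ratio (~0.40).  ``hole_width`` is the angular footprint per dip in
    degrees; the default is the geometric footprint of a 3.4 mm dosator
    at mid-annulus radius of the production container.
    """

    positions: np.ndarray = field(default_factory=_default_positions)
    hole_density_deficit: float = 0.12
    hole_width: float = 3.61

    def __post_init__(self) -> None:
        self.positions = np.mod(np.asarray(self.positions, dtype=float), 360.0)
        if self.positions.size != 8:
            raise ValueError("expected eight dosing positions (M01–M08)")
        if len(set(self.positions.tolist())) != 8:
            raise ValueError("dosing positions must be pairwise distinct")
        if not 0 <= self.hole_density_deficit < 1:
            raise ValueError("hole density deficit must lie in [0, 1)")
        if self.hole_width <= 0:
            raise ValueError("hole width must be positive")

    @property
    def labels(self) -> list[str]:
        return [f"M{k + 1:02d}" for k in range(self.positions.size)]


# Table of bundled excipients: (bulk, tapped, true) densities g·cm⁻³ and
# the container charge in g.  Solid THz index 1.78 is a stated assumption.
_LACTOSE_SOLID_INDEX = 1.78

LACTOHALE_100 = MaterialSpec("Lactohale 100", 0.697, 0.828, 1.539,
                             _LACTOSE_SOLID_INDEX, 70.9)
LACTOHALE_200 = MaterialSpec("Lactohale 200", 0.622, 0.996, 1.543,
                             _LACTOSE_SOLID_INDEX, 63.3)
LACTOHALE_220 = MaterialSpec("Lactohale 220", 0.400, 0.785, 1.547,
                             _LACTOSE_SOLID_INDEX, 40.7)

MATERIALS: dict[str, MaterialSpec] = {
    m.name: m for m in (LACTOHALE_100, LACTOHALE_200, LACTOHALE_220)
}

DEFAULT_GEOMETRY = ContainerGeometry()


def material_from_dict(d: dict) -> MaterialSpec:
    """Build a MaterialSpec from a config mapping; a bare ``name`` that
    matches a bundled preset resolves to that preset, with any further
    keys overriding preset fields."""
    name = d.get("name")
    if name in MATERIALS:
        base = MATERIALS[name]
        overrides = {k: v for k, v in d.items() if k != "name"}
        return replace(base, **overrides) if overrides else base
    return MaterialSpec(**d)
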