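"""Normal-incidence Fresnel optics and container geometry.

The measurement principle: a terahertz pulse travelling through the
HDPE container wall is partially reflected at the container/powder
interface.  At normal incidence the field reflection coefficient is

    r = (n_c - n_p) / (n_c + n_p)

with ``n_c`` the container index and ``n_p`` the effective refractive
index of the powder bed.  A loosely packed powder has ``n_p`` close to 1
(mostly air), so ``r > 0``; densification raises ``n_p`` towards the
solid index and drives ``r`` towards zero (and negative once
``n_p > n_c``).  Inverting the relation yields ``n_p`` from a measured
``r``, and ``n_p`` is in turn an effective-medium proxy for the relative
bulk density of the bed.

The geometry side provides the nominal (gravimetric) relative density of
an annular powder layer from its mass, cross-section area and fill
height — the reference quantity against which the optical measurement is
calibrated.

Unit conventions: lengths in mm, masses in g, densities in g·cm⁻³.
Conversions between mm³ and cm³ happen here and nowhere else.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "fresnel_reflection",
    "invert_reflection",
    "annulus_area",
    "nominal_relative_density",
    "average_fill_height",
    "IndexEstimate",
    "CompactionStage",
]

#: mm³ per cm³ — the single place the mixed length units meet.
_MM3_PER_CM3 = 1000.0

#: heights of the compression unit resting on the powder bed: a 10 mm
#: metal ring topped by a 63 mm load-sensor block.  Caliper displacement
#: readings run from the container bottom to the top of the block.
RING_HEIGHT_MM = 10.0
SENSOR_BLOCK_HEIGHT_MM = 63.0


def fresnel_reflection(n_powder, n_container):
    """Field reflection coefficient at the container/powder interface.

    Parameters
    ----------
    n_powder : float or array_like
        Effective refractive index of the powder bed (> 0).
    n_container : float
        Refractive index of the container wall (> 0), 1.54 for HDPE.

    Returns
    -------
    float or ndarray
        ``(n_container - n_powder) / (n_container + n_powder)``,
        strictly inside (-1, 1) for positive finite indices.
    """
    n_p = np.asarray(n_powder, dtype=float)
    if np.any(n_p <= 0) or n_container <= 0:
        raise ValueError("refractive indices must be positive")
    r = (n_container - n_p) / (n_container + n_p)
    return float(r) if np.isscalar(n_powder) else r


def invert_reflection(r, n_container):
    """Effective powder index from a measured reflection coefficient.

    The unique algebraic inverse of :func:`fresnel_reflection`:
    ``n_p = n_container * (1 - r) / (1 + r)``.

    Raises
    ------
    ValueError
        If ``|r| >= 1`` (non-physical for a dielectric interface) or the
        container index is not positive.
    """
    r_arr = np.asarray(r, dtype=float)
    if n_container <= 0:
        raise ValueError("container index must be positive")
    if np.any(np.abs(r_arr) >= 1):
        raise ValueError("reflection coefficient must satisfy |r| < 1")
    n_p = n_container * (1.0 - r_arr) / (1.0 + r_arr)
    return float(n_p) if np.isscalar(r) else n_p


def annulus_area(outer_diameter_mm: float, inner_diameter_mm: float) -> float:
    """Cross-section area of the annular container interior, in mm².

    ``A = π (Do² − Di²) / 4``.  With the production container
    (Do = 138 mm, Di = 78 mm) this area times the 10 mm layer height and
    the bulk density reproduces the powder masses used to fill the
    container, which pins the formula.  ``Di = 0`` degenerates to the
    full disc.
    """
    if not outer_diameter_mm > inner_diameter_mm >= 0:
        raise ValueError(
            "require outer_diameter > inner_diameter >= 0, got "
            f"Do={outer_diameter_mm}, Di={inner_diameter_mm}"
        )
    return np.pi * (outer_diameter_mm**2 - inner_diameter_mm**2) / 4.0


def nominal_relative_density(
    mass_g: float, area_mm2: float, fill_height_mm: float, true_density_g_cm3: float
) -> float:
    """Gravimetric relative density of the powder layer.

    ``ϱ̄_r = m / (A · h̄ · ϱ_t)`` — powder mass over the mass the layer
    volume would have at the pore-free solid density.  Dimensionless,
    strictly inside (0, 1) for a porous bed.

    Raises
    ------
    ValueError
        On non-positive inputs, or when the result falls outside (0, 1),
        which signals mutually inconsistent mass/volume/density inputs.
    """
    for name, v in (
        ("mass_g", mass_g),
        ("area_mm2", area_mm2),
        ("fill_height_mm", fill_height_mm),
        ("true_density_g_cm3", true_density_g_cm3),
    ):
        if not v > 0:
            raise ValueError(f"{name} must be positive, got {v}")
    volume_cm3 = area_mm2 * fill_height_mm / _MM3_PER_CM3
    rho_r = mass_g / (volume_cm3 * true_density_g_cm3)
    if not 0.0 < rho_r < 1.0:
        raise ValueError(
            f"relative density {rho_r:.4f} outside (0, 1): inconsistent inputs"
        )
    return rho_r


def average_fill_height(
    displacements_mm,
    ring_height_mm: float = RING_HEIGHT_MM,
    block_height_mm: float = SENSOR_BLOCK_HEIGHT_MM,
) -> float:
    """Mean fill height from the eight caliper displacement readings.

    Each reading is the distance from the container bottom to the top of
    the compression unit (powder layer + 10 mm ring + 63 mm sensor
    block), measured at eight evenly spaced positions around the
    annulus.  The fill height is the mean reading minus the unit height.

    Raises
    ------
    ValueError
        If not exactly eight readings are supplied or the resulting
        height is not positive.
    """
    d = np.asarray(displacements_mm, dtype=float)
    if d.shape != (8,):
        raise ValueError(f"expected eight caliper positions, got {d.size}")
    h = float(d.mean()) - ring_height_mm - block_height_mm
    if h <= 0:
        raise ValueError(f"non-positive fill height {h:.3f} mm from readings")
    return h


@dataclass
class IndexEstimate:
    """Effective refractive indices with a record of their provenance."""

    values: np.ndarray
    source: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        finite = self.values[np.isfinite(self.values)]
        if finite.size and np.any(finite <= 0):
            raise ValueError("refractive indices must be positive")

    @property
    def mean(self) -> float:
        """Mean index over finite entries."""
        return float(np.nanmean(self.values))


@dataclass
class CompactionStage:
    """One compression stage of the powder bed.

    Carries the eight caliper displacement readings and, once resolved
    against the geometry and material, the nominal fill height and
    relative density.  ``applied_pressure_kpa`` is metadata only — no
    mechanics is derived from it.
    """

    stage_index: int
    displacements_mm: np.ndarray
    applied_pressure_kpa: float = float("nan")
    fill_height_mm: float = field(default=float("nan"))
    nominal_density: float = field(default=float("nan"))

    def __post_init__(self) -> None:
        self.displacements_mm = np.asarray(self.displacements_mm, dtype=float)
        if self.displacements_mm.shape != (8,):
            raise ValueError("expected eight caliper positions")

    def resolve(self, material, geometry) -> "CompactionStage":
        """Fill in h̄ and ϱ̄_r from a material and container geometry."""
        self.fill_height_mm = average_fill_height(self.displacements_mm)
        if self.fill_height_mm > geometry.interior_height:
            raise ValueError("fill height exceeds container interior height")
        self.nominal_density = nominal_relative_density(
            material.mass,
            geometry.annulus_area_mm2,
            self.fill_height_mm,
            material.true_density,
        )
        return self
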