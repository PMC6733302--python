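"""Linear index→density calibration.

One model per material: the mean nominal relative density of the bed is
regressed on the mean measured refractive index,

    ϱ̄_r = a0 + a1 · n̄_p,

by ordinary least squares over the pooled compaction stages of all
calibration runs.  The fitted line then predicts the relative density
of subsequent scans from their mean index alone.

``DensityCalibration`` is the model object; ``fit()`` returns a
``CalibrationResults`` carrying the estimates, their standard errors,
R², RMSE (root mean squared calibration residual, in relative-density
units) and a ``summary()`` table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .signal import AngularProfile

__all__ = [
    "DensityCalibration",
    "CalibrationResults",
    "ExtrapolationWarning",
    "fit_calibration",
    "predict_density",
    "mean_index",
]


class ExtrapolationWarning(UserWarning):
    """Prediction requested outside the fitted index range."""


def mean_index(profile) -> float:
    """Mean refractive index n̄_p of an angular profile or index series.

    Accepts an :class:`~thzpowder.signal.AngularProfile` (datum/empty
    bins are already excluded there), an object with a ``values``
    attribute, or a plain array; NaN entries are ignored.
    """
    if isinstance(profile, AngularProfile):
        return profile.mean
    values = getattr(profile, "values", profile)
    arr = np.asarray(values, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size == 0:
        raise ValueError("no finite index values to average")
    return float(arr.mean())


class DensityCalibration:
    """OLS model of mean relative density against mean refractive index.

    Parameters
    ----------
    index_means : array_like
        n̄_p per calibration point (one point per stage and run).
    density_means : array_like
        Nominal ϱ̄_r per calibration point, from mass, annulus area,
        fill height and true density.
    material : str, optional
        Label carried through to the results and persisted model.
    """

    def __init__(self, index_means, density_means, material: str | None = None):
        x = np.asarray(index_means, dtype=float)
        y = np.asarray(density_means, dtype=float)
        if x.shape != y.shape or x.ndim != 1:
            raise ValueError("index and density means must be equal-length 1-D")
        keep = np.isfinite(x) & np.isfinite(y)
        x, y = x[keep], y[keep]
        if x.size < 2:
            raise ValueError("need at least two calibration points")
        if np.ptp(x) == 0:
            raise ValueError("degenerate abscissa: all index means identical")
        self.exog = x
        self.endog = y
        self.material = material

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        index_col: str = "n_p_mean",
        density_col: str = "rho_r",
        material: str | None = None,
    ) -> "DensityCalibration":
        return cls(df[index_col].to_numpy(), df[density_col].to_numpy(),
                   material=material)

    def fit(self) -> "CalibrationResults":
        x, y = self.exog, self.endog
        n = x.size
        xbar, ybar = x.mean(), y.mean()
        sxx = float(np.sum((x - xbar) ** 2))
        sxy = float(np.sum((x - xbar) * (y - ybar)))
        a1 = sxy / sxx
        a0 = ybar - a1 * xbar
        resid = y - (a0 + a1 * x)
        ss_res = float(np.sum(resid**2))
        ss_tot = float(np.sum((y - ybar) ** 2))
        r_squared = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
        rmse = float(np.sqrt(ss_res / n))
        if n > 2:
            sigma2 = ss_res / (n - 2)
            se_a1 = float(np.sqrt(sigma2 / sxx))
            se_a0 = float(np.sqrt(sigma2 * (1.0 / n + xbar**2 / sxx)))
        else:
            se_a0 = se_a1 = float("nan")
        return CalibrationResults(
            model=self,
            params=np.array([a0, a1]),
            bse=np.array([se_a0, se_a1]),
            rsquared=r_squared,
            rmse=rmse,
            nobs=n,
            index_range=(float(x.min()), float(x.max())),
            resid=resid,
        )


@dataclass
class CalibrationResults:
    """Fitted index→density calibration line and its diagnostics."""

    model: DensityCalibration
    params: np.ndarray  # (a0, a1)
    bse: np.ndarray  # standard errors of (a0, a1)
    rsquared: float
    rmse: float
    nobs: int
    index_range: tuple[float, float]
    resid: np.ndarray

    @property
    def a0(self) -> float:
        return float(self.params[0])

    @property
    def a1(self) -> float:
        return float(self.params[1])

    @property
    def material(self) -> str | None:
        if self.model is not None:
            return self.model.material
        return getattr(self, "_material", None)

    def predict(self, index_mean, warn_extrapolation: bool = True):
        """Relative density ϱ̄_r = a0 + a1·n̄_p for new mean indices."""
        x = np.asarray(index_mean, dtype=float)
        if warn_extrapolation:
            lo, hi = self.index_range
            if np.any(x < lo) or np.any(x > hi):
                warnings.warn(
                    f"predicting outside the fitted index range "
                    f"[{lo:.4f}, {hi:.4f}]",
                    ExtrapolationWarning,
                    stacklevel=2,
                )
        out = self.a0 + self.a1 * x
        return float(out) if np.isscalar(index_mean) else out

    def summary(self) -> str:
        label = self.material or "<unlabelled>"
        lines = [
            "Density calibration (OLS)",
            "=" * 44,
            f"material:        {label}",
            f"n points:        {self.nobs}",
            f"a0 (intercept):  {self.a0:+.6f}  (se {self.bse[0]:.6f})",
            f"a1 (slope):      {self.a1:+.6f}  (se {self.bse[1]:.6f})",
            f"R-squared:       {self.rsquared:.4f}",
            f"RMSE:            {self.rmse:.6f}  (relative-density units)",
            f"index range:     [{self.index_range[0]:.4f}, "
            f"{self.index_range[1]:.4f}]",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "material": self.material,
            "a0": self.a0,
            "a1": self.a1,
            "r_squared": float(self.rsquared),
            "rmse": float(self.rmse),
            "n_points": int(self.nobs),
            "index_min": self.index_range[0],
            "index_max": self.index_range[1],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationResults":
        """Rehydrate persisted results (model and residuals are absent)."""
        res = cls(
            model=None,  # type: ignore[arg-type]
            params=np.array([d["a0"], d["a1"]]),
            bse=np.array([np.nan, np.nan]),
            rsquared=float(d["r_squared"]),
            rmse=float(d["rmse"]),
            nobs=int(d["n_points"]),
            index_range=(float(d["index_min"]), float(d["index_max"])),
            resid=np.array([]),
        )
        res._material = d.get("material")  # type: ignore[attr-defined]
        return res


def fit_calibration(points, material: str | None = None) -> CalibrationResults:
    """Fit the calibration line from (n̄_p, ϱ̄_r) pairs."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array of (index, density)")
    return DensityCalibration(pts[:, 0], pts[:, 1], material=material).fit()


def predict_density(results: CalibrationResults, index_mean):
    """Apply a fitted calibration to new mean indices."""
    return results.predict(index_mean)
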