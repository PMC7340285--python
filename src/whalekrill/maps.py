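"""Gridded predictions, line-transect densities, map averaging, deciles.

Final models are applied to the 1-km² grid per cruise with the effort
offset fixed at log(1), so maps show per-unit-effort expected abundance
(decile scaling is offset-invariant). Monthly maps average a calendar
month across years; annual maps average the surveyed months within a
year; the overall map first averages months within each year and then
averages across years, weighting all years equally regardless of how
many months each contributed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


def segment_density(n: float, length_km: float, esw_km: float, g0: float) -> float:
    """Line-transect segment density D = n / (2 · L · ESW · g0), animals/km².

    ESW is the effective strip half-width; g0 the trackline detection
    probability.
    """
    if length_km <= 0:
        raise ValueError("segment length must be positive")
    if esw_km <= 0 or not (0 < g0 <= 1):
        raise ValueError("need esw > 0 and 0 < g0 <= 1 (detection correction undefined)")
    if n < 0:
        raise ValueError("sighting count must be non-negative")
    return n / (2.0 * length_km * esw_km * g0)


@dataclass
class PredictionRaster:
    """Per-unit-effort expected abundance on the grid for one cruise-month."""

    species: str
    year: int
    month: int
    values: np.ndarray  # 2-D, NaN where covariates unavailable

    @property
    def key(self) -> tuple[int, int]:
        return (self.year, self.month)


def predict_grid(
    fit,
    cell_table: pd.DataFrame,
    grid,
    species: str,
    year: int,
    month: int,
) -> PredictionRaster:
    """Apply a fitted model to the grid's cell covariate table.

    ``fit`` is a glm.ModelFit or glm.HurdleFit; the hurdle combines parts
    as π·μ/(1−NB(0;μ,θ)). ``cell_table`` must carry every model covariate
    (kriged surfaces joined to static grid covariates and the cruise's
    climate columns); a missing covariate raises with its name. Cells with
    NaN covariates are masked.
    """
    pred = np.asarray(fit.predict(cell_table, offset_value=0.0), dtype=float)
    if np.any(pred < 0):
        raise ValueError("negative abundance prediction")
    return PredictionRaster(species, year, month, grid.raster(pred))


def average_maps(
    rasters: list[PredictionRaster], scheme: str
) -> dict[object, tuple[np.ndarray, list[tuple[int, int]]]]:
    """Cellwise-average monthly prediction rasters.

    ``scheme``:
      - "monthly": one map per calendar month, averaged across years;
      - "annual": one map per year, averaged over its surveyed months;
      - "overall": a single map — within-year mean first, then the mean of
        the yearly maps (equal weight per year).

    Returns {key: (array, contributing (year, month) list)}; key is the
    month, the year, or "overall".
    """
    if not rasters:
        raise ValueError("no rasters to average")
    if scheme == "monthly":
        groups: dict[object, list[PredictionRaster]] = {}
        for r in rasters:
            groups.setdefault(r.month, []).append(r)
        return {
            m: (np.mean([r.values for r in rs], axis=0), [r.key for r in rs])
            for m, rs in sorted(groups.items())
        }
    if scheme == "annual":
        groups = {}
        for r in rasters:
            groups.setdefault(r.year, []).append(r)
        return {
            yr: (np.mean([r.values for r in rs], axis=0), [r.key for r in rs])
            for yr, rs in sorted(groups.items())
        }
    if scheme == "overall":
        annual = average_maps(rasters, "annual")
        yearly = [arr for arr, _ in annual.values()]
        prov = [k for _, keys in annual.values() for k in keys]
        return {"overall": (np.mean(yearly, axis=0), prov)}
    raise ValueError(f"unknown averaging scheme {scheme!r}")


def decile_scale(raster_set: list[np.ndarray]) -> tuple[list[np.ndarray], np.ndarray]:
    """Assign decile classes 1-10 from the pooled values of the whole set.

    Class boundaries are the pooled 10%,...,90% quantiles; boundary ties
    assign the lower class; NaN cells stay NaN (encoded 0 in the class
    arrays). Returns (class arrays, boundaries).
    """
    pooled = np.concatenate([np.asarray(r, dtype=float).ravel() for r in raster_set])
    pooled = pooled[~np.isnan(pooled)]
    if pooled.size == 0:
        raise ValueError("no finite values to scale")
    if np.ptp(pooled) == 0.0:
        warnings.warn("constant pooled values; single decile class")
        bounds = np.full(9, pooled[0])
    else:
        bounds = np.quantile(pooled, np.arange(1, 10) / 10.0)
    out = []
    for r in raster_set:
        arr = np.asarray(r, dtype=float)
        # ties at a boundary fall in the lower class (right-open intervals)
        cls = 1 + np.searchsorted(bounds, arr, side="left")
        cls = np.where(np.isnan(arr), 0, cls).astype(int)
        out.append(cls)
    return out, bounds
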