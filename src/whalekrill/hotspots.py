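"""Getis-Ord Gi* hotspots, FDR masking, persistence, AB-ratio overlap.

For each monthly prediction raster the local Gi* statistic is computed
with a binary fixed-band neighbourhood (self included, 3 km by default —
the survey bin scale):

    Gi* zᵢ = [Σⱼ wᵢⱼ xⱼ − X̄ Wᵢ] / (S · √[(n Σⱼ wᵢⱼ² − Wᵢ²) / (n − 1)])

with global mean X̄ and SD S over the raster's n unmasked cells. Cell
p-values are Benjamini-Hochberg adjusted within the raster and the
hotspot mask keeps cells with positive z and adjusted p < 0.05. Masked
z-scores are rescaled to [0, 1] per raster and summed over months into a
persistence surface (range 0..M for M months).

Trophic overlap uses the AB ratio: spatial covariance of the predator and
prey fields divided by the product of their means; its local (per-cell)
decomposition averages back to the global value exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats
from statsmodels.stats.multitest import multipletests


@dataclass
class WeightSpec:
    """Gi* neighbourhood: binary band (km) or inverse distance, self included."""

    scheme: str = "fixed_band"  # fixed_band | inverse_distance
    band_km: float = 3.0
    cell_km: float = 1.0

    def __post_init__(self) -> None:
        if self.band_km <= 0:
            raise ValueError("band must be positive")
        if self.scheme not in ("fixed_band", "inverse_distance"):
            raise ValueError(f"unknown weight scheme {self.scheme!r}")

    def kernel(self) -> np.ndarray:
        r = int(np.floor(self.band_km / self.cell_km))
        ax = np.arange(-r, r + 1) * self.cell_km
        dx, dy = np.meshgrid(ax, ax)
        d = np.hypot(dx, dy)
        if self.scheme == "fixed_band":
            return (d <= self.band_km).astype(float)
        with np.errstate(divide="ignore"):
            k = np.where(d > 0, self.cell_km / d, 1.0)  # self weight 1
        k[d > self.band_km] = 0.0
        return k


@dataclass
class HotspotRaster:
    """Per-month Gi* output with FDR mask and normalized z."""

    label: object
    z: np.ndarray
    p: np.ndarray
    p_adj: np.ndarray
    mask: np.ndarray  # True = significant positive-z hotspot cell
    norm_z: np.ndarray  # masked z rescaled to [0, 1], 0 elsewhere
    constant: bool = False


def getis_ord_gstar(
    raster: np.ndarray, weights: WeightSpec | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Gi* z-score and two-sided normal p per cell.

    NaN cells are excluded from the statistic and returned as NaN. A
    constant raster has S = 0; z is defined as 0 everywhere and flagged
    via a warning.
    """
    weights = weights or WeightSpec()
    x = np.asarray(raster, dtype=float)
    valid = ~np.isnan(x)
    n = int(valid.sum())
    if n < 9:
        raise ValueError(f"need >= 9 unmasked cells, got {n}")
    xbar = x[valid].mean()
    s = x[valid].std(ddof=0)
    if s == 0.0:
        warnings.warn("constant raster: Gi* z defined as 0 everywhere")
        z = np.where(valid, 0.0, np.nan)
        return z, np.where(valid, 1.0, np.nan)
    k = weights.kernel()
    filled = np.where(valid, x, 0.0)
    vm = valid.astype(float)
    wx = ndimage.convolve(filled, k, mode="constant", cval=0.0)
    wsum = ndimage.convolve(vm, k, mode="constant", cval=0.0)
    w2sum = ndimage.convolve(vm, k**2, mode="constant", cval=0.0)
    denom_inner = (n * w2sum - wsum**2) / (n - 1)
    denom = s * np.sqrt(np.maximum(denom_inner, 0.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (wx - xbar * wsum) / denom
    z = np.where(valid, z, np.nan)
    z = np.where(valid & (denom == 0.0), 0.0, z)  # whole-raster neighbourhood
    p = np.where(valid, 2.0 * stats.norm.sf(np.abs(z)), np.nan)
    return z, p


def fdr_mask(
    z: np.ndarray, p: np.ndarray, alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg adjustment within one raster.

    Returns (mask, adjusted p); mask = positive z AND adjusted p < alpha.
    """
    z = np.asarray(z, dtype=float)
    p = np.asarray(p, dtype=float)
    p_adj = np.full(p.shape, np.nan)
    valid = ~np.isnan(p)
    if valid.sum() == 0:
        return np.zeros(p.shape, dtype=bool), p_adj
    _, adj, _, _ = multipletests(p[valid].ravel(), alpha=alpha, method="fdr_bh")
    p_adj[valid] = adj
    mask = valid & (z > 0) & (p_adj < alpha)
    return mask, p_adj


def hotspot_raster(
    raster: np.ndarray,
    label: object = None,
    weights: WeightSpec | None = None,
    alpha: float = 0.05,
) -> HotspotRaster:
    """Full per-month chain: Gi*, BH-FDR mask, [0, 1] rescaled z."""
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        z, p = getis_ord_gstar(raster, weights)
    constant = any("constant raster" in str(w.message) for w in caught)
    mask, p_adj = fdr_mask(z, p, alpha)
    norm = np.zeros(z.shape)
    if mask.any():
        zm = z[mask]
        lo, hi = zm.min(), zm.max()
        norm[mask] = 1.0 if lo == hi else 0.0  # single-cell mask -> 1
        if hi > lo:
            norm[mask] = (zm - lo) / (hi - lo)
    return HotspotRaster(label, z, p, p_adj, mask, norm, constant)


def persistence_sum(rasters: list[HotspotRaster]) -> np.ndarray:
    """Sum of per-month normalized masked z; range 0..len(rasters)."""
    if not rasters:
        raise ValueError("no hotspot rasters")
    shape = rasters[0].norm_z.shape
    for r in rasters:
        if r.norm_z.shape != shape:
            raise ValueError("hotspot rasters are on misaligned grids")
    return np.sum([r.norm_z for r in rasters], axis=0)


# --------------------------------------------------------------------------
# AB-ratio trophic overlap


def _check_pair(pred: np.ndarray, prey: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(pred, dtype=float)
    b = np.asarray(prey, dtype=float)
    if a.shape != b.shape:
        raise ValueError("predator and prey rasters are on misaligned grids")
    both = ~(np.isnan(a) | np.isnan(b))
    if np.any(a[both] < 0) or np.any(b[both] < 0):
        raise ValueError("abundance fields must be non-negative")
    return a, b


def ab_ratio_global(predator: np.ndarray, prey: np.ndarray) -> float:
    """AB = mean[(pᵢ−p̄)(bᵢ−b̄)] / (p̄·b̄) over shared unmasked cells."""
    a, b = _check_pair(predator, prey)
    both = ~(np.isnan(a) | np.isnan(b))
    av, bv = a[both], b[both]
    if av.mean() == 0.0 or bv.mean() == 0.0:
        warnings.warn("AB ratio undefined (a field has zero mean)")
        return np.nan
    num = np.mean((av - av.mean()) * (bv - bv.mean()))
    return float(num / (av.mean() * bv.mean()))


def ab_ratio_local(predator: np.ndarray, prey: np.ndarray) -> np.ndarray:
    """Local ABᵢ = (pᵢ−p̄)(bᵢ−b̄)/(p̄·b̄); its cellwise mean is the global AB."""
    a, b = _check_pair(predator, prey)
    both = ~(np.isnan(a) | np.isnan(b))
    av, bv = a[both], b[both]
    if av.mean() == 0.0 or bv.mean() == 0.0:
        warnings.warn("AB ratio undefined (a field has zero mean)")
        return np.full(a.shape, np.nan)
    out = np.full(a.shape, np.nan)
    out[both] = (a[both] - av.mean()) * (b[both] - bv.mean()) / (av.mean() * bv.mean())
    return out


def temporal_mean_sd(local_rasters: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Cellwise mean and SD (n−1 denominator) of local AB rasters over time."""
    if len(local_rasters) < 2:
        raise ValueError("need >= 2 months for a temporal SD")
    stack = np.stack([np.asarray(r, dtype=float) for r in local_rasters])
    return np.nanmean(stack, axis=0), np.nanstd(stack, axis=0, ddof=1)
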