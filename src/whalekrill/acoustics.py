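"""Acoustic krill biomass conversion.

Per-bin area backscatter (s_A, m²/m²) is apportioned over a trawl-derived
length-frequency distribution, divided by per-length individual
backscattering cross-sections σ_bs (supplied — target-strength modeling is
upstream of this package), and multiplied by the length-weight relationship

    M(L) = 0.0002 L² − 0.0017 L + 0.005   [grams, L in mm]

to yield areal biomass density (g/m²):

    N = s_A / Σ_l f_l σ_bs,l      (individuals / m²)
    B = N · Σ_l f_l M(L_l)        (g / m²)

Along-track integrations are then accumulated into 3-km bins carrying the
acoustic sampling effort (summed cell volume), whose log is the offset of
the krill count model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

LW_COEFFS = (0.0002, -0.0017, 0.005)  # quadratic length-weight, g vs mm
LENGTH_SPAN_MM = (8.0, 30.0)


def length_weight(length_mm) -> np.ndarray | float:
    """Krill mass (g) from length (mm) via the quadratic length-weight fit.

    Raises if any result is non-positive (occurs for lengths ~3.5-5 mm,
    outside the 8-30 mm modeled span).
    """
    scalar = np.isscalar(length_mm)
    L = np.asarray(length_mm, dtype=float)
    if np.any(L < 0):
        raise ValueError("length must be non-negative")
    a, b, c = LW_COEFFS
    m = a * L**2 + b * L + c
    if np.any(m <= 0):
        bad = np.atleast_1d(L)[np.atleast_1d(m) <= 0]
        raise ValueError(
            f"length-weight relationship non-positive at L={bad.tolist()} mm; "
            f"lengths outside the {LENGTH_SPAN_MM} mm modeled span"
        )
    return float(m) if scalar else m


@dataclass
class LengthFrequency:
    """Trawl length-frequency distribution over a common length grid."""

    lengths_mm: np.ndarray
    proportions: np.ndarray

    def __post_init__(self) -> None:
        self.lengths_mm = np.asarray(self.lengths_mm, dtype=float)
        self.proportions = np.asarray(self.proportions, dtype=float)
        if self.lengths_mm.shape != self.proportions.shape:
            raise ValueError("lengths and proportions must align")
        if not np.all(np.diff(self.lengths_mm) > 0):
            raise ValueError("lengths must be strictly increasing")
        if abs(self.proportions.sum() - 1.0) > 1e-9:
            raise ValueError(
                f"proportions sum to {self.proportions.sum()}, expected 1"
            )
        if np.any(self.proportions < 0):
            raise ValueError("proportions must be non-negative")

    @classmethod
    def uniform(cls, n_classes: int = 12) -> "LengthFrequency":
        lo, hi = LENGTH_SPAN_MM
        lengths = np.linspace(lo, hi, n_classes)
        return cls(lengths, np.full(n_classes, 1.0 / n_classes))


@dataclass
class CrossSectionTable:
    """Per-length individual backscattering cross-sections σ_bs (m²)."""

    lengths_mm: np.ndarray
    sigma_bs: np.ndarray

    def __post_init__(self) -> None:
        self.lengths_mm = np.asarray(self.lengths_mm, dtype=float)
        self.sigma_bs = np.asarray(self.sigma_bs, dtype=float)
        if self.lengths_mm.shape != self.sigma_bs.shape:
            raise ValueError("lengths and sigma_bs must align")
        if np.any(self.sigma_bs <= 0):
            raise ValueError("sigma_bs must be positive")
        if np.any(np.diff(self.sigma_bs) < 0):
            warnings.warn("sigma_bs not monotone non-decreasing with length")

    @classmethod
    def default(cls, lengths_mm: np.ndarray | None = None) -> "CrossSectionTable":
        """Packaged synthetic table over 8-30 mm: σ_bs ∝ L², anchored at
        1e-6 m² for a 20-mm animal (a plausible scattering magnitude; the
        physics-based target-strength model is out of scope here)."""
        if lengths_mm is None:
            lengths_mm = LengthFrequency.uniform().lengths_mm
        lengths_mm = np.asarray(lengths_mm, dtype=float)
        return cls(lengths_mm, 1e-6 * (lengths_mm / 20.0) ** 2)


def biomass_from_backscatter(
    area_backscatter, lf: LengthFrequency, xs: CrossSectionTable
):
    """Convert area backscatter s_A (m²/m²) to krill biomass (g/m²).

    Linear in s_A. The length grids of ``lf`` and ``xs`` must agree.
    """
    if lf.lengths_mm.shape != xs.lengths_mm.shape or not np.allclose(
        lf.lengths_mm, xs.lengths_mm
    ):
        raise ValueError(
            "length-frequency and cross-section tables must share a length grid"
        )
    denom = float(np.sum(lf.proportions * xs.sigma_bs))
    if denom == 0.0:
        raise ValueError("mean backscattering cross-section is zero")
    mean_mass = float(np.sum(lf.proportions * length_weight(lf.lengths_mm)))
    sa = np.asarray(area_backscatter, dtype=float)
    if np.any(sa < 0):
        raise ValueError("backscatter must be non-negative")
    out = sa / denom * mean_mass
    return float(out) if np.isscalar(area_backscatter) else out


def backscatter_from_biomass(biomass_gm2, lf: LengthFrequency, xs: CrossSectionTable):
    """Invert the biomass conversion (used to synthesize backscatter)."""
    unit = biomass_from_backscatter(1.0, lf, xs)
    return np.asarray(biomass_gm2, dtype=float) / unit


def bin_acoustics(
    samples: pd.DataFrame,
    lf: LengthFrequency,
    xs: CrossSectionTable,
    bin_km: float = 3.0,
    cell_volume_m3: float = 3000.0,
) -> pd.DataFrame:
    """Accumulate along-track integrations into fixed-length bins.

    ``samples`` columns: distance_km (along track), sa (area backscatter,
    m²/m²), cell_count (vertical cells integrated), area_m2 (footprint of
    the integration interval). Surface (0-5 m) and bottom-adjacent cells
    are excluded upstream. Bins with zero sampled cells are dropped with a
    warning. Returns one row per bin: bin_index, biomass_g, mean g/m²,
    cell_count, acoustic_volume_m3, log_volume (the model offset).
    """
    required = {"distance_km", "sa", "cell_count", "area_m2"}
    missing = required - set(samples.columns)
    if missing:
        raise ValueError(f"samples missing columns: {sorted(missing)}")
    cols = [
        "bin_index", "biomass_g", "density_gm2",
        "cell_count", "acoustic_volume_m3", "log_volume",
    ]
    if len(samples) == 0:
        return pd.DataFrame(columns=cols)
    df = samples.copy()
    df["bin_index"] = (df["distance_km"] // bin_km).astype(int)
    df["density_gm2"] = biomass_from_backscatter(df["sa"].to_numpy(), lf, xs)
    df["biomass_g"] = df["density_gm2"] * df["area_m2"]
    rows = []
    for b, grp in df.groupby("bin_index", sort=True):
        cells = int(grp["cell_count"].sum())
        if cells == 0:
            warnings.warn(f"bin {b} has zero sampled acoustic cells; excluded")
            continue
        area = float(grp["area_m2"].sum())
        total = float(grp["biomass_g"].sum())
        volume = cells * cell_volume_m3
        rows.append(
            dict(
                bin_index=int(b),
                biomass_g=total,
                density_gm2=total / area if area > 0 else np.nan,
                cell_count=cells,
                acoustic_volume_m3=volume,
                log_volume=np.log(volume),
            )
        )
    return pd.DataFrame(rows, columns=cols) if rows else pd.DataFrame(columns=cols)
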