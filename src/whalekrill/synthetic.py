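"""Synthetic study system with known ground truth.

Emulates a multi-year shipboard survey of krill and whales in a small
coastal upwelling region: a 1-km² planar study grid with bathymetric and
distance covariates, east-west transects cut into 3-km effort bins,
spatially autocorrelated oceanographic fields at two depth layers,
AR(1) monthly climate-index series, acoustic krill biomass drawn from a
Bernoulli × zero-truncated-negative-binomial hurdle with a log-volume
effort offset, and whale counts drawn from an NB2 with a log-area offset.

Every output is a pure function of the generating spec and seed, and the
spec (`TruthSpec`) is serialized alongside each dataset so parameter
recovery can be tested downstream.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.stats import nbinom
from shapely import LineString, Point, distance as shp_distance

from .terms import linear_predictor

OCEAN_VARS = (
    "temp_surface",
    "temp_mid",
    "sal_surface",
    "sal_mid",
    "fluor_surface",
    "fluor_mid",
)
DISTANCE_VARS = ("dist_mainland", "dist_island", "dist_cordell", "dist_200m")
BATHY_VARS = DISTANCE_VARS + ("depth", "contour_index")
CLIMATE_INDICES = ("soi", "pdo", "npgo", "ui")
SURVEY_MONTHS = (5, 6, 7, 9)  # May, Jun, Jul, Sep; Apr/Aug/Oct unsampled
N_LAGS = 4  # current month plus 1-3 month lags


# --------------------------------------------------------------------------
# Study grid


@dataclass
class FeatureSpec:
    """Synthetic geographic features, all in planar km coordinates.

    Lines are vertex sequences; distances are Euclidean point-to-geometry.
    """

    coastline: list[tuple[float, float]]
    island: tuple[float, float]
    cordell: tuple[float, float]
    isobath_200m: list[tuple[float, float]]

    @classmethod
    def default(cls, extent_km: tuple[float, float]) -> "FeatureSpec":
        lx, ly = extent_km
        return cls(
            coastline=[(lx, 0.0), (lx, ly)],  # mainland along the east edge
            island=(0.55 * lx, 0.25 * ly),
            cordell=(0.45 * lx, 0.75 * ly),
            isobath_200m=[(0.35 * lx, 0.0), (0.35 * lx, ly)],  # shelf break
        )


@dataclass
class StudyGrid:
    """1-km² (by default) prediction grid with static covariates.

    ``cells`` has one row per cell: cell_id, x, y (midpoint km), depth (m),
    contour_index (0-100), and the four feature distances (km). Cell ids
    run row-major from the south-west corner.
    """

    cells: pd.DataFrame
    nx: int
    ny: int
    cell_km: float
    extent_km: tuple[float, float]
    features: FeatureSpec

    def __len__(self) -> int:
        return len(self.cells)

    @property
    def xy(self) -> np.ndarray:
        return self.cells[["x", "y"]].to_numpy()

    def raster(self, values) -> np.ndarray:
        """Reshape a cell-ordered vector to a 2-D array, row 0 = north."""
        arr = np.asarray(values, dtype=float).reshape(self.ny, self.nx)
        return np.flipud(arr)

    def cell_index(self, x, y) -> np.ndarray:
        """Row-major cell ids of the cells containing points (x, y)."""
        ix = np.clip((np.asarray(x) / self.cell_km).astype(int), 0, self.nx - 1)
        iy = np.clip((np.asarray(y) / self.cell_km).astype(int), 0, self.ny - 1)
        return iy * self.nx + ix


def make_study_grid(
    extent_km: tuple[float, float] = (30.0, 30.0),
    cell_km: float = 1.0,
    feature_spec: FeatureSpec | None = None,
) -> StudyGrid:
    """Build the study grid with depth, contour index and feature distances.

    Depth follows a shelf profile deepening westward (offshore), crossing
    200 m at the 200-m isobath line, with a shoal at the bank feature.
    Contour index is (max depth - min depth) / max depth over the 3x3 cell
    neighbourhood, scaled to 0-100.
    """
    lx, ly = float(extent_km[0]), float(extent_km[1])
    if lx <= cell_km or ly <= cell_km:
        raise ValueError(
            f"degenerate extent {extent_km}: need more than one cell per axis"
        )
    nx, ny = round(lx / cell_km), round(ly / cell_km)
    if not (np.isclose(nx * cell_km, lx) and np.isclose(ny * cell_km, ly)):
        raise ValueError(f"extent {extent_km} is not divisible by cell size {cell_km}")
    feats = feature_spec or FeatureSpec.default((lx, ly))

    xs = (np.arange(nx) + 0.5) * cell_km
    ys = (np.arange(ny) + 0.5) * cell_km
    xg, yg = np.meshgrid(xs, ys)  # row-major, south row first
    x, y = xg.ravel(), yg.ravel()

    coast = LineString(feats.coastline)
    isobath = LineString(feats.isobath_200m)
    island = Point(feats.island)
    cordell = Point(feats.cordell)
    pts = [Point(px, py) for px, py in zip(x, y)]
    dist_mainland = np.array([shp_distance(p, coast) for p in pts])
    dist_island = np.array([shp_distance(p, island) for p in pts])
    dist_cordell = np.array([shp_distance(p, cordell) for p in pts])
    dist_200m = np.array([shp_distance(p, isobath) for p in pts])

    depth = _shelf_depth(x, y, feats, lx)
    contour = _contour_index(depth.reshape(ny, nx)).ravel()

    cells = pd.DataFrame(
        {
            "cell_id": np.arange(nx * ny),
            "x": x,
            "y": y,
            "depth": depth,
            "contour_index": contour,
            "dist_mainland": dist_mainland,
            "dist_island": dist_island,
            "dist_cordell": dist_cordell,
            "dist_200m": dist_200m,
        }
    )
    return StudyGrid(cells, nx, ny, cell_km, (lx, ly), feats)


def _shelf_depth(x, y, feats: FeatureSpec, lx: float) -> np.ndarray:
    """Monotone-offshore shelf/slope profile with a shoal at the bank."""
    x_iso = feats.isobath_200m[0][0]
    x_coast = max(px for px, _ in feats.coastline)
    # 10 m at the coast, 200 m at the isobath, ~2000 m at the west edge
    shelf = 10.0 + (200.0 - 10.0) * np.clip((x_coast - x) / (x_coast - x_iso), 0, None)
    slope = np.clip((x_iso - x) / max(x_iso, 1e-9), 0, 1)
    depth = np.where(x >= x_iso, shelf, 200.0 + 1800.0 * slope**1.5)
    bx, by = feats.cordell
    bump = 140.0 * np.exp(-(((x - bx) ** 2 + (y - by) ** 2)) / (2 * 2.0**2))
    return np.maximum(depth - bump, 5.0)


def _contour_index(depth2d: np.ndarray) -> np.ndarray:
    ny, nx = depth2d.shape
    padded = np.pad(depth2d, 1, mode="edge")
    stacks = [
        padded[i : i + ny, j : j + nx] for i in range(3) for j in range(3)
    ]
    local = np.stack(stacks)
    ci = 100.0 * (local.max(axis=0) - local.min(axis=0)) / local.max(axis=0)
    return np.clip(ci, 0.0, 100.0)


# --------------------------------------------------------------------------
# Gaussian random fields


def simulate_field(
    points,
    sill: float,
    range_km: float,
    nugget: float = 0.0,
    trend_coeffs: dict[str, float] | None = None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Draw one realization of a stationary isotropic Gaussian field.

    Exponential covariance C(h) = (sill - nugget) * exp(-h / range_km) with
    a nugget on the diagonal; ``sill`` is the total sill. ``trend_coeffs``
    adds a polynomial mean over keys from {"1","x","y","x^2","x*y","y^2"}.
    ``points`` is an (n, 2) array or a StudyGrid (its cell midpoints).
    """
    if isinstance(points, StudyGrid):
        points = points.xy
    points = np.asarray(points, dtype=float)
    if sill < 0 or nugget < 0 or sill < nugget:
        raise ValueError("need sill >= nugget >= 0")
    if range_km <= 0:
        raise ValueError("range_km must be positive")
    rng = rng if rng is not None else np.random.default_rng(seed)

    n = len(points)
    mean = _trend(points, trend_coeffs)
    psill = sill - nugget
    if sill == 0.0:
        return mean.copy()
    cov = psill * np.exp(-cdist(points, points) / range_km)
    cov[np.diag_indices(n)] += nugget
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise ValueError(
            "covariance construction is not positive definite for "
            f"sill={sill}, range_km={range_km}, nugget={nugget}"
        ) from exc
    return mean + chol @ rng.standard_normal(n)


def _trend(points: np.ndarray, coeffs: dict[str, float] | None) -> np.ndarray:
    out = np.zeros(len(points))
    if not coeffs:
        return out
    x, y = points[:, 0], points[:, 1]
    basis = {"1": 1.0, "x": x, "y": y, "x^2": x * x, "x*y": x * y, "y^2": y * y}
    for key, c in coeffs.items():
        if key not in basis:
            raise ValueError(f"unknown trend basis term {key!r}")
        out = out + c * basis[key]
    return out


def simulate_climate(
    n_months: int,
    ar_coeff: float,
    sd: float,
    seed: int | None = None,
    mean: float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Stationary AR(1) monthly index series with innovation SD ``sd``."""
    if abs(ar_coeff) >= 1:
        raise ValueError(f"nonstationary AR coefficient {ar_coeff}")
    if sd < 0:
        raise ValueError("sd must be non-negative")
    rng = rng if rng is not None else np.random.default_rng(seed)
    x = np.empty(n_months)
    marginal_sd = sd / np.sqrt(1 - ar_coeff**2) if sd > 0 else 0.0
    x[0] = mean + marginal_sd * rng.standard_normal()
    eps = sd * rng.standard_normal(n_months - 1)
    for t in range(1, n_months):
        x[t] = mean + ar_coeff * (x[t - 1] - mean) + eps[t - 1]
    return x


# --------------------------------------------------------------------------
# Cruise calendar and climate context


@dataclass
class CruiseContext:
    """One survey cruise: identity, timing, and lagged climate indices."""

    cruise_id: str
    year: int
    month: int
    climate: dict[str, list[float]]  # index -> [lag0, lag1, lag2, lag3]

    def __post_init__(self) -> None:
        if self.month not in SURVEY_MONTHS:
            raise ValueError(f"month {self.month} outside survey months {SURVEY_MONTHS}")
        for name, lags in self.climate.items():
            if len(lags) != N_LAGS:
                raise ValueError(f"climate index {name!r} needs {N_LAGS} lag values")

    def climate_columns(self) -> dict[str, float]:
        return {
            f"{name}_lag{l}": self.climate[name][l]
            for name in self.climate
            for l in range(N_LAGS)
        }


def make_cruise_calendar(
    n_cruises: int = 41,
    start_year: int = 2004,
    months: tuple[int, ...] = SURVEY_MONTHS,
    climate_params: dict[str, dict[str, float]] | None = None,
    seed: int = 0,
) -> list[CruiseContext]:
    """Build cruises cycling through survey months from ``start_year`` on,
    with AR(1) climate series generated for the whole span and matched to
    each cruise month at lags 0-3.
    """
    climate_params = climate_params or DEFAULT_CLIMATE_PARAMS
    n_years = (n_cruises + len(months) - 1) // len(months)
    total_months = (n_years + 1) * 12
    rng = np.random.default_rng(seed)
    series = {
        name: simulate_climate(
            total_months, p["ar"], p["sd"], mean=p.get("mean", 0.0), rng=rng
        )
        for name, p in climate_params.items()
    }
    cruises = []
    for k in range(n_cruises):
        year = start_year + k // len(months)
        month = months[k % len(months)]
        # absolute month index into the series; offset 12 leaves room for lags
        t = 12 + (year - start_year) * 12 + (month - 1)
        climate = {
            name: [float(series[name][t - l]) for l in range(N_LAGS)]
            for name in series
        }
        cruises.append(CruiseContext(f"C{k:03d}", year, month, climate))
    return cruises


DEFAULT_CLIMATE_PARAMS: dict[str, dict[str, float]] = {
    # AR coefficient, innovation SD and mean chosen so the marginal mean/SD
    # sit near the observed monthly index summaries (~0 +- 1-2 for
    # SOI/PDO/NPGO, ~191 +- 81 for the upwelling index)
    "soi": dict(ar=0.6, sd=1.4, mean=0.1),
    "pdo": dict(ar=0.8, sd=0.7, mean=0.0),
    "npgo": dict(ar=0.8, sd=0.65, mean=0.2),
    "ui": dict(ar=0.5, sd=70.0, mean=191.0),
}


def centered_quadratic(name: str, center: float, curvature: float) -> dict[str, float]:
    """Coefficients for -curvature * (x - center)^2 expanded on the raw
    scale, i.e. a dome-shaped response peaking (at 0) at ``center``.

    Returns a {term: coef} dict including the intercept contribution, to be
    merged into a linear predictor with :func:`merge_coefs`.
    """
    return {
        "1": -curvature * center**2,
        name: 2.0 * curvature * center,
        f"{name}^2": -curvature,
    }


def merge_coefs(*parts: dict[str, float]) -> dict[str, float]:
    """Merge {term: coef} dicts, summing shared terms (e.g. intercepts)."""
    out: dict[str, float] = {}
    for part in parts:
        for term, coef in part.items():
            out[term] = out.get(term, 0.0) + coef
    return out


# --------------------------------------------------------------------------
# Ground truth


@dataclass
class TruthSpec:
    """Generating parameters for one synthetic dataset.

    Coefficient dicts map design terms (see :mod:`whalekrill.terms`) to
    values; `"1"` is the intercept. Offsets are implicit: log acoustic
    volume for the krill count part, log survey area for whales.
    """

    field_params: dict[str, dict[str, float]]
    climate_params: dict[str, dict[str, float]]
    krill_presence: dict[str, float]
    krill_count: dict[str, float]
    krill_theta: float
    whale_coefs: dict[str, dict[str, float]]
    whale_theta: dict[str, float]
    cell_volume_m3: float = 3000.0
    mean_cells_per_bin: float = 266.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.krill_theta <= 0 or any(t <= 0 for t in self.whale_theta.values()):
            raise ValueError("dispersion theta must be positive")
        for var, p in self.field_params.items():
            if p["sill"] < p["nugget"] or p["nugget"] < 0:
                raise ValueError(f"{var}: need sill >= nugget >= 0")
            if p["range_km"] <= 0:
                raise ValueError(f"{var}: range must be positive")

    @classmethod
    def default(cls, seed: int = 0) -> "TruthSpec":
        """Smallest truth exercising every selection pathway per species:
        one quadratic oceanographic term, one distance term, one lagged
        climate term. Magnitudes give a ~79% krill presence rate and whale
        encounter rates near the 3% (blue) / 16% (humpback) presence rates
        of a ~4,000-bin survey.
        """
        field_params = {
            "temp_surface": dict(mean=12.6, sill=2.0, range_km=8.0, nugget=0.05),
            "temp_mid": dict(mean=10.2, sill=0.8, range_km=8.0, nugget=0.02),
            "sal_surface": dict(mean=33.4, sill=0.06, range_km=8.0, nugget=0.002),
            "sal_mid": dict(mean=33.6, sill=0.04, range_km=8.0, nugget=0.001),
            "fluor_surface": dict(mean=9.0, sill=8.0, range_km=6.0, nugget=0.2),
            "fluor_mid": dict(mean=3.2, sill=2.0, range_km=6.0, nugget=0.05),
        }
        return cls(
            field_params=field_params,
            climate_params={k: dict(v) for k, v in DEFAULT_CLIMATE_PARAMS.items()},
            krill_presence=merge_coefs(
                {"1": 2.3, "dist_200m": -0.12, "soi_lag1": 0.35},
                centered_quadratic("temp_mid", 10.2, 0.5),
            ),
            krill_count=merge_coefs(
                {"1": -7.55, "dist_200m": -0.06, "ui_lag1": 0.004},
                centered_quadratic("fluor_mid", 3.2, 0.09),
            ),
            krill_theta=1.5,
            whale_coefs={
                "blue": merge_coefs(
                    {"1": -4.05, "dist_200m": -0.15, "soi_lag3": 0.3},
                    centered_quadratic("temp_surface", 12.6, 0.18),
                ),
                "humpback": merge_coefs(
                    {"1": -3.25, "dist_200m": -0.08, "ui_lag3": 0.003},
                    centered_quadratic("temp_surface", 12.6, 0.12),
                ),
            },
            whale_theta={"blue": 1.0, "humpback": 1.2},
            seed=seed,
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "TruthSpec":
        with open(path) as fh:
            raw = json.load(fh)
        raw["whale_theta"] = {k: float(v) for k, v in raw["whale_theta"].items()}
        return cls(**raw)


# Detection condition lookup: class tuple -> (esw_km, g0). Detection-function
# fitting is out of scope; conditions map to supplied values.
DETECTION_TABLE: dict[tuple[str, str], tuple[float, float]] = {
    ("calm", "good"): (2.0, 0.95),
    ("calm", "fair"): (1.7, 0.90),
    ("moderate", "good"): (1.6, 0.88),
    ("moderate", "fair"): (1.3, 0.82),
    ("rough", "good"): (1.1, 0.75),
    ("rough", "fair"): (0.9, 0.65),
}
SEA_STATES = ("calm", "moderate", "rough")
VISIBILITIES = ("good", "fair")
SWELLS = ("low", "medium", "high")


class FieldSimulator:
    """Draws the six oceanographic fields on a grid, factoring each
    covariance once and reusing it across cruises."""

    def __init__(self, grid: StudyGrid, field_params: dict[str, dict[str, float]]):
        self.grid = grid
        self.params = field_params
        self._chol: dict[str, np.ndarray | None] = {}
        pts = grid.xy
        d = cdist(pts, pts)
        for var, p in field_params.items():
            psill = p["sill"] - p["nugget"]
            if p["sill"] == 0:
                self._chol[var] = None
                continue
            cov = psill * np.exp(-d / p["range_km"])
            cov[np.diag_indices(len(pts))] += p["nugget"]
            self._chol[var] = np.linalg.cholesky(cov)

    def draw(self, var: str, rng: np.random.Generator) -> np.ndarray:
        p = self.params[var]
        mean = p.get("mean", 0.0)
        chol = self._chol[var]
        if chol is None:
            return np.full(len(self.grid), mean)
        return mean + chol @ rng.standard_normal(len(self.grid))


# --------------------------------------------------------------------------
# Observations


def simulate_observations(
    grid: StudyGrid,
    cruises: list[CruiseContext],
    truth: TruthSpec,
    seed: int | None = None,
    bin_km: float = 3.0,
    line_spacing_km: float = 3.0,
    min_bin_km: float = 1.0,
) -> pd.DataFrame:
    """Simulate the full bin table for a set of cruises.

    Transects run east-west at ``line_spacing_km`` spacing and are cut into
    ``bin_km`` segments; the final segment of each line has a random
    truncated length and is discarded when shorter than ``min_bin_km``.
    Krill biomass (integer grams) follows the hurdle
    Bernoulli(logit^-1(X gamma)) x ZTNB(exp(X beta + log volume), theta);
    whale counts follow NB2(exp(X beta + log area), theta).
    """
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    sim = FieldSimulator(grid, truth.field_params)
    frames = [
        _simulate_cruise(grid, cruise, truth, sim, rng, bin_km, line_spacing_km, min_bin_km)
        for cruise in cruises
    ]
    bins = pd.concat(frames, ignore_index=True)
    bins["bin_id"] = [f"B{i:05d}" for i in range(len(bins))]
    return bins


def _simulate_cruise(grid, cruise, truth, sim, rng, bin_km, spacing, min_bin_km):
    lx, ly = grid.extent_km
    rows = []
    line_ys = np.arange(spacing / 2, ly, spacing)
    for y0 in line_ys:
        n_full = int(lx // bin_km)
        tail = rng.uniform(0, bin_km)
        lengths = [bin_km] * max(n_full - 1, 0) + [tail]
        start = 0.0
        for length in lengths:
            if length >= min_bin_km:
                rows.append((start + length / 2, y0, length))
            start += length
    mid = pd.DataFrame(rows, columns=["x", "y", "length_km"])
    n = len(mid)

    cells = grid.cells.iloc[grid.cell_index(mid["x"], mid["y"])].reset_index(drop=True)
    df = pd.concat([mid, cells[list(BATHY_VARS)].reset_index(drop=True)], axis=1)
    df.insert(0, "cruise_id", cruise.cruise_id)
    df.insert(1, "year", cruise.year)
    df.insert(2, "month", cruise.month)

    for var in OCEAN_VARS:
        field = sim.draw(var, rng)
        df[var] = field[grid.cell_index(mid["x"], mid["y"])]
    for col, val in cruise.climate_columns().items():
        df[col] = val

    # detection conditions constant within cruise (weather), esw/g0 by lookup
    sea = SEA_STATES[rng.integers(len(SEA_STATES))]
    vis = VISIBILITIES[rng.integers(len(VISIBILITIES))]
    df["sea_state"] = sea
    df["swell"] = SWELLS[rng.integers(len(SWELLS))]
    df["visibility"] = vis
    esw, g0 = DETECTION_TABLE[(sea, vis)]
    df["esw_km"] = esw
    df["g0"] = g0
    df["survey_area_km2"] = 2.0 * df["length_km"] * esw

    counts = np.clip(rng.poisson(truth.mean_cells_per_bin, n), 1, None)
    df["acoustic_cell_count"] = counts
    df["acoustic_volume_m3"] = counts * truth.cell_volume_m3

    # krill hurdle
    p = _sigmoid(linear_predictor(df, truth.krill_presence))
    present = rng.uniform(size=n) < p
    mu = np.exp(
        linear_predictor(df, truth.krill_count) + np.log(df["acoustic_volume_m3"])
    )
    biomass = np.zeros(n, dtype=int)
    biomass[present] = sample_ztnb(mu[present], truth.krill_theta, rng)
    df["krill_biomass_g"] = biomass

    for species, coefs in truth.whale_coefs.items():
        mu_w = np.exp(linear_predictor(df, coefs) + np.log(df["survey_area_km2"]))
        theta = truth.whale_theta[species]
        df[f"{species}_count"] = rng.negative_binomial(theta, theta / (theta + mu_w))
    return df


def _sigmoid(eta: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-eta))


def sample_ztnb(mu, theta, rng: np.random.Generator) -> np.ndarray:
    """Zero-truncated NB2 draws by inverse CDF above the zero mass."""
    mu = np.asarray(mu, dtype=float)
    p = theta / (theta + mu)
    p0 = nbinom.cdf(0, theta, p)
    u = p0 + (1 - p0) * rng.uniform(size=mu.shape)
    y = nbinom.ppf(np.minimum(u, 1 - 1e-16), theta, p).astype(int)
    return np.maximum(y, 1)


def expected_values(bins: pd.DataFrame, truth: TruthSpec) -> pd.DataFrame:
    """Per-bin expected values implied by the truth (for recovery tests).

    Columns: krill_presence_p, krill_count_mu (ZTNB latent mean, includes
    offset), krill_mean (hurdle mean p*mu/(1-NB0)), and per-species
    whale_mean.
    """
    out = pd.DataFrame(index=bins.index)
    p = _sigmoid(linear_predictor(bins, truth.krill_presence))
    mu = np.exp(
        linear_predictor(bins, truth.krill_count)
        + np.log(bins["acoustic_volume_m3"])
    )
    nb0 = (truth.krill_theta / (truth.krill_theta + mu)) ** truth.krill_theta
    out["krill_presence_p"] = p
    out["krill_count_mu"] = mu
    out["krill_mean"] = p * mu / (1 - nb0)
    for species, coefs in truth.whale_coefs.items():
        out[f"{species}_mean"] = np.exp(
            linear_predictor(bins, coefs) + np.log(bins["survey_area_km2"])
        )
    return out


def write_dataset(outdir, grid: StudyGrid, bins: pd.DataFrame, truth: TruthSpec) -> None:
    """Write grid cells and bins as CSV and the truth spec as JSON."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    grid.cells.to_csv(outdir / "grid_cells.csv", index=False)
    bins.to_csv(outdir / "bins.csv", index=False)
    truth.to_json(outdir / "truth.json")
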