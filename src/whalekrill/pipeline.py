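"""End-to-end pipeline: simulate → krige → biomass → fit/select → predict
→ hotspots → overlap, from a single validated config.

Every stage writes plain-text artifacts (CSV tables, JSON reports, ASCII
grid rasters) under the output directory and registers them in a manifest
with SHA-256 checksums; a run is a pure function of (config, seed). In
synthetic mode no external files are needed.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, ValidationError, field_validator

from . import acoustics, glm, hotspots, kriging, maps, selection, synthetic
from .rasters import write_ascii_grid

STAGES = (
    "simulate", "krige", "biomass", "fit", "select", "predict", "hotspots", "overlap",
)

# variable/layer naming for kriged surfaces
SURFACE_VARS = {
    ("temperature", "surface"): "temp_surface",
    ("temperature", "midwater"): "temp_mid",
    ("salinity", "surface"): "sal_surface",
    ("salinity", "midwater"): "sal_mid",
    ("fluorescence", "surface"): "fluor_surface",
    ("fluorescence", "midwater"): "fluor_mid",
}


# --------------------------------------------------------------------------
# Configuration


class SyntheticConfig(BaseModel):
    extent_km: tuple[float, float] = (30.0, 30.0)
    cell_km: float = Field(1.0, gt=0)
    n_cruises: int = Field(8, ge=1)
    start_year: int = 2004
    bin_km: float = Field(3.0, gt=0)
    line_spacing_km: float = Field(3.0, gt=0)


class CVConfig(BaseModel):
    enabled: bool = True
    k: int = Field(10, ge=2)
    runs: int = Field(20, ge=1)


class QCThresholds(BaseModel):
    pct_ci95: float = Field(90.0, gt=0)
    pct_2sd: float = Field(90.0, gt=0)
    pct_rmse: float = Field(30.0, gt=0)
    pct_me: float = Field(2.0, gt=0)


class GiStarConfig(BaseModel):
    scheme: str = "fixed_band"
    band_km: float = Field(3.0, gt=0)

    @field_validator("scheme")
    @classmethod
    def _scheme(cls, v):
        if v not in ("fixed_band", "inverse_distance"):
            raise ValueError("scheme must be fixed_band or inverse_distance")
        return v


class RunConfig(BaseModel):
    seed: int = 0
    synthetic: SyntheticConfig = SyntheticConfig()
    qc: QCThresholds = QCThresholds()
    selection_alpha: float = Field(0.05, gt=0, lt=1)
    cv: CVConfig = CVConfig()
    gistar: GiStarConfig = GiStarConfig()
    fdr_alpha: float = Field(0.05, gt=0, lt=1)
    averaging_schemes: list[str] = ["monthly", "annual", "overall"]
    covariates: dict[str, str] | None = None  # name -> class; default Table-1 set

    @field_validator("averaging_schemes")
    @classmethod
    def _schemes(cls, v):
        bad = set(v) - {"monthly", "annual", "overall"}
        if bad:
            raise ValueError(f"unknown averaging schemes {sorted(bad)}")
        return v

    def covariate_classes(self) -> dict[str, str]:
        if self.covariates is not None:
            return self.covariates
        cov = {v: "polynomial" for v in synthetic.OCEAN_VARS}
        cov.update({v: "distance" for v in synthetic.DISTANCE_VARS})
        cov.update({"depth": "polynomial", "contour_index": "polynomial"})
        cov.update({c: "climate" for c in synthetic.CLIMATE_INDICES})
        return cov


def validate_config(raw: dict) -> tuple[RunConfig | None, list[str]]:
    """Validate a raw config dict; returns (config, errors). All
    violations are reported at once with their field paths."""
    try:
        return RunConfig.model_validate(raw), []
    except ValidationError as exc:
        errs = [
            ".".join(str(p) for p in e["loc"]) + ": " + e["msg"]
            for e in exc.errors()
        ]
        return None, errs


# --------------------------------------------------------------------------
# Manifest


class Manifest:
    def __init__(self, outdir: Path):
        self.outdir = Path(outdir)
        self.entries: list[dict] = []

    def add(self, stage: str, path: Path, inputs: list[str] | None = None) -> None:
        rel = str(Path(path).relative_to(self.outdir))
        digest = hashlib.sha256(Path(path).read_bytes()).hexdigest()
        self.entries.append(
            dict(stage=stage, path=rel, sha256=digest, inputs=inputs or [])
        )

    @property
    def stages(self) -> set[str]:
        return {e["stage"] for e in self.entries}

    def write(self) -> Path:
        path = self.outdir / "manifest.json"
        with open(path, "w") as fh:
            json.dump(dict(artifacts=self.entries), fh, indent=2, sort_keys=True)
        return path


# --------------------------------------------------------------------------
# Stages


def stage_simulate(config: RunConfig, outdir: Path, manifest: Manifest):
    sc = config.synthetic
    grid = synthetic.make_study_grid(sc.extent_km, sc.cell_km)
    cruises = synthetic.make_cruise_calendar(
        sc.n_cruises, sc.start_year, seed=config.seed
    )
    truth = synthetic.TruthSpec.default(seed=config.seed)
    bins = synthetic.simulate_observations(
        grid, cruises, truth, seed=config.seed + 1,
        bin_km=sc.bin_km, line_spacing_km=sc.line_spacing_km,
    )
    d = outdir / "simulate"
    d.mkdir(parents=True, exist_ok=True)
    grid.cells.to_csv(d / "grid_cells.csv", index=False)
    bins.to_csv(d / "bins.csv", index=False)
    truth.to_json(d / "truth.json")
    for p in ("grid_cells.csv", "bins.csv", "truth.json"):
        manifest.add("simulate", d / p)
    return grid, cruises, truth, bins


def stage_krige(config, outdir: Path, manifest: Manifest, grid, bins):
    """One surface per (cruise, variable, layer): C × 3 × 2 total."""
    d = outdir / "krige"
    d.mkdir(parents=True, exist_ok=True)
    thresholds = config.qc.model_dump()
    surfaces: dict[tuple[str, str], np.ndarray] = {}
    qc_rows = []
    for cruise_id, grp in bins.groupby("cruise_id", sort=True):
        pts = grp[["x", "y"]].to_numpy()
        for (var, layer), col in SURFACE_VARS.items():
            surf = kriging.krige_surface(
                pts, grp[col].to_numpy(), grid.xy,
                cruise_id=str(cruise_id), variable=var, layer=layer,
                thresholds=thresholds,
            )
            surfaces[(str(cruise_id), col)] = surf.values
            path = d / f"{cruise_id}_{col}.asc"
            write_ascii_grid(path, grid.raster(surf.values), cellsize=grid.cell_km)
            manifest.add("krige", path)
            qc_rows.append(
                dict(cruise_id=cruise_id, variable=var, layer=layer,
                     pct_within_ci95=surf.qc.pct_within_ci95,
                     pct_within_2sd=surf.qc.pct_within_2sd,
                     pct_rmse=surf.qc.pct_rmse, pct_me=surf.qc.pct_me,
                     passed=surf.qc.passed, detrended=surf.qc.detrended)
            )
    qc = pd.DataFrame(qc_rows)
    qc.to_csv(d / "qc.csv", index=False)
    manifest.add("krige", d / "qc.csv")
    return surfaces, qc


def stage_biomass(config, outdir: Path, manifest: Manifest, bins, truth):
    """Acoustic chain round trip: synthesize per-bin backscatter from the
    generator's biomass and reconvert via the length-frequency /
    cross-section arithmetic; carries the log-volume offset."""
    d = outdir / "biomass"
    d.mkdir(parents=True, exist_ok=True)
    lf = acoustics.LengthFrequency.uniform()
    xs = acoustics.CrossSectionTable.default()
    area_m2 = bins["length_km"].to_numpy() * 1e3 * 200.0  # 200-m swath footprint
    density = bins["krill_biomass_g"].to_numpy() / area_m2
    sa = acoustics.backscatter_from_biomass(density, lf, xs)
    recon = acoustics.biomass_from_backscatter(sa, lf, xs) * area_m2
    out = bins[["bin_id", "cruise_id", "acoustic_cell_count", "acoustic_volume_m3"]].copy()
    out["sa"] = sa
    out["biomass_g"] = recon
    out["log_volume"] = np.log(bins["acoustic_volume_m3"])
    out.to_csv(d / "bin_biomass.csv", index=False)
    manifest.add("biomass", d / "bin_biomass.csv")
    return out


def stage_select(config, outdir: Path, manifest: Manifest, bins):
    """Screening + backward stepwise + year interactions per model part."""
    d = outdir / "select"
    d.mkdir(parents=True, exist_ok=True)
    cov = config.covariate_classes()
    alpha = config.selection_alpha
    static = [v for v in cov if cov[v] in ("distance",) or v in ("depth", "contour_index")]
    designs: dict[str, glm.DesignSpec] = {}
    tables = []
    parts = [
        ("krill_zero", "krill_biomass_g", "logistic", None),
        ("krill_count", "krill_biomass_g", "trunc-negbin", "acoustic_volume_m3"),
        ("blue", "blue_count", "negbin", "survey_area_km2"),
        ("humpback", "humpback_count", "negbin", "survey_area_km2"),
    ]
    for name, response, family, offset in parts:
        screens, full = selection.screen_all(
            cov, bins, response, family, offset, alpha
        )
        for s in screens:
            t = s.candidates.copy()
            t.insert(0, "part", name)
            t.insert(1, "covariate", s.covariate)
            t["chosen"] = [
                s.chosen is not None and lbl == _label_of(s.chosen)
                for lbl in t["label"]
            ]
            tables.append(t)
        if not full.terms:
            warnings.warn(f"{name}: no covariate survived screening")
            designs[name] = full
            continue
        try:
            path_result = selection.backward_stepwise(full, bins, alpha)
        except (ValueError, np.linalg.LinAlgError) as exc:
            warnings.warn(f"{name}: stepwise failed ({exc}); keeping screened design")
            designs[name] = full
            continue
        design = path_result.final
        if design.terms:
            present = [v for v in static if any(t.covariate == v for t in design.terms)]
            if present:
                _, design = selection.year_interaction_test(design, bins, present, alpha)
        designs[name] = design
        path_result.steps.to_csv(d / f"stepwise_{name}.csv", index=False)
        manifest.add("select", d / f"stepwise_{name}.csv")
    pd.concat(tables, ignore_index=True).to_csv(d / "screening.csv", index=False)
    manifest.add("select", d / "screening.csv")
    with open(d / "designs.json", "w") as fh:
        json.dump({k: _design_to_dict(v) for k, v in designs.items()}, fh, indent=2)
    manifest.add("select", d / "designs.json")
    return designs


def _label_of(term: glm.Term) -> str:
    return f"lag{term.lag}" if term.lag is not None else term.transform


def _design_to_dict(spec: glm.DesignSpec) -> dict:
    return dict(
        response=spec.response,
        offset=spec.offset,
        family=spec.family,
        terms=[
            dict(covariate=t.covariate, transform=t.transform, lag=t.lag,
                 by_year=t.by_year)
            for t in spec.terms
        ],
    )


def stage_fit(config, outdir: Path, manifest: Manifest, bins, designs):
    """Fit final models and run the diagnostic battery."""
    d = outdir / "fit"
    d.mkdir(parents=True, exist_ok=True)
    fits: dict[str, object] = {}
    report: dict[str, dict] = {}

    zero = designs["krill_zero"]
    count = designs["krill_count"]
    if zero.terms or count.terms:
        hurdle = glm.fit_hurdle(zero, count, bins)
        fits["krill"] = hurdle
        report["krill"] = dict(
            aic=hurdle.aic, bic=hurdle.bic, llf=hurdle.llf, n=hurdle.n,
            converged=hurdle.converged,
            theta=hurdle.count.theta if hurdle.count else None,
        )
        if config.cv.enabled and hurdle.zero is not None and hurdle.count is not None:
            cv = glm.kfold_cv(
                lambda fr: glm.fit_hurdle(zero, count, fr), bins,
                "krill_biomass_g", config.cv.k, config.cv.runs, config.seed,
            )
            report["krill"]["cv"] = dict(
                rmse_training=cv.rmse_training, rmse_test=cv.rmse_test,
                mae_training=cv.mae_training, mae_test=cv.mae_test,
            )
        resid = bins["krill_biomass_g"].to_numpy() - hurdle.predict(bins)
        sub = slice(0, min(len(bins), 800))  # cap the weight matrix size
        moran = glm.morans_i(
            resid[sub], bins[["x", "y"]].to_numpy()[sub], "inverse_distance"
        )
        report["krill"]["morans_i"] = dict(I=moran.I, z=moran.z, p=moran.p)

    for species in ("blue", "humpback"):
        design = designs[species]
        if not design.terms:
            continue
        fit = glm.fit_negbin(design, bins)
        null = glm.fit_negbin(
            glm.DesignSpec(design.response, [], design.offset, "negbin"), bins
        )
        fits[species] = fit
        entry = dict(
            aic=fit.aic, bic=fit.bic, llf=fit.llf, n=fit.n, theta=fit.theta,
            converged=fit.converged,
            nagelkerke_r2=glm.nagelkerke_r2(fit.llf, null.llf, fit.n),
            params={k: float(v) for k, v in fit.params.items()},
        )
        # Vuong: adopt zero-inflation only on significant improvement
        try:
            zinb = glm.fit_zinb(design, bins)
            zstat, pval, pref = glm.vuong_test(zinb, fit)
            entry["vuong"] = dict(z=zstat, p=pval, zinb_preferred=pref == "a")
        except Exception as exc:  # pragma: no cover - defensive
            entry["vuong"] = dict(error=str(exc))
        if config.cv.enabled:
            cv = glm.kfold_cv(
                lambda fr, ds=design: glm.fit_negbin(ds, fr), bins,
                design.response, config.cv.k, config.cv.runs, config.seed,
            )
            entry["cv"] = dict(
                rmse_training=cv.rmse_training, rmse_test=cv.rmse_test,
                mae_training=cv.mae_training, mae_test=cv.mae_test,
            )
        if len(design.terms) >= 2:
            _, X, _ = design.build(bins)
            lin = X[[c for c in X.columns if c != "const" and "^" not in c
                     and ":year[" not in c]]
            if lin.shape[1] >= 2:
                entry["vif"] = {k: float(v) for k, v in glm.vif(lin).items()}
        report[species] = entry

    with open(d / "fits.json", "w") as fh:
        json.dump(report, fh, indent=2, default=float)
    manifest.add("fit", d / "fits.json")
    return fits, report


def stage_predict(config, outdir: Path, manifest: Manifest,
                  grid, bins, surfaces, fits):
    """Per-cruise grid predictions plus averaged and decile-scaled maps."""
    d = outdir / "predict"
    d.mkdir(parents=True, exist_ok=True)
    rasters: dict[str, list[maps.PredictionRaster]] = {s: [] for s in fits}
    static_cols = list(synthetic.BATHY_VARS) + ["x", "y"]
    for cruise_id, grp in bins.groupby("cruise_id", sort=True):
        cells = grid.cells[["cell_id"] + static_cols].copy()
        for col in SURFACE_VARS.values():
            cells[col] = surfaces[(str(cruise_id), col)]
        first = grp.iloc[0]
        for col in grp.columns:
            if any(col.startswith(f"{c}_lag") for c in synthetic.CLIMATE_INDICES):
                cells[col] = first[col]
        cells["year"] = first["year"]
        year, month = int(first["year"]), int(first["month"])
        for species, fit in fits.items():
            r = maps.predict_grid(fit, cells, grid, species, year, month)
            rasters[species].append(r)
            path = d / f"{species}_{cruise_id}.asc"
            write_ascii_grid(path, r.values, cellsize=grid.cell_km)
            manifest.add("predict", path)
    # averaged map sets with decile classes, pooled per species & scheme
    for species, rs in rasters.items():
        for scheme in config.averaging_schemes:
            averaged = maps.average_maps(rs, scheme)
            arrays = [arr for arr, _ in averaged.values()]
            classes, bounds = maps.decile_scale(arrays)
            prov = {}
            for (key, (_, keys)), cls in zip(averaged.items(), classes):
                path = d / f"{species}_{scheme}_{key}_decile.asc"
                write_ascii_grid(path, cls.astype(float), cellsize=grid.cell_km)
                manifest.add("predict", path)
                prov[str(key)] = [list(k) for k in keys]
            with open(d / f"{species}_{scheme}_provenance.json", "w") as fh:
                json.dump(dict(decile_bounds=list(bounds), maps=prov), fh, indent=2)
            manifest.add("predict", d / f"{species}_{scheme}_provenance.json")
    return rasters


def stage_hotspots(config, outdir: Path, manifest: Manifest, rasters):
    d = outdir / "hotspots"
    d.mkdir(parents=True, exist_ok=True)
    weights = hotspots.WeightSpec(config.gistar.scheme, config.gistar.band_km)
    persistence: dict[str, np.ndarray] = {}
    monthly: dict[str, list[hotspots.HotspotRaster]] = {}
    for species, rs in rasters.items():
        hs = [
            hotspots.hotspot_raster(r.values, r.key, weights, config.fdr_alpha)
            for r in rs
        ]
        monthly[species] = hs
        persistence[species] = hotspots.persistence_sum(hs)
        path = d / f"{species}_persistence.asc"
        write_ascii_grid(path, persistence[species])
        manifest.add("hotspots", path)
    return monthly, persistence


def stage_overlap(config, outdir: Path, manifest: Manifest, rasters):
    """Global AB per year and local AB temporal mean/SD per whale species."""
    d = outdir / "overlap"
    d.mkdir(parents=True, exist_ok=True)
    if "krill" not in rasters:
        warnings.warn("no krill predictions; overlap skipped")
        return {}
    krill_by_key = {r.key: r.values for r in rasters["krill"]}
    results = {}
    rows = []
    for species in ("blue", "humpback"):
        if species not in rasters:
            continue
        locals_ = []
        annual_pred = maps.average_maps(rasters[species], "annual")
        annual_krill = maps.average_maps(rasters["krill"], "annual")
        for year in annual_pred:
            ab = hotspots.ab_ratio_global(
                annual_pred[year][0], annual_krill[year][0]
            )
            rows.append(dict(species=species, year=year, ab_ratio=ab))
        for r in rasters[species]:
            if r.key in krill_by_key:
                locals_.append(hotspots.ab_ratio_local(r.values, krill_by_key[r.key]))
        if len(locals_) >= 2:
            mean, sd = hotspots.temporal_mean_sd(locals_)
            write_ascii_grid(d / f"{species}_ab_mean.asc", mean)
            write_ascii_grid(d / f"{species}_ab_sd.asc", sd)
            manifest.add("overlap", d / f"{species}_ab_mean.asc")
            manifest.add("overlap", d / f"{species}_ab_sd.asc")
            results[species] = dict(mean=mean, sd=sd)
    ab = pd.DataFrame(rows)
    ab.to_csv(d / "ab_ratio_by_year.csv", index=False)
    manifest.add("overlap", d / "ab_ratio_by_year.csv")
    results["by_year"] = ab
    return results


# --------------------------------------------------------------------------
# Driver


def run_pipeline(config: RunConfig, outdir) -> Manifest:
    """Run the full chain; deterministic given (config, seed)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = Manifest(outdir)
    grid, cruises, truth, bins = stage_simulate(config, outdir, manifest)
    surfaces, _qc = stage_krige(config, outdir, manifest, grid, bins)
    stage_biomass(config, outdir, manifest, bins, truth)
    designs = stage_select(config, outdir, manifest, bins)
    fits, _report = stage_fit(config, outdir, manifest, bins, designs)
    rasters = stage_predict(config, outdir, manifest, grid, bins, surfaces, fits)
    stage_hotspots(config, outdir, manifest, rasters)
    stage_overlap(config, outdir, manifest, rasters)
    manifest.write()
    return manifest
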