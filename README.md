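# whalekrill

A tested, reusable implementation of a predator–prey spatial modeling
chain for shipboard line-transect surveys of baleen whales and their krill
prey. The pipeline covers every stage between raw survey bins and
management-relevant overlap maps:

1. **Kriged oceanographic surfaces** — ordinary kriging of temperature,
   salinity and fluorescence (surface 1–9 m and midwater 30–40 m layers)
   per cruise onto a 1-km² grid, with four leave-one-out cross-validation
   quality gates and second-order trend removal as fallback.
2. **Acoustic krill biomass** — conversion of area backscatter to g/m²
   via a length-frequency distribution, per-length backscattering
   cross-sections, and the length–weight relationship
   M(L) = 0.0002 L² − 0.0017 L + 0.005 (g, L in mm), binned to 3-km
   effort bins with a log-volume offset.
3. **Abundance models** — a two-part hurdle for krill (logistic presence
   × zero-truncated NB2 abundance, offset log acoustic volume) and NB2
   GLMs for whale counts (offset log survey area, D = n / (2·L·ESW·g(0))
   for segment densities), with a defined covariate-selection protocol:
   univariate form/lag screening, backward stepwise elimination under an
   ΔAIC-2 / BIC decision rule, and likelihood-ratio tests for year
   interactions. Diagnostics: Vuong tests against zero-inflated
   alternatives, VIF, Moran's I on residuals, Nagelkerke pseudo-R², and
   repeated k-fold cross-validation (k = 10, 20 runs).
4. **Hotspots and overlap** — per-month Getis-Ord Gi* z-scores with
   Benjamini–Hochberg FDR masking, a 0-to-M hotspot persistence surface,
   and AB-ratio trophic overlap
   (AB = mean[(pᵢ−p̄)(bᵢ−b̄)] / (p̄·b̄)) as global per-year scalars and
   local per-cell maps with temporal mean/SD.

Because real survey data of this kind are rarely deposited, the package
ships a first-class synthetic study generator (`whalekrill.synthetic`)
that draws observations from exactly the model families the analysis
fits — Gaussian random fields with known variograms, AR(1) climate
indices, hurdle krill biomass and NB2 whale counts with known
coefficients — so every downstream stage is testable against ground
truth.

## Worked example

```python
import numpy as np
from whalekrill import glm, synthetic, hotspots

grid = synthetic.make_study_grid((24.0, 24.0), cell_km=1.0)
cruises = synthetic.make_cruise_calendar(8, seed=0)
truth = synthetic.TruthSpec.default(seed=0)
bins = synthetic.simulate_observations(grid, cruises, truth, seed=1)
print(f"{len(bins)} bins over {len(cruises)} cruises; "
      f"krill zero fraction {(bins.krill_biomass_g == 0).mean():.2f}")

zero = glm.DesignSpec("krill_biomass_g",
                      [glm.Term("temp_mid", "quadratic"), glm.Term("dist_200m"),
                       glm.Term("soi", lag=1)],
                      family="logistic")
count = glm.DesignSpec("krill_biomass_g",
                       [glm.Term("fluor_mid", "quadratic"), glm.Term("dist_200m"),
                        glm.Term("ui", lag=1)],
                       offset="acoustic_volume_m3", family="trunc-negbin")
hurdle = glm.fit_hurdle(zero, count, bins)
print(f"hurdle AIC {hurdle.aic:.1f}, count-part theta {hurdle.count.theta:.2f} "
      f"(truth {truth.krill_theta})")
print(f"presence slope on dist_200m: {hurdle.zero.params['dist_200m']:.3f} "
      f"+/- {hurdle.zero.bse['dist_200m']:.3f} "
      f"(truth {truth.krill_presence['dist_200m']})")
```

prints

```
488 bins over 8 cruises; krill zero fraction 0.38
hurdle AIC 4965.7, count-part theta 1.46 (truth 1.5)
presence slope on dist_200m: -0.100 +/- 0.027 (truth -0.12)
```

— the hurdle recovers the generating dispersion (θ = 1.5) and the
shelf-break distance effect on krill presence within one standard error.

The full chain runs from one config via the CLI:

```bash
whalekrill all --seed 7 --outdir out/           # full synthetic pipeline
whalekrill krige --seed 7 --outdir out/         # ...or any single stage
```

The output bundle contains the simulated dataset (CSV + truth JSON), one
ASCII-grid raster per kriged surface with a QC table, selection and fit
reports (JSON/CSV), per-cruise prediction and decile maps, hotspot
persistence surfaces, AB-ratio maps and per-year AB scalars, and a
`manifest.json` with SHA-256 checksums (two runs with the same config and
seed produce identical checksums).

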