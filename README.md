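# wetch4

Causality-guided upscaling and driver attribution of boreal–Arctic wetland
methane (CH₄) emissions.

Wetlands are the largest and most uncertain natural CH₄ source, and the
boreal–Arctic — warming several times faster than the global mean — is where
that uncertainty bites hardest. Flux towers and chambers measure emissions
at points; climate questions need gridded, regional, multi-decadal answers.
`wetch4` implements the full statistical chain between the two, for
scientists who work with eddy-covariance/chamber flux compilations and
gridded reanalysis-style drivers:

1. **Causal discovery (PCMCI).** For each wetland type (bog, fen, marsh,
   tundra), find the lagged causal parents of weekly flux among eight
   drivers — soil/air temperature, GPP, pressure, precipitation, wind, snow
   cover, soil water — by PC-style condition selection followed by momentary
   conditional-independence tests. The CI test is linear partial
   correlation: ρ(X, Y | Z) is the Pearson correlation of the residuals of
   X and Y after projection on Z, with a two-sided t test on
   n − |Z| − 2 degrees of freedom.
2. **Causality-guided regression.** Per type, a small smooth regressor on
   the retained (driver, lag) features minimizes a mixed-frequency loss —
   pointwise squared error for weekly (EC) records plus window-mean squared
   error for chamber period means — with a penalty λ Σ max(0, −sign(ρ)·S)²
   that keeps each learned sensitivity S consistent in sign with its causal
   link. A 20-member ensemble over random 80/10/10 splits gives the
   estimate and its sampling uncertainty.
3. **Upscaling.** Intensities (nmol CH₄ m⁻² s⁻¹) become per-cell emissions
   via spherical cell areas and wetland type fractions, then annual
   regional totals (Tg CH₄ yr⁻¹) with OLS trends, two-sided t tests, and a
   per-calendar-month split of the trend.
4. **Attribution.** Per cell and year: the dominant driver of inter-annual
   variability (largest |partial correlation| of detrended anomalies given
   the other seven drivers, grouped into temperature/GPP/water/others), and
   a factor-constant trend decomposition
   ΔCH₄(X) = Model_all − Model_X = β_X ΔX, whose group contributions add
   exactly to the all-factor model trend.

A seeded synthetic-data generator reproduces the statistical structure this
analysis assumes (seasonal cycles, AR(1) anomalies, warming/greening trends,
a lagged type-specific flux law, mixed-frequency noisy observations), so
every stage is verifiable offline against a known truth. Real gridded
inputs in the same layout can be substituted file-for-file; none are
shipped.

## Worked example

Each script in `examples/` exercises one capability. The core loop —
simulate, infer graphs, train, validate — looks like:

```python
import wetch4 as w
from wetch4.causal_graph import build_panel, infer_graph
from wetch4.flux_model import train_all_types

grid, cfg = w.GridSpec(), w.TruthConfig(seed=1)
drivers  = w.generate_drivers(grid, cfg)
wetlands = w.generate_wetlands(grid, cfg)
truth    = w.generate_truth_flux(drivers, wetlands, cfg)
sites    = w.sample_sites(truth, wetlands, n_ec=30, n_chamber=40, cfg=cfg)

graphs = {wt: infer_graph(build_panel([r for r in sites if r.wetland_type == wt],
                                      drivers, wt), max_lag=8, alpha=0.05)
          for wt in w.WETLAND_TYPES}
models, member_metrics, _ = train_all_types(sites, graphs, drivers,
                                            n_members=5, seed=10)
```

Running `python examples/02_infer_causal_graph.py` prints, for the fen type
whose planted truth is TS at lag 0 and GPP at lag 2:

```
fen     planted (TS,0) (GPP,2)  ->  (TS,0) rho=+0.25 p=2.1e-13  (GPP,2) rho=+0.08 p=2.5e-02
```

— the discovery stage recovered exactly the planted links, with the
conditional strength and significance of each. `03_train_and_validate.py`
then reports the pooled held-out skill of the ensemble:

```
R    = 0.937 +- 0.009
MAE  = 7.37 +- 0.14 nmol CH4 m-2 s-1
NMAE = 4.65 +- 0.38 %
```

and `04_upscale_and_trends.py` / `05_attribute_drivers.py` close the loop at
the regional scale:

```
mean 0.687 +- 0.008 Tg CH4 yr-1 (+- = ensemble member spread)
trend: +0.0043 Tg yr-2, +12.7% over 20 years (two-sided t-test p = 1.04e-18)
truth trend: +14.5%  (upscaling should land close)
...
dominant-driver shares: temperature 96.3%, GPP 3.7%
trend attribution:      temperature +83.3%, GPP +14.5%
```

The upscaled trend tracks the generator's true trend, and attribution
recovers the planted design — warming-dominated emissions with vegetation
productivity second.

## Command line

A thin CLI mirrors the library:

```bash
wetch4 run-all --outdir out --seed 1        # all stages + manifest
wetch4 simulate --config my.yaml            # or stage by stage
wetch4 infer-graph ... ; wetch4 train ... ; wetch4 upscale ... ; wetch4 attribute ...
```

Outputs are NetCDF grids, CSV tables, JSON graphs/models, and a
`manifest.json` with the config hash and SHA-256 of every file; a fixed
master seed makes reruns bit-identical.

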