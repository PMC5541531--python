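# carnrange

Mapping and modelling of large-carnivore range contractions.

Most of the world's large (≥ 15 kg) terrestrial carnivores occupy only a
fraction of the area they inhabited around AD 1500. Quantifying that loss
requires comparing historic range maps — digitized from heterogeneous,
coarse sources — against modern survey polygons, and then asking what
distinguishes the places a species vanished from the places it persists.
`carnrange` implements that workflow as a tested, reusable pipeline for
conservation biogeographers:

1. **Harmonization** — historic and current polygon maps are rasterized to
   a fine geographic grid (0.05° at full scale) and reconciled: apparent
   range *expansions* ("slivers" and "islands" created by source mismatch)
   are absorbed into the historic range (so current ⊆ historic), coastlines
   are aligned by adding land cells within *k* grid cells of both the range
   and the ocean, and ranges are clipped to each species' published
   elevational limits.
2. **Composite mapping** — per-species persistence/contraction maps are
   stacked into historic, current, lost and percent-lost richness
   composites; *intact guild* cells are those that historically held ≥ 1
   species and have lost none. All "% of land" statistics weight cells by
   their exact spherical area.
3. **Contraction model** — on a coarse (50 km-class) grid, every cell of a
   species' historic range yields a binary observation: has the species'
   range contracted from that cell? Contraction likelihood is modelled as

   logit P(y<sub>ic</sub> = 1) = β₀ + **x**<sub>c</sub>ᵀ**β** + b<sub>i</sub>,  b<sub>i</sub> ~ N(0, σ²<sub>s</sub>)

   with standardized rural human population density, cattle density (both
   log(1+x)-transformed) and % cropland as predictors and a random
   intercept per species, fitted by maximum likelihood under the Laplace
   approximation. Residual spatial autocorrelation is absorbed with a
   **residuals auto-covariate (RAC)**: deviance residuals of the
   non-spatial fit are averaged over all cells within 300 km of each cell,
   standardized, and added as an extra covariate before refitting. Effects
   are reported as % change in the odds of contraction per 1 s.d., and
   variance explained as marginal / conditional pseudo-R² on the latent
   scale (distribution variance π²/3). A variant with random intercepts
   and slopes by geographical region quantifies regional heterogeneity via
   conditional modes with 95% prediction intervals.

Because the original range polygons and covariate grids are large external
datasets, the package ships a **synthetic world generator**: land masks,
spatially autocorrelated covariate fields, overlapping species ranges and
realized contractions drawn from the same model family the estimator fits,
with the generating parameters retained. Every stage of the pipeline runs,
and is validated, without downloading anything.

## Worked example

```sh
cat > config.yaml <<'YAML'
seed: 7
output_dir: out
synthetic:
  resolution: 0.5
  extent: [-60, 60, -30, 30]
  coarse_factor: 5
model:
  rac_radius_km: 600
YAML
carnrange run -c config.yaml
```

prints (abridged):

```
Land historically occupied by >=1 species: 99.8%
Land with intact guild today: 39.4%

## Per-species contraction (% of historic range lost)
   species    family  mass_kg  pct_contraction iucn_status population_trend
species_09   Canidae     68.2        58.083363          CR       decreasing
species_06   Ursidae    227.0        30.298688          NT       decreasing
...

## Contraction model (RAC, odds per 1 s.d.)
               term      beta       se  pct_odds_change     ci_low    ci_high      p_value
rural_pop_density_z -0.094361 0.078679        -9.004570 -22.008626   6.167746 2.304062e-01
   cattle_density_z  0.604866 0.075376        83.100716  57.953421 112.251637 1.017788e-15
         cropland_z  0.023796 0.069080         2.408153 -10.559894  17.256455 7.304918e-01
              rac_z  0.989999 0.073246       169.123286 133.132380 210.670456 1.258409e-41

## Pseudo-R2
     model  marginal  conditional  var_fixed  var_random  var_resid
      base  0.087589     0.183927   0.353101    0.388372   3.289868
       rac  0.286863     0.339463   1.428751    0.261980   3.289868
rac+region  0.281053     0.369166   1.465723    0.459520   3.289868
```

Reading the output: in this simulated world, 39.4% of the land still holds
its complete historic carnivore guild; cattle density carries a strongly
positive effect (+83% odds of contraction per 1 s.d.) in this single
realization while the RAC term soaks up the spatially structured noise the
generator injected; the species random intercept plus fixed effects
explain ~34% of latent-scale variance (conditional R²). Estimates from a
single small-window realization are noisy by design — averaged over many
seeds they recover the generating coefficients (see the recovery study
below).

All intermediate artifacts (harmonized rasters as ESRI ASCII grids,
observation table, coefficient/effect/R² tables, run manifest) are written
under `out/`; a rerun with an unchanged config reuses them and reproduces
the report byte for byte.

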