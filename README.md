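# ecobaci

Statistical analysis of paired-plot **Before-After-Control-Impact (BACI)
field experiments on multivariate arthropod count data** — the design used
to test whether a soil-applied biopesticide (e.g. *Metarhizium*-based tick
control sprayed on residential lawn/forest plots) harms the non-target
arthropod community.

It is written for ecotoxicologists and field ecologists who have
taxon-by-sample count tables with design metadata (location, paired
treated/control plot, habitat, sampling occasion, sample type) and want the
complete inference chain:

1. **Pooling** of raw component samples (soil cores, litter cores, pitfall
   traps) into one analysis sample per design cell, including 15%-subsample
   extrapolation for hyper-abundant orders;
2. **Negative-binomial many-GLM**: per-taxon NB regressions
   `Y_ij ~ NB(mu_ij, Phi_j)`, `Var = mu + mu^2/Phi`, with log-linear mean
   `log mu = intercept_j + period_p + habitat_h + location_l (+ treatment_t)`,
   fitted by IRLS with profile-ML dispersion and combined through a summed
   log-likelihood;
3. **AIC decision rule** comparing the nested null and treatment models, and
   sequential **analysis of deviance** with p-values from permuting whole
   rows of randomized-quantile residuals (cross-taxon correlation preserved);
4. **BACI effects** per taxon,
   `(treated_after - control_after) - (treated_before - control_before)`,
   with standard errors over (location, habitat) replicates;
5. **Bootstrap power analysis** — retrospective (what reduction could this
   design detect with 80% power?) and prospective (what sample size would a
   future study need?) — driven by the same AIC rule;
6. A **synthetic-data generator** that emulates the full field design
   (13 locations x paired 8x8 m plots x lawn/forest, bulk and pitfall
   sampling, dominant-taxon skew, overdispersion, lost samples), so every
   stage runs and is testable with no external data.

## Worked example

```python
from ecobaci import (SyntheticConfig, simulate_dataset, compare_models_aic,
                     ModelSpec, baci_effect, retrospective_power)

cfg = SyntheticConfig(seed=42, n_taxa=8, occasions_bulk=("pre", "post1"),
                      n_pitfall_locations=0, n_pitfall_late_locations=0,
                      n_dirty_pitfall=0)
raw, pooled = simulate_dataset(cfg)
bulk = pooled.select((pooled.meta["sample_type"] == "bulk").to_numpy())

cmp = compare_models_aic(bulk, ModelSpec.null(), ModelSpec.alternative(),
                         n_resamples=199, seed=1)
res = baci_effect(bulk, ("pre", "post1"))
grid = retrospective_power(bulk, ("pre", "post1"), factors=(0.3, 0.5, 0.7),
                           n_reps=200, seed=2)
```

prints (via the obvious accessors):

```
311 raw components pooled into 104 bulk samples
AIC null = 4474.0, AIC treatment = 4488.1, delta = 14.1 -> preferred: null (p = 0.995)
    taxon  baci_effect    baci_se
    acari  -326.615385 293.426778
  araneae     0.384615   0.924998
blattodea    -0.038462   0.141212
 factor  power    mc_se
    0.3  0.910 0.020236
    0.5  0.585 0.034841
    0.7  0.280 0.031749
smallest detectable reduction: 0.7
```

Read: this dataset was generated with **no** treatment effect, and the AIC
rule agrees — adding treatment costs 14.1 AIC units, so the null model is
preferred and the resampling p-value for the added term is ~1.  The BACI
effect for the dominant order (acari) is large in count units but well
within one replicate SE of zero.  The bootstrap power grid says a 70%
abundance reduction (factor 0.3) would be detected in 91% of replicates,
while a 30% reduction would usually be missed; the smallest reduction
detectable at the 80%-power criterion on this grid is 70%.

The same operations are available from the shell:

```sh
ecobaci simulate --seed 42 --out-dir scratch/demo
ecobaci fit scratch/demo/pooled_counts.csv --occasions pre,post1 \
        --resamples 199 --seed 1 --out scratch/fit.json
ecobaci baci scratch/demo/pooled_counts.csv --occasions pre,post1 \
        --out scratch/baci.csv --plot scratch/baci.png
ecobaci power scratch/demo/pooled_counts.csv --mode retro --seed 2 \
        --reps 500 --out scratch/power.csv
ecobaci run analysis.yaml        # full pipeline from a YAML config
```

`ecobaci run` executes the study's four analyses (bulk and pitfall, each
pre vs. first and pre vs. second post-spray occasion) and writes AIC
comparison tables, deviance tables, BACI CSVs, optional power grids and a
machine-readable run log; reruns with the same seed are byte-identical.

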