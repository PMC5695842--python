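# Methods

## The experiment the package models

A paired-plot Before-After-Control-Impact (BACI) field trial of a
soil-applied biopesticide: 13 locations, each with one treated and one
control 8 m x 8 m plot, each plot split into lawn and forest habitat.
Ground-dwelling arthropods are counted to order level from two kinds of
samples — bulk soil/litter cores (three occasions: pre-spray, ~1 week post,
~3 weeks post) and pitfall traps (a 7-location subset at two occasions, plus
a 3-location subset at a late occasion).  Raw component samples (2 lawn
cores; 2 forest soil + 2 forest litter cores; 2 pitfall traps per habitat)
are summed into one *pooled sample* per
(location, plot, habitat, occasion, sample type) cell; pooled samples are
the modelling unit.  On the full design this yields 156 bulk and 68 pitfall
pooled samples from 468 and 136 raw components (1 litter sample lost, 7
pitfalls unsortable).  Two orders (mites, springtails) are so abundant that
bulk samples are counted from a 15% subsample and scaled by 100/15;
extrapolated counts are rounded half-up to integers after pooling so the
count likelihood is defined.

## The abundance model

For taxon *j* in pooled sample *i*, counts are negative binomial,
`Y_ij ~ NB(mu_ij, Phi_j)` in the mean/size parameterization
`Var = mu + mu^2 / Phi` (`Phi -> inf` is Poisson; this convention is fixed
package-wide so dispersion numbers are comparable everywhere), with log-link
mean

    null:        log mu_ij = intercept_j + period_p + habitat_h + location_l
    alternative: ...                                            + treatment_t

Factors are treatment-contrast coded with fixed reference levels (`before`,
`lawn`, `control`, first location).  Taxa are fitted independently — the
design has too few rows per parameter to estimate a cross-taxon correlation
matrix — and combined through the summed log-likelihood (the "many-GLM"
idiom of model-based community ecology).  Cross-taxon dependence is instead
respected at inference time by resampling whole sample rows.

### Fitting

Per taxon: IRLS updates of the coefficients at fixed dispersion, alternated
with a bounded Brent search for the profile-ML dispersion on log(Phi) in
[1e-3, 1e8], until the relative log-likelihood change is below 1e-8 (max 200
outer iterations; non-converged taxa are flagged and the model AIC marked
approximate in the summary).  Linear predictors are clipped at +/-30 to keep
the working weights finite.  For effectively Poisson data the profile is
flat and increasing in Phi, so the boundary value is taken when it beats the
interior optimum; the log-likelihood uses an asymptotic expansion of the
rising-factorial term above Phi = 1e7, where the direct `lgamma` difference
loses more than single precision.  An all-zero taxon is degenerate: its mean
is floored at 1e-8 and Phi pinned at the upper bound, it stays in parameter
and AIC totals (this cancels in nested comparisons) but is excluded from
likelihood-ratio statistics.  A taxon with constant non-zero counts is fitted
normally (its dispersion simply lands on the upper bound); flooring it like
the all-zero case would discard a well-defined likelihood.

### Model comparison and term tests

The treatment decision rule is pure AIC: with
`AIC = -2 * sum_j llf_j + 2 * sum_j (p_j + 1)` (every coefficient plus one
estimated dispersion per taxon counted as free), the treatment model is
"preferred" iff its AIC is lower; exact ties (within 1e-9) go to the smaller
model by parsimony.  Term significance uses sequential (type-I) analysis of
deviance: for each added term the summed likelihood-ratio (or optionally
Wald) statistic is compared against a null distribution obtained by
permuting whole rows of randomized-quantile (PIT / Dunn-Smyth) residuals
under the smaller model and mapping them back to counts through that model's
fitted NB distributions, `p = (1 + #[resampled >= observed]) / (1 + B)`.
Permuting rows as units preserves the cross-taxon correlation the mean model
ignores.  B >= 99 is enforced; B = 999 is the default.

## BACI effects

Per taxon, the replicate-level BACI value in each (location, habitat) cell
is `(treated_after - control_after) - (treated_before - control_before)` on
within-cell means of pooled samples; the reported effect is the mean over
replicates and its SE the sample SD (n-1 denominator) over replicates
divided by sqrt(n).  Effects are in count units; no per-taxon p-values are
attached (with ~20 orders unadjusted tests would flag one by chance, while
multiplicity corrections would mask modest real shifts).  The plotting
helper displays effects on an inverse-hyperbolic-sine scale, which is
log-like for large |x| but linear (and sign-preserving) through zero.

## Bootstrap power

Power is defined operationally as the probability that the AIC rule prefers
the treatment model.  Each replicate draws pooled-sample rows with
replacement (unstratified, across the whole occasion pair; metadata travels
with the row), multiplies treated x after counts by a reduction factor
(abundance reduction = 1 - factor), rounds half-up, and refits both models.
Replicates in which a factor level vanishes from the resample are redrawn
and counted.  Retrospective mode keeps the observed sample size and scans
factors 0.10-0.90 in steps of 0.05; prospective mode inflates the resample
size by an integer multiplier (1-20 for bulk, 10-100 step 10 for pitfall)
at 25% and 50% reductions.  The target criterion is power >= 0.80; grids
report the Monte-Carlo SE `sqrt(p(1-p)/n_reps)` per cell.

A property worth knowing: the resampling distribution is centred on the
*template's* empirical treatment contrast, not on zero, so the "power" at
factor 1 — the rule's false-selection rate — varies with the template and
can be substantial.  This anticonservatism is inherent to retrospective
bootstrap power and is surfaced, not hidden: the test suite pins the
factor-1 rate for a fixed template and checks the negative control (scaling
all rows equally collapses power toward that rate).

## The synthetic-data generator

The generator inverts the abundance model.  Per-taxon baselines, habitat and
period effects, a location effect shared by the paired plots, and a
treatment multiplier on treated x after cells define `mu` per design cell;
raw components are drawn NB(mu/k, Phi/k) for a k-component cell so the
pooled sum is exactly NB(mu, Phi).  The two dominant taxa's bulk counts pass
through a binomial 15% subsample and are scaled back up (mean-preserving,
variance-inflating), mirroring the counting protocol.  One bulk litter
sample and 7 pitfall traps are removed at random — the dirty-trap draw is
constrained to one per cell so every pooled cell keeps a usable trap and the
design arithmetic (156 / 68 pooled rows) is preserved, matching the study's
reported pooling.

Defaults, chosen once for realism where no empirical values exist:

| parameter | default | rationale |
|---|---|---|
| `n_locations` | 13 | the field layout |
| `n_taxa` | 20 | arthropod orders observed |
| dominant intercepts | exp = 500, 150 counts/cell | two orders at ~2 orders of magnitude above the rest, as observed totals imply |
| other intercepts | LogNormal(0.3, 1.0) | strongly right-skewed community |
| habitat effects | Normal(0, 0.7) per taxon | lawn/forest contrasts of order e^0.7 |
| period effects | Normal(0, 0.4) per taxon | seasonal drift between occasions |
| location effects | Normal(0, 0.5), shared across taxa | paired plots share their location |
| dispersions Phi | Uniform(0.3, 2) | strong overdispersion (Var/mean of 10-400 at these means) |
| `pitfall_log_offset` | -3.0 | pitfall counts ~5% of bulk, as the observed totals suggest |
| `treatment_multiplier` | 1.0 | no effect unless asked for |

What the generator does **not** emulate: spatial autocorrelation beyond the
shared location effect, zero-inflation, taxon-specific treatment latencies,
or between-occasion dependence within a plot.  Tests passing on this
generator therefore validate the estimator and decision-rule machinery under
the model's own assumptions, not the field data's every idiosyncrasy.

## Problem sizes

Bootstrap and Monte-Carlo sizes in the shipped tests and acceptance script
are desk-scale choices with documented MC error: 100-200 decision-rule
replicates, 150-200 bootstrap replicates per power-grid cell (MC SE <=
0.035), reduced factor/multiplier grids, and 8-taxon panels for repeated
simulation.  Full-scale runs (10,000 retrospective / 1,000 prospective
replicates, the complete grids, 20 taxa) are available through the same
functions and the `ecobaci power` CLI by setting `n_reps`, `factors` and
`multipliers` explicitly.

## Known limitations

- AIC parameter accounting treats every per-taxon dispersion as free; other
  conventions shift all AICs by a constant per model and can change small
  delta-AIC values.
- The PIT-residual row-permutation null is the closest standard scheme to
  "resampling rows of data"; exact p-values depend mildly on the residual
  scheme chosen.
- Dispersion estimates at the search bound (1e8) indicate effectively
  Poisson taxa; their Phi values should be read as "large", not as precise
  estimates.
- The retrospective power bootstrap conditions on the observed template (see
  above); its factor-1 rate is not a size-alpha test.
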