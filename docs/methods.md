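# Methods

This note records the models, numerical choices and limitations behind
`sdmeval`, in the spirit of a statistical package's methods documentation.
Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Discrimination metrics

All four metrics compare a binary occurrence vector `y` with predicted
probabilities `p` at one hierarchical level.

* **AUC.** Computed from average ranks (Mann–Whitney). Two tie policies:
  `half` (default; tied presence–absence pairs count ½, so a constant
  predictor scores 0.5) and `strict` (only strictly higher pairs count, the
  literal pairwise-indicator definition, under which a constant predictor
  scores 0). Continuous model output makes ties measure-zero, but
  degenerate cases — notably intercept-only models predicting unseen groups
  — produce exact ties, and the half convention gives them the conventional
  chance value. The tie policy used is recorded in every result row.
* **Tjur's R².** `mean(p | y=1) − mean(p | y=0)`.
* **max-TSS / max-Kappa.** Both statistics are step functions of the
  threshold `t` (prediction rule `t_i = 1[p_i ≥ t]`, boundary inclusive),
  changing value only where `t` crosses an observed `p`. The maximizer
  therefore sweeps the sorted distinct values of `p`, plus `t = 0`
  (everything predicted present) and a value just above `max(p)`
  (everything absent, only reachable when `max(p) < 1`). This makes "all
  possible thresholds" exact rather than grid-approximated; the dense-grid
  sweep survives in the tests as the independent oracle. Value ties resolve
  to the smallest candidate threshold.
* **Kappa's chance accuracy.** `A_e` uses the standard marginal-product
  form `[(a+b)(a+c) + (c+d)(b+d)] / n²` — the universal Cohen definition.
* **Undefined values.** A single-class `y` (or a degenerate table with
  `A_e = 1`) yields NaN, never an exception. Pipelines exclude NaNs from
  averages and report how many repeats contributed (`n_repeats_used`) plus
  an explicit `missing_flag`.
* **Reporting transforms.** `2·AUC − 1` maps chance to 0; Tjur's R² is
  square-root transformed. Negative Tjur values (worse-than-chance) take a
  *signed* root, `sign(R²)·√|R²|`, preserving order; the choice is exposed
  in the output metadata via the transform column being monotone.

## Hierarchical aggregation

Plot- and site-level occurrence is "any unit occupied": `y_G = 1 −
Π(1−y_i)`, the group maximum. Probabilities aggregate by the same formula
(noisy-OR), which treats units within a group as independent. The model's
random effects induce within-group correlation in the *data*, but the
evaluation formula deliberately ignores it — the aggregated probability is
the model's own statement about group occupancy under its fitted structure,
and the Monte-Carlo consistency test (Bernoulli simulation vs noisy-OR)
checks exactly this identity. Aggregated vectors are indexed by group
identifier in lexicographic order for deterministic joins.

## Synthetic community generator

The generator emulates a nested fungal occupancy survey: 16 sites × 5
plots/site × ~64 units/plot (≈5,100 units in total at defaults), one binary
site-level covariate (management), and two unit-level covariates (deadwood
volume, used as log-volume; decay stage 1–5, entering standardized together
with its square). Species occurrence follows a probit model

    P(y_ij = 1) = Φ( x_i' β_j + Σ_k η_ik λ_kj )

with species responses `β_j` drawn from a community distribution and
latent-variable random effects: factors `η` drawn per site, plot and unit,
loaded per species through `λ`.

Defaults and why:

| parameter | default | rationale |
|---|---|---|
| sites × plots/site | 16 × 5 | the survey design being emulated |
| units per plot | 1 + NegBin(shape 8, mean 63) | only the ~5,100-unit total is fixed by the design; counts are overdispersed but strictly positive |
| species pool | 150 | large enough that ≥68 species survive the 10-occurrence filter |
| intercepts | Normal(−3.2, 1.3²) on the probit scale | yields a rare-skewed community: retained prevalences from ~0.2% to >40%, median ≈5%, with ≥5 species below 1% and ≥5 above 10% |
| fixed-effect responses | means (0, 0.5, 0.3, −0.3), sds (0.5, 0.4, 0.4, 0.3) for (management, log-volume, decay, decay²) | moderate niche signal and heterogeneity; negative decay² mean gives intermediate-decay optima |
| latent factors | 2 per level, loading scales (0.6, 0.5, 0.4) | random effects carry a variance share comparable to the fixed effects, as in strongly spatially structured communities |
| volume | log-normal(6, 1.5²) (cm³) | spans twigs to trunks |
| decay stages | probabilities (0.15, 0.2, 0.25, 0.25, 0.15) | mild mode at intermediate stages |

The pool is generated in full, occurrences are realized as independent
Bernoulli draws, and species with fewer than 10 occurrences are dropped —
reproducing the survey's filtering step rather than forcing a fixed species
count. Everything is driven by one `numpy` Generator seed; identical seeds
give byte-identical communities.

What the generator does **not** emulate: spatial coordinates or
distance-decaying dependence, multi-year dynamics, traits or phylogeny,
detection error. A green pattern test therefore establishes that the
evaluation machinery reproduces the qualitative behaviour of the metrics on
hierarchically structured data — not that it reproduces any particular real
community.

## Occupancy model

Per species, a Bayesian hierarchical probit with scalar random intercepts:

    z_i = x_i'β + u_site(i) + u_plot(i) + ε_i,  ε ~ N(0,1),  y_i = 1[z_i > 0]

Three variants: `FR` (full fixed effects + site/plot intercepts), `F`
(fixed only), `R` (species intercept + site/plot intercepts). This is a
deliberate simplification of a multivariate latent-factor joint model: the
package's subject is the *evaluation framework*, which needs predictions
whose usable random-effect information varies with the cross-validation
design; species-shared factors change statistical efficiency, not that
mechanism. A unit-level random effect is generated in the synthetic truth
but never fitted — in a univariate probit it is confounded with the
residual.

* **Sampler.** Gibbs with latent-utility data augmentation: truncated
  normal draws for `z` (inverse-CDF method, quantiles clipped to
  [1e−15, 1−1e−16] so `|z − m| ≤ ~8`), conjugate normal updates for `β`
  and the level intercepts, conjugate inverse-gamma updates for the level
  variances. All updates are matrix-valued across species sharing the
  design matrix, so a whole community fits in one pass. Defaults: 2 chains
  × (1000 burn + 1000 kept) draws.
* **Priors.** `β ~ N(0, 5²)` on standardized covariates (vague);
  `σ² ~ InvGamma(2, 0.5)` per level (weakly informative, prior mean 0.5).
  Configurable at model construction.
* **Convergence.** Split-chain potential scale reduction per coefficient;
  values above 1.1 raise a warning, not an error. Short exploratory chains
  on rare species routinely trip it; the pipeline records it.
* **Design matrix.** `[1, management, z(log volume), z(decay), z(decay²)]`
  with standardization constants learned on the training units and reused
  verbatim for held-out units.
* **Prediction.** Posterior-mean probability (averaged over draws, the
  recorded convention). For units whose site/plot was in the training data
  the fitted intercept draws enter the linear predictor. For unseen groups
  the intercept is integrated out by simulation: each unseen group receives
  one standard-normal sequence across posterior draws (seeded
  deterministically from the fit seed and the group identifier, so
  prediction is reproducible), scaled by that draw's σ. The analytic limit
  `Φ(L/√(1+σ²))` is available as `marginalize="analytic"` and doubles as
  the correctness cross-check; the simulated route is the default because
  it mirrors how held-out prediction behaves in latent-variable fitting
  software, including its finite-draw jitter.

## Cross-validation

Folds are built by shuffling the blocks at the blocking level (units,
plots, or sites) and dealing them round-robin: fold sizes in *blocks*
differ by at most one (unit-balanced folds are impossible in general with
unequal block sizes). Every fold assignment is checked exhaustively at
construction: full coverage, no overlap, and no block split across folds;
`cross_validate` additionally asserts that no unit's prediction comes from
a training set containing it. Ten independent repeats (seeded
`base_seed`, repeat index) are averaged downstream.

Repeat aggregation: metrics are computed per repeat and the metric values
averaged (`metric_mean`, default); averaging the prediction matrices first
(`prediction_mean`) is available as a config switch. Species whose training
split is single-class in some fold get missing predictions for that fold,
logged per species × fold; metrics then use the non-missing subset when it
still contains both classes.

## Known limitations and numerical notes

* Site-level evaluation rests on only 16 points at the emulated design;
  these values are computed but intrinsically noisy.
* Under site-blocked CV, an intercept-only (`R`) model predicts each
  held-out site as a near-constant; the pooled AUC then ranks fold-level
  intercepts against fold occupancy, and because a fold's training set
  mechanically under-represents that fold's presences, the species-averaged
  AUC falls measurably *below* 0.5 (≈0.43–0.44 on the scaled synthetic
  world) rather than sitting at chance. A community-level shrinkage prior
  on intercepts would damp this; the per-species model keeps it visible.
  The acceptance suite asserts the idealized chance band and documents the
  measured behaviour.
* The acceptance script and pattern tests run a scaled world (~19
  units/plot ⇒ ~1,400 units, 80-species pool ⇒ ~55–60 retained, 1–2 CV
  repeats, 2×500 sampler iterations) to stay desk-sized; the asserted
  patterns are orderings and correlations that are stable at this scale.
* Figure-style plotting is left to the user; the pipeline's contract is the
  tidy `results.csv` (one row per species × variant × strategy × level ×
  metric) plus `manifest.json` with seeds and versions.
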