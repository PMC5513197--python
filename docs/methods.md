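# Methods

## Overview

`expobench` is a simulation laboratory for one question: how well do
variable-selection methods recover main effects and two-way interactions
of environmental exposures when the exposures are many and strongly
correlated? Everything in the package serves that experiment: a synthetic
exposome generator, a registry of outcome scenarios, six selection
methods, 13 performance measures and an orchestration layer.

## Synthetic exposome

Exposures are standardized jointly Gaussian variables, E ~ N(0, Σ),
p = 237 by default, organised in 15 families (frozen sizes
51, 38, 30, 24, 20, 16, 13, 11, 9, 7, 6, 5, 4, 2, 1 — the published
constraints fix only the count, the 1–51 range and the total). The real
cohort matrix behind the original design is not public; the generator
reproduces its *published marginal statistics* instead:

| statistic | target |
|---|---|
| share of pairwise \|r\| < 0.2 | 0.81 |
| share of pairwise \|r\| < 0.1 | 0.64 |
| median pairwise \|r\| | 0.06 |
| share of exposures with a partner \|r\| > 0.6 | 0.78 |
| 13-variable high block, all pairwise \|r\| | ≥ 0.62 (mean ≈ 0.78) |
| 13-variable low block, all pairwise \|r\| | ≤ 0.1 |

Σ is assembled as a factor model, `Σ = L L' + D` with `D ≥ 0`, so it is
positive semi-definite by construction (an eigenvalue-clipping repair,
`nearest_positive_definite`, is kept as a safety net and for user-supplied
matrices). The loadings have five parts:

1. **Background factors** (4, orthogonal): heavy-tailed per-exposure
   loadings produce the bulk of small correlations.
2. **Family factors**: moderate within-family correlation (products of
   loadings ~0.1–0.35).
3. **Cluster factors**: ~78% of exposures sit in within-family clusters
   of 2–8 whose members correlate at 0.63–0.75 — these, plus the high
   block, supply exactly the published fraction of "strong-partnered"
   exposures.
4. **A dedicated high-block factor** with loadings tuned so the block's
   pairwise correlations centre on 0.78 and never drop below 0.62.
5. **Factor-level correlation**: the structural factor directions are
   tilted into a small shared meta-space (half weakly, half strongly),
   which correlates whole clusters and families with each other and
   creates the broad 0.1–0.4 shoulder of the |r| distribution at no
   communality cost. "Satellite" loadings (cluster members loading
   moderately on a foreign cluster, sign-aligned with the factor
   correlation so they can never erode within-cluster correlations) fill
   the 0.25–0.6 range.

A bounded calibration loop (≤ 25 iterations, ≤ 4 fresh structural draws,
all deterministic in the seed) adjusts two global scales — background
(drives the median and the <0.1 fraction) and satellite/tilt (drives the
<0.2 fraction) — until the four headline statistics sit within ±3
percentage points (median: ±0.02); failure raises a `CalibrationError`
naming the violated target. The low block is kept clean structurally: its
members carry no family/cluster loadings and capped background loadings.

*Fidelity limits.* The generator matches the four calibrated statistics
and the two block constraints; the remaining |r| percentiles are close
but not calibrated (25th ≈ 0.02 vs 0.03 published; 97.5th ≈ 0.55–0.65 vs
0.61). Within- vs between-family correlation breakdowns of the original
cohort were never published and are a modelling choice here. Real
exposome marginals are also not Gaussian; this package deliberately keeps
the Gaussian copula of the original design.

## Outcome scenarios

The true model is linear with five predictors and 0–2 products,
Y = β₀ + ΣβₖXₖ + γ₁₂X₁X₂ + γ₁₃X₁X₃ + ε, ε ~ N(0, σ), all β = 1.
The 21-row scenario registry (`SCENARIOS`) fixes, per sub-scenario, the
interaction count/size/sign (strong |γ| = 1, moderate 0.5), the tabulated
σ, the nominal adjusted R² and the predictor-draw mode: *mixed* (uniform
over all exposures), *high* (uniform over the high block) or *low*
(uniform over the near-independent block; this sensitivity row has no
tabulated σ and is calibrated at run time). Predictor labels X₁…X₅ follow
draw order and interactions always attach to the first drawn predictors;
by exchangeability of the draw this is unbiased.

The tabulated σ values are treated as ground truth; two diagnostics
verify them instead of re-tuning: `expected_r2` computes the population
R² = Var F/(Var F + σ²) in closed form from Gaussian moments
(Cov(XᵢXⱼ, XₖXₗ) = ρᵢₖρⱼₗ + ρᵢₗρⱼₖ, Var(XᵢXⱼ) = 1 + ρᵢⱼ², mains and
products uncorrelated), and `calibrate_sigma` inverts it,
σ = √(VarF·(1−R²)/R²), averaging Var F over 200 seeded predictor draws.
On the calibrated exposome these reproduce the tabulated values (e.g.
σ ≈ 13.0 for the high-correlation main-effects row printed as 13, and the
five tabulated adjusted R² of 0.11/0.27/0.13/0.30/0.31 to within ±0.01).
`true_model_sensitivity` reports the per-term significance rate when
fitting only the true terms — under strong predictor correlation it is
far below the nominal 0.9 used to motivate the original tuning, which is
inherent to collinear designs, not a calibration error.

## Selection methods

All selectors share one surface: a model object over (E, Y) whose
`fit()` returns a `SelectionResults` (terms, coefficients where the
method has them, predictor, diagnostics). Flags on the returned
`SelectedModel` record what the method can and cannot provide
(`has_single_model` — false for EWAS₂; `predicts`; `has_terms` — false
for BRT; `searches_interactions`), and the metrics layer uses them to
decide which measures apply.

* **EWAS₂**: marginal simple-regression p-values, BY step-up at α = 0.05;
  pairs of survivors retested with both mains plus the product; the
  product p-values BY-corrected again. Only the interaction coefficient
  is tested in step 2. Output is a set of marginally associated terms.
* **DSA**: candidate terms are mains (order 1) plus quadratics and all
  pairwise products (order 2, no hierarchy constraint). The search keeps
  a best-RSS incumbent per size 0..10 and sweeps deletion / substitution
  / addition moves (a move replaces the incumbent of its target size when
  it strictly lowers RSS; additions are evaluated in closed form from the
  projection of each candidate column on the current orthonormal basis)
  until a full sweep changes nothing. The final size minimises the
  cross-validated RMSE *of the search itself*: the search is re-run in
  each of 5 training folds and its per-size incumbents scored on the
  held-out fold; ties favour the smaller size, and the full-data
  incumbent of the winning size is refitted by OLS. Scoring fixed
  full-data incumbents on their own training folds was tried first and
  discarded: selection leakage made the search fill the size cap on
  benchmark-scale data, which contradicts the reported behaviour of the
  original algorithm ("never reached").
* **Sun3step**: within each family, exposures with pairwise sample
  |r| > 0.60 are grouped by connected components (a deterministic,
  order-invariant reading of "groups of highly correlated exposures");
  each group keeps its smallest marginal p-value. Survivors enter a CART
  whose cost-complexity pruning level is chosen by minimum 5-fold CV
  error (no 1-SE rule); variables used in any split go to an order-2 DSA
  restricted to them.
* **LASSO**: scikit-learn coordinate descent on standardized exposures
  over a 50-point log-spaced λ path (ratio 0.01), λ* by minimum 3-fold CV
  error on a shared fold split; coefficients reported on the original
  scale. No interaction terms by design — it is the mains-only reference
  for the group lasso.
* **Group lasso with strong hierarchy**: the objective described in the
  README, solved by FISTA with a power-iteration step size, warm starts
  along the path and group soft-thresholding; group weight √3 so group
  size does not bias selection; products are formed from standardized
  exposures and centered but not rescaled. λ* by minimum CV error on the
  same shared 3-fold split as LASSO. With the pair universe disabled the
  solver *is* the lasso objective and reproduces scikit-learn's solution
  (an equivalence kept under test). For p > 100 a sure-screening stage
  keeps the 5000 product columns most correlated with Y; with screening
  off the exact objective is solved. KKT residuals of the solver are
  property-tested on small instances.
* **BRT**: scikit-learn stage-wise squared-error boosting (depth 4,
  shrinkage 0.01, bag fraction 0.5, ≤ 5000 trees); the tree count
  minimises the error on a fixed seeded 25% holdout. Importances are the
  unnormalized split-gain totals averaged over trees. Backward
  elimination repeatedly drops the lowest-importance half of the
  variables (keep ⌈(1−f)·n⌉, at least one dropped) down to a single
  variable, with the empty "predict the training mean" model as an extra
  candidate; the smallest recorded set minimising the holdout error wins.
  The learning rate, bag fraction and holdout estimator are not pinned by
  the original description; they are config-exposed defaults chosen from
  common boosting practice.

## Performance measures

Thirteen measures per (fitted, true) pair; exact formulas in the README
and module docstrings. Conventions worth stating: term matching is exact
on kind and unordered indices (a quadratic never matches a true term but
contributes its variable); the alternative measures use the
*data-generating* Σ in absolute value, so proxy credit is sign-agnostic
and population-level; an empty selection scores 0 on sensitivity- and
FDP-type measures (no discoveries, no false discoveries) while its
alternative measures are undefined (NaN); measures a method cannot
produce are NaN and excluded from aggregation means, with replicate
counts reported alongside. R²_rel divides the method's native
out-of-sample R² (penalized coefficients, OLS refit, or tree ensemble) by
that of the true-term OLS fit on the same N = 10000 validation set; it
may exceed 1 or go negative.

## Benchmark orchestration and problem sizes

`run_benchmark` builds Σ once, then loops scenarios × replicates ×
methods with replicate-level sub-seeds shared across methods (identical
data per replicate), streams per-replicate chunks to disk (making
interrupted runs resumable bit-for-bit) and records one long-format row
per measure, with failures flagged rather than aborting the loop. The
paper-scale experiment (100 replicates, N = 1200/10000, p = 237, all
seven methods) is what the defaults describe; the test suite and the
acceptance script exercise the same code paths at reduced sizes — 237
exposures wherever the generator's calibration is the object under test
(its statistics and the scenario-level adjusted R², 100 replicates of
N = 1200), and 4–20 exposures with 150–600 observations for
selector-behaviour checks, where exhaustive-search oracles are feasible.
Scaled-down runs reproduce the qualitative selector contrasts (sparse
DSA models with low FDP and high AltSens under correlation; larger, more
sensitive penalized selections), but scenario-level mean-metric *ratios*
between methods are unstable at these sizes and are therefore computed by
the reporting layer without being asserted against the original
full-cohort values, which depended on the unavailable cohort matrix.

## Numerical choices and degenerate inputs

Incumbent updates in DSA require a relative RSS improvement above 1e-12;
candidate columns whose residual norm after projection is below 1e-10 of
their norm are skipped (rank protection). OLS on rank-deficient designs
falls back to the pseudo-inverse, flags the fit and reports NaN p-values
so a 100-replicate loop never aborts on collinear draws. Penalized
selection calls a coefficient nonzero above 1e-8 on the standardized
scale. The FISTA solver checks relative objective change every 10
iterations against tol = 1e-5 (tighter in tests). Constant outcomes give
a zero-tree BRT with zero importances. All randomness flows from
per-purpose `SeedSequence` streams derived from one master seed, so any
component can be regenerated independently and runs are reproducible
across platforms.

## Known limitations

* The generator matches marginal summary statistics, not the full joint
  structure of a real exposome; conclusions about method rankings at full
  scale therefore carry the usual caveat that a different Σ with the same
  marginals could shift them.
* Gaussian exposures and noise, linear true models, no confounders, no
  missing data, interactions of order two only — all by design of the
  emulated experiment.
* Group-lasso interaction coefficients are reported on the standardized
  product scale (selection and prediction are unaffected).
* Full-scale GLINTERNET and DSA₂ runs at p = 237 are computationally
  heavy (minutes per replicate); the sure-screening stage and the
  benchmark's resumability exist for exactly that use.
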