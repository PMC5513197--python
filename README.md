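# expobench

Simulation benchmark for **detecting two-way exposure interactions** with
variable-selection methods in an exposome setting.

Exposome-health studies measure hundreds of correlated environmental
exposures on the same participants and ask which of them — and which
*pairs* of them — drive a health outcome. `expobench` rebuilds, as a
tested Python pipeline, a systematic comparison of six selection methods
on synthetic exposome data:

* **EWAS₂** — two-step exposome-wide screening: marginal tests with a
  Benjamini–Yekutieli correction, then pairwise interaction tests among
  the survivors;
* **DSA₁ / DSA₂** — deletion/substitution/addition model search with the
  final size chosen by cross-validated RMSE, without (order 1) and with
  (order 2: quadratics + pairwise products) interaction terms;
* **Sun3step** — within-family collinearity screen → pruned regression
  tree (CART) → order-2 DSA on the surviving variables;
* **LASSO** — ℓ₁-penalized main-effects selection (3-fold CV);
* **GLINTERNET-style group lasso** — linear pairwise-interaction models
  under *strong hierarchy* via the overlapped group lasso: every candidate
  pair (i, j) owns a group θ⁽ⁱʲ⁾ = (θᵢ, θⱼ, θ_int) penalized by
  λ·√3·‖θ⁽ⁱʲ⁾‖₂, so a selected interaction always activates both mains;
* **BRT** — gradient-boosted regression trees (depth 4, ≤ 5000 trees) with
  backward variable elimination by split-gain importance.

## The simulation design

Exposures are drawn as **E ~ N(0, Σ)** with a 237 × 237 correlation matrix
Σ generated to match the marginal statistics of a real mother–child cohort
exposome: 81% of absolute pairwise correlations below 0.2, 64% below 0.1,
median |r| = 0.06, 78% of exposures having at least one partner with
|r| > 0.6, a 13-exposure block whose pairwise |r| all exceed 0.62 (mean
≈ 0.78) and a 13-exposure near-independent block. Outcomes follow

    Y = β₀ + β₁X₁ + … + β₅X₅ [+ γ₁₂X₁X₂ [+ γ₁₃X₁X₃]] + ε,   ε ~ N(0, σ),

with all βs equal to 1 and 21 tabulated sub-scenarios (0–2 interactions;
strong |γ| = 1 or moderate |γ| = 0.5, either sign; adjusted R² ≈ 0.1 or
0.3 via σ; predictors drawn from the whole exposome, from the
high-correlation block, or from the near-independent block). Each
replicate simulates a training set (N = 1200) and a validation set
(N = 10000); every method sees identical data and is scored with 13
measures — relative model size (RMS), relative number of variables (RNV),
relative out-of-sample R² (R²_rel), term/variable/interaction sensitivity
(Sens, Sensvar, Sens₂) and false-discovery proportions (FDP, FDPvar,
FDP₂), plus correlation-aware alternatives, e.g.

    AltSens = (1/n_A) Σ_{i∈A} max_{j∈B} |corr(X_i, X_j)|,

which credits a missed predictor when a strongly correlated proxy was
selected (AltFDP, AltSens₂, AltFDP₂ analogous).

## Worked example

```python
import numpy as np
from expobench import (GeneratorConfig, build_correlation_model,
                       summarize_correlations, SCENARIOS, simulate_study,
                       DSA, DSAConfig, evaluate)

model = build_correlation_model(GeneratorConfig(seed=1))
s = summarize_correlations(model)
print(f"|r|<0.2: {s.frac_below_02:.2f}   |r|<0.1: {s.frac_below_01:.2f}   "
      f"median |r|: {s.median_abs:.3f}   partner>0.6: {s.frac_partner_above_06:.2f}")

study = simulate_study(SCENARIOS["2e"], model, replicate_id=0, seed=7)
res = DSA(study.train_exposures, study.train_outcome,
          config=DSAConfig(maxorder=2, seed=7)).fit()
print(res.summary())
report = evaluate(res, study, model)
print(f"sens_var={report.sens_var:.2f}  alt_sens={report.alt_sens:.2f}  "
      f"fdp_var={report.fdp_var:.2f}  r2_rel={report.r2_rel:.2f}")
```

prints

```
|r|<0.2: 0.79   |r|<0.1: 0.62   median |r|: 0.059   partner>0.6: 0.78
Selection by DSA2
================================
terms selected     : 1
variables involved : 1
interaction terms  : 0
single fitted model: True
provides predictor : True
n_sweeps           : 9
chosen_size        : 1
terms:
  X2   4.1694
sens_var=0.20  alt_sens=0.85  fdp_var=0.00  r2_rel=0.87
```

The generated exposome reproduces the target correlation profile (first
line). On a high-correlation scenario with one strong interaction, DSA₂
collapses the five highly inter-correlated true predictors into a single
main effect: only one of five true predictors is recovered
(`sens_var = 0.20`), but it is a true one (`fdp_var = 0`), the remaining
predictors are represented through correlation (`alt_sens = 0.85`), and
the one-term model still captures 87% of the out-of-sample R² of the true
seven-coefficient model (`r2_rel = 0.87`) — the characteristic behaviour
of sparse selectors under strong exposure correlation.

Every selector follows the same pattern: a model object built from the
training data whose `fit()` returns a `SelectionResults` with the selected
`terms`, native coefficients, a `predict()` rule, per-stage `diagnostics`
and a `summary()` table. A command-line interface mirrors the library:

```bash
expobench benchmark --scenarios 1c,2e --methods LASSO,DSA2 --replicates 5 \
    --seed 7 --out runs/demo
expobench report --results runs/demo/results_long.csv --ratios DSA2:DSA1
expobench calibrate --seed 1 --scenario 2e
```

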