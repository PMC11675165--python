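# Methods

## The structural model

The package encodes the allostatic self-efficacy (ASE) account of fatigue
and depression as a linear-Gaussian structural causal model over age (A),
gender (G), metacognition of allostatic control (M), fatigue (F), general
self-efficacy (S) and depression (D):

```
A = N_a                G = N_g
M = θ1·A + θ2·G + N_m
F = θ3·M + θ4·A + θ5·G + N_f
S = θ6·A + θ7·G + N_s
D = θ8·F + θ9·S + θ10·F·S + θ11·A + θ12·G + N_d
```

with jointly independent noise; `N_g` is Bernoulli, all others Gaussian.
Assumptions inherited from this form: effects are linear and additive on
the raw questionnaire scales, noise is homoscedastic, gender is binary,
and there are no cycles, no latent confounders beyond A and G, and no
measurement error in the scores.

**The interaction term is not an edge.** `θ10·F·S` is an extra term in D's
equation; the DAG keeps only F→D and S→D. This keeps d-separation
semantics standard: the graph answers "which variables can influence
which", while the F·S term only changes the functional form of an
influence the graph already contains. Consequently `analytic_ace` refuses
treatment–outcome pairs whose directed paths pass through D when θ10 ≠ 0
(the effect is then not a single derivative), and the mixed derivative
∂²E[D | do(F, S)]/∂f∂s = θ10 is exposed separately.

**Interventions.** `do(X := x)` replaces X's equation by the constant;
all other equations are untouched. Noise is drawn once per call in the
fixed node order (A, G, M, S, F, D) from a single seeded generator, so a
seed fully determines a table and seeds are portable across interventions
on the same variable set (intervening on a node does not shift the draws
of the others).

## Synthetic cohort

`default_pbihb_like_config()` states the world the package tests itself
in: **N = 60 healthy adults**, age ~ Normal(30, 8) years, gender ~
Bernoulli(0.5), and raw-scale scores with means mid-range for each
instrument. The metacognition → fatigue coefficient is anchored at
**θ3 = −0.48** (the empirically plausible raw-scale value); the
interaction defaults to **θ10 = 0**. The remaining coefficients and noise
scales are package constants, chosen once so that each structural equation
has R² ≈ 0.1–0.3 — typical for questionnaire regressions — and so that
score distributions sit inside instrument bounds:

| parameter | value | | parameter | value |
|---|---|---|---|---|
| θ1 (A→M) | −0.06 | | θ7 (G→S) | 1.5 |
| θ2 (G→M) | −1.0 | | θ8 (F→D) | 0.45 |
| θ3 (M→F) | −0.48 | | θ9 (S→D) | −0.35 |
| θ4 (A→F) | 0.15 | | θ11 (A→D) | −0.05 |
| θ5 (G→F) | 2.0 | | θ12 (G→D) | 1.0 |
| θ6 (A→S) | 0.08 | | θ10 (F·S→D) | 0 |

noise sd: M 1.5, F 3.5, S 2.5, D 4.0; intercepts M 7.5, F 27.0, S 26.85,
D 8.0. The optional **questionnaire-range mode** clips each score to its
instrument bounds (M ∈ [0,10], FSS total ∈ [9,63], GSES ∈ [10,40], CES-D ∈
[0,60]) and then rounds to the instrument granularity — 0.5 for the MAIA
subscale sum (subscale scores are item means), integers elsewhere — with
ties rounded half away from zero. Clipping precedes rounding, and both
only move values toward the bounds, so rank orders are essentially
preserved (Spearman ρ > 0.99 at the default noise scales).

What the generator emulates: the joint dependence structure, effect sizes
and score discreteness of a small healthy-adult questionnaire cohort.
What it does not: item-level response processes, floor/ceiling pile-ups in
clinical samples, missingness, measurement error in M as a proxy
construct, or any non-Gaussian tail behaviour. A green simulation-based
test therefore establishes correctness of the statistical machinery under
the model's own assumptions, not robustness to their violation.

## Conditional-independence tests

**MIcg.** For continuous x, y and a mixed conditioning set, rows are
stratified by the joint configuration of the discrete conditioners
(a variable counts as discrete when it takes ≤ 5 integer levels, or when
forced via the `discrete` argument). Within stratum g of size N_g the
partial correlation r_g of x and y given the continuous conditioners is
computed from least-squares residuals; the statistic is Σ_g −N_g ln(1−r_g²)
— twice the Gaussian log-likelihood ratio of regressing y on (x +
continuous z) versus (continuous z) per stratum — referred to χ² with
**df = number of strata** (1 when no conditioner is discrete, 2 when
gender is conditioned on). Each stratum must contain at least
|continuous z| + 3 rows; a zero-variance residual or |r| = 1 raises a
degenerate-input error rather than returning an infinite statistic. The
asymptotic χ² reference is mildly anticonservative at N = 60 (measured
type-I error ≈ 0.015–0.03 at nominal 0.01 across seed streams); no
small-sample correction is applied because the statistic is defined as the
plain likelihood ratio.

**GCM.** x and y are each regressed on z — by gradient-boosted trees (300
trees, depth 2, learning rate 0.1, fixed seed; both fits share the seed so
the statistic is symmetric in x and y) or by closed-form least squares —
and T = √n · mean(R)/sd(R) of the residual products R_i is referred to a
standard normal, two-sided. sd is population-style (no df correction).
With an empty conditioning set this is a studentized test of zero
covariance. The boosted learner requires n ≥ 20; the linear learner only a
full-rank design.

**KCI.** Gaussian kernels on standardized inputs with median-heuristic
bandwidths; for a conditional test the x-kernel is computed on (x, z/2) so
it carries the conditioning information, the centered kernel matrices are
regressed out of z by kernel ridge regression (penalty 10⁻³), and the
trace statistic tr(K̃x|z · K̃y|z) is referred to a gamma null matched on its
first two moments. No permutations: results are deterministic given the
bandwidths (the `seed` argument is interface-only). Measured calibration:
nominal at conventional levels unconditionally; the conditional variant is
mildly liberal (≈ 0.09 at nominal 0.05 in a linear-confounder benchmark),
which is characteristic of the moment-matched null with a fixed ridge.

**Decisions.** `bonferroni_decide` sets each result's decision at
family_alpha / family_size — 0.05/5 = 0.01 for the five-statement family.

## Effect estimators

All three report a 95% two-sided interval and a **one-sided p-value in the
negative direction**, because both theory-driven hypotheses predict
negative effects; the pre-specified level is α = 0.017 (0.05/3 across the
three estimators).

**Covariate adjustment.** OLS of outcome on treatment plus the adjustment
set; t-based inference with the residual df. When a DAG is supplied the
adjustment set is checked against the backdoor criterion and an invalid
set is an error; without a DAG a warning is issued.

**Generalized propensity score.** A Gaussian linear model of the
continuous treatment on the covariates gives f̂(t|z); stabilized weights
f̂(t)/f̂(t|z) (Gaussian marginal numerator) enter a weighted least squares
of outcome on treatment alone, with HC0 robust standard errors.
**Weights are not truncated by default.** With a continuous treatment the
largest weights belong precisely to the observations whose treatment is
far from its conditional mean — the ones that identify the deconfounded
slope — and percentile truncation (1/99, upper-only, or 0.5/99.5) was
measured to bias the estimate by ≈ 0.04–0.06 on a true effect of −0.48 and
to drop interval coverage to 0.70–0.85. Untruncated weights recover the
truth (bias < 0.005, coverage 0.94 over 200 replicates at n = 5000).
Truncation remains available via the `truncate` argument for heavy-tailed
situations.

**DML.** Partially linear model with K-fold cross-fitting (default 5
folds): nuisances E[treatment|z] and E[outcome|z] are fit out-of-fold —
boosted trees by default, closed-form least squares as the `linear`
option — and θ̂ is the residual-on-residual slope. The standard error
comes from the empirical variance of the Neyman-orthogonal score,
intervals from normal quantiles. Deterministic given the seed. At study
scale (n = 60) the boosted nuisances are noisy and attenuate θ̂ toward
zero — visible in any flexible-learner DML at this n — so simulation
checks of estimator consistency use the linear option when the generating
model is itself linear.

**Interaction effect (θ10).** The regression route fits D on F, S, F·S
and the covariates and reads off the F·S coefficient, exactly matching the
structural form of D's equation. The propensity and DML routes treat
T = F·S as the continuous treatment with {F, S} added to the controls.
This treatment definition is a genuine design choice (the product is
nearly collinear with its factors); with strong factor–product collinearity
the propensity route's conditional density model can become
near-degenerate, so the regression route is the primary reading of θ10 and
the other two are triangulation.

## Hypothesis pipeline and graph revision

`run_hypothesis_1` evaluates the five J0-implied statements — M⊥S|A,G;
M⊥D|F,A,G; M⊥D|F,A,G,S; F⊥S|A,G; F⊥S|A,G,M — under each requested test
family at the Bonferroni-corrected 0.01 level. `run_hypothesis_2`
estimates θ3 for the primary adjustment set {A,G} and the sensitivity set
{A,G,S} (both valid under the backdoor criterion in J0 and J1, so their
asymptotic agreement is itself a model check). `run_hypothesis_3`
estimates θ10 for {A,G} and {A,G,M}.

`reconcile_single_edge` scores every single-edge addition that keeps the
graph acyclic: a candidate predicts "not rejected" exactly when it
d-separates the tested statement, and candidates are ranked by mismatch
count with lexicographic tie-breaking (the unmodified graph is the
baseline and wins ties). Candidate endpoints are restricted by default to
the questionnaire scores {M, F, S, D} — age and gender are exogenous
demographics, not plausible targets of revision — and the restriction can
be lifted. Method votes per statement collapse to one decision by
**majority vote** (ties resolve to "not rejected", the reading that keeps
the graph unrevised absent a majority against it); a single method can be
selected instead. On decision patterns like the published ones (M⊥S|A,G,
M⊥D|F,A,G and F⊥S|A,G rejected; the other two retained) the unique
zero-mismatch single-edge revisions are M→S and S→M, and the tie-break
ranks M→S first — the revised graph J1.

## Numerical conventions

- Randomness: one `numpy` Generator seeded per sampling call; replicate
  seeds in tests derive from a meta-seed and stay below 2³¹.
- d-separation: reachability on the moralized ancestral subgraph;
  exhaustively equal to a brute-force path-enumeration oracle (and to
  networkx's implementation) on every DAG with ≤ 4 nodes.
- Degenerate inputs raise typed errors (`DegenerateInputError`,
  `EstimationError`, `GraphError`, `CohortError`) rather than returning
  non-finite statistics; the CLI maps schema errors to exit code 2 and
  estimation errors to 3.
- Rounding in range mode: clip, then round to granularity, ties away from
  zero.

## Known limitations

- The MIcg χ² reference is anticonservative at N = 60 (see above); at the
  published study scale, borderline rejections near p ≈ 0.01 should be
  read cautiously.
- The conditional KCI gamma null is mildly liberal; it is used as a
  sensitivity check, not the primary test.
- With questionnaire-scale effect sizes (partial correlations ≈ 0.06),
  n = 5000 gives only ≈ 85% power for the weakest induced dependence in
  the revised-graph world; joint five-statement decision patterns
  therefore reproduce the revised graph's signature in ≈ 78% of
  replicates, not ≥ 90%.
- The propensity and DML readings of θ10 inherit the factor–product
  collinearity problem above; small-sample DML attenuates effects.
- Nothing here addresses latent confounding, cycles, measurement error,
  or longitudinal dynamics; the package tests the stated model, it does
  not discover models.
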