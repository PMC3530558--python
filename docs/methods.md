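# Methods

This note documents the statistical model, the numerical choices, and the
design decisions behind `phenomm`, in the spirit of a package vignette. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Model and assumptions

For animal *i* in batch *j* (batch = all animals assayed on one day):

    Y_ij = β₀ + β₁ G_i + β₂ S_i + β₃ W_i + β₄ G_i S_i + u_j + ε_ij

- `G` genotype (0 wildtype, 1 knockout; zygosity collapsed — one mutant
  genotype is analysed per line), `S` sex (0 female, 1 male), `W` body
  weight in grams.
- `u_j ~ N(0, σ_u²)` iid across batches. Batch is treated as a *random*
  effect: assay days are a random sample of possible days, nobody cares
  about Wednesday's mean per se, and a random intercept spends one variance
  parameter rather than one df per day (~170 days in a control archive).
  Batch is a composite of day, technician, cage and litter effects; no
  attempt is made to decompose it.
- `ε_ij ~ N(0, σ_e²)`, optionally with separate σ_e² for wildtype and
  knockout animals (the heterogeneous-residual analogue of nlme's
  `varIdent`).
- With weight in the model (eq2), the weight–trait relationship is assumed
  linear with a common slope (homogeneity of regression).

eq1 omits the β₃ term; eq2 includes it. Comparing the two genotype calls
classifies weight mediation (below). Body weight itself is a phenotype and
is analysed under eq1 only — it cannot be its own covariate, and call
tables report `NA` for weight × eq2.

## Fitting

The marginal covariance is block-diagonal by batch, so every likelihood
evaluation reduces via the Woodbury identity to per-batch, per-genotype
sufficient statistics (`O(B·p²)` per evaluation, no per-observation work
inside the optimiser). The residual scale and the fixed effects are
profiled out analytically, leaving at most two free parameters: the
variance ratio γ = σ_u²/σ_e²(wt) ∈ [0, ∞) and the log residual-variance
ratio d = log σ_e²(ko)/σ_e²(wt). These are maximised by L-BFGS-B from a
moment-based start plus fixed fallbacks; convergence tolerance 1e-12 on the
objective, 200 iterations per start. Fits are deterministic. γ estimated at
the boundary is reported as exactly σ_u² = 0 — a singular fit is a result,
not an error. Weight is centred at the control mean before fitting so the
intercept is interpretable at a realistic body weight; this is a pure
reparameterisation (the raw-weight intercept is recoverable from the fit).

REML fits agree with `statsmodels` MixedLM to ~1e-6 in log-likelihood on
homogeneous models (tested); the heterogeneous-residual structure is not
available in statsmodels, which is why the engine is implemented here.

## The top-down pipeline

Starting from the fully loaded model of the chosen equation:

1. **Random structure.** Keep the batch intercept iff the REML LRT against
   the model without it rejects at p < 0.05, using the 50:50 mixture of a
   point mass at zero and χ²(1) — the boundary-corrected reference for a
   variance component; a plain χ²(1) would be conservative and distort
   retention rates. Single-batch datasets drop the intercept without
   testing.
2. **Residual structure.** Homogeneous vs genotype-stratified σ_e² by REML
   LRT (χ²(1)); skipped (homogeneous kept) when either genotype group has
   fewer than 3 animals.
3. **Fixed-effect reduction.** Non-genotype terms are removed one at a
   time by ML LRTs (largest p first, re-testing after each removal) at
   p < 0.05. REML is used for variance-structure comparisons and final
   estimates, ML wherever fixed effects differ, since REML likelihoods are
   not comparable across fixed-effect structures. **Both genotype terms
   (β₁ and β₄) are exempt from screening.** Screening the interaction
   first and then testing it jointly at step 4 creates a selection
   circularity: under the null, the interactions that survive a p < 0.05
   screen are precisely the spuriously extreme ones, and replicates
   retaining them reject at step 4 over 60% of the time, inflating overall
   type-I error from ~0.05 to ~0.09 (measured by simulation at the
   confounded design below). Exempting the hypothesis terms removes the
   circularity. A consequence is that sex, protected by the model
   hierarchy while the interaction is present, is effectively only
   removable in interaction-free models; with cohorts of 7 + 7 this costs
   little.
4. **Genotype test.** With the random intercept present: a REML Wald test
   of {β₁, β₄} — t for a single contrast, joint F otherwise — with
   Satterthwaite denominator degrees of freedom (the lmerTest / SAS PROC
   MIXED correction; joint df pooled over eigencontrasts). The df are
   computed from the curvature of the REML likelihood in the variance
   components (finite-difference Hessian, relative step 1e-4). This
   matters: mutants typically occupy only ~4 batches, so the genotype
   contrast has few effective degrees of freedom and a χ²-referenced LRT
   rejects at ~0.09 instead of 0.05 at the study conditions used in the
   acceptance suite; the Satterthwaite test is calibrated (~0.05 at a
   fixed specification) and agrees with R's lmerTest to ≥ 4 decimals in t,
   F, df and p (cross-checked in development). Without random effects the
   model is ordinary regression and the test is the joint ML LRT, which
   matches an independent OLS computation to < 1e-8 (tested). The final
   model is refitted by REML for reported estimates. The reported effect
   is β₁ + β₄/2 (sex-averaged), with per-sex effects β₁ (female) and
   β₁ + β₄ (male) alongside; the direction arrow follows the sex-averaged
   sign.
5. **/6. Diagnostics.** Emitted as numeric series, not gates: Q-Q data for
   batch means, BLUPs and conditional residuals per genotype,
   residual-vs-fitted per genotype, weight-vs-trait when modelled, and a
   runs test on time-ordered batch means. Visual inspection is the
   intended use.

**Multiplicity.** Genotype p-values are Benjamini–Hochberg adjusted to
control FDR at 0.05. The family is all traits × equations analysed in one
invocation — a pragmatic, configurable choice; the family definition is
recorded in the output. Model-building tests (steps 1–3) are unadjusted by
design: they select a model, they are not the inference.

**Mediation categories** (same trait and line, threshold on adjusted p):
eq1 significant only → `weight_mediated`; both significant, same sign →
`direct_beyond_weight`; both, opposite signs → `reversed_after_weight`;
eq2 only → `direct_no_weight_phenotype`; neither → `not_significant`.

## Reference range

Per sex, the band is the 2.5th–97.5th percentile of matched wildtype
values, computed by linear interpolation between order statistics (NumPy's
default, the Hyndman–Fan type 7 convention). The convention is configurable
because the band edges shift slightly with it; whichever is used is
recorded. A warning flags bands built from fewer than 120 controls, the
usual minimum in reference-interval practice. A mutant cohort is abnormal
when at least 60% of animals lie *strictly* beyond the *same* side of the
band (values equal to an edge count as inside — the tie-break is
undocumented in portal implementations and had to be fixed somewhere);
3 high + 2 low out of 7 is normal.

Two false-positive computations are provided for null mutants against a
perfectly estimated band. The **exact** rate enumerates the trinomial
(below, inside, above) outcome space with 2.5% per tail and returns the
probability that either direction alone reaches the threshold — the true
rate of the implemented call (≈ 3.9×10⁻⁷ for n = 7 at 60%). The
**binomial** sketch returns the upper tail of B(n, 0.05) — animals outside
either end, direction ignored (≈ 6×10⁻⁶ for n = 7; ≈ 1.2×10⁻⁵ for either
of two sexes via 1 − (1 − p)²). The sketch is the figure usually quoted
and overstates the directional rate ~15-fold; both are reported so the
discrepancy is visible rather than buried. The exact rate is verified
against Monte-Carlo in the acceptance suite, at the 60% threshold and at a
30% threshold where the rate is large enough to pin down sharply.

## Control diagnostics

`variance_fractions` attributes control trait variance to sex, weight,
batch and residual. Sex and weight take incremental explained sums of
squares from sequential OLS fits — incremental fractions are
order-dependent, so the order (sex, then weight) is fixed and recorded.
Batch takes σ_u²/s²_Y from a REML random-intercept fit rather than a
batch-as-fixed-factor R², which would inflate with ~170 levels. The
residual takes the remainder; if sampling noise pushes the explained sum
past 1 the explained parts are renormalised (flagged).

`runs_test_batch_means` is the Wald–Wolfowitz runs test about the median
of time-ordered batch means (values equal to the median dropped): exact
runs distribution up to 30 retained values, normal approximation (no
continuity correction) above. The approximation's two-sided rejection rate
at n = 100 is 0.0555 by exact enumeration, which is why no continuity
correction is applied — with it the test is conservative (0.034).

## The simulator

`simulate.generate_dataset` draws studies with exactly the structure the
model assumes: Gaussian iid batch intercepts, Gaussian residuals
(optionally per genotype), weight per animal from its sex mean plus a
knockout shift plus noise, and the trait as the linear combination above.
Mutants are placed in their own batches by default (asynchronous controls
— the confounded layout that breaks pooled tests); controls form weekly
cohorts. Batch labels are ISO dates a week apart so diagnostics can order
them. The seed is split (NumPy `SeedSequence.spawn`) into independent
streams for batch effects, weights and residuals.

Defaults model a DEXA fat-mass-like trait: β₀ = 8, β₂ = 1, β₃ = 0.25
trait-units/g, σ_u = 0.7, σ_e = 1.0, weight means 22/28 g (f/m) with SD
2.5 g, 20 control batches × 5, 7 mutants per sex in 4 batches. These sizes
put batch at roughly a quarter of control trait variance, matching what
large control archives show, and mirror a weekly high-throughput pipeline.

Named scenarios fix the parameter sets used throughout the tests:
`null_confounded` (no effect anywhere, σ_u = σ_e = 1 — the t-test trap),
`direct_effect` (β₁ = 1.5), `weight_mediated` (weight −4 g, β₃ = 0.4, no
direct effect), `reversed_after_weight` (weight −9 g, β₃ = 0.5, direct
+2.4 — a dwarf carrying more fat than its size predicts; magnitudes sized
for ~90% power of each component call under the Satterthwaite F at these
cohort sizes, so the joint pattern appears in a clear majority of
replicates), and `no_batch` (σ_u = 0).

What the simulator does *not* emulate — and therefore what passing tests
do not establish about real data: non-Gaussian or heavy-tailed batch
effects, temporal drift or autocorrelation across days (batch effects are
exchangeable by construction), batch effects on body weight itself,
litter/cage substructure within batch, missing-data mechanisms beyond
missing-at-random weights, and measurement error in weight. Calibration
results here say the machinery is correct under its own assumptions; the
diagnostics module exists because real data must earn those assumptions.

## Numerical and edge-case policy

- Convergence: objective tolerance 1e-12, ≤ 200 iterations per start,
  multiple starts; non-convergence raises a fitting error with
  diagnostics.
- σ_u² at the boundary reports exactly 0; constant data (zero residual
  variance) is handled without crashing and reports σ_e² = 0.
- "Outside" a reference band is strict inequality; band edges are inside.
- Batch labels are opaque strings; temporal ordering is attempted only
  when all labels parse as ISO dates, otherwise input order is used.
- Records missing weight are used by eq1 and excluded (with a logged
  count) by eq2.
- Single-sex datasets drop sex and interaction terms up front (logged);
  single-batch datasets drop the random intercept without testing.
- Problem sizes in the acceptance suite (1000 null replicates, 200
  replicates per recovery/mediation check, 10⁶ reference-range draws, 500
  runs-test replicates) balance the sharpness of the statistical
  assertions against a few minutes of runtime on one core.

## Known limitations

- No random slopes, crossed random effects, or non-Gaussian responses.
- Only two residual structures (homogeneous, genotype-stratified); the
  candidate set is deliberately small and extensible.
- The Satterthwaite approximation, while standard, is itself approximate;
  with very few batches the genotype test is approximately, not exactly,
  calibrated (the acceptance suite bounds it within the 99% binomial
  envelope at the confounded design).
- The step-2 structure pre-test still induces a small selection effect on
  step 4 (measured as ~1 point of type-I at the acceptance design);
  removing it entirely would mean always fitting stratified residuals,
  which 14-animal cohorts cannot support.
- The FDR family is per invocation; cross-release or cross-line family
  definitions are the caller's responsibility.
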