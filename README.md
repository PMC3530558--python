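# phenomm

Phenotype calling for batch-structured knockout-mouse data: linear mixed
models with a batch random intercept, body-weight mediation classification,
and percentile reference ranges.

## The problem

High-throughput mouse phenotyping pipelines measure quantitative traits
(DEXA body composition, clinical chemistry, morphometrics) on small cohorts
of knockout animals — typically 7 per sex — that trickle into the pipeline
in several small **batches** (assay days) as breeding allows, while control
animals accumulate on other days. Day-to-day variation is large: in control
archives, batch alone explains on the order of a quarter of trait variance.
Because mutants and controls are rarely measured on the same day, batch
*confounds* genotype, and a pooled Student's *t*-test or ANOVA — which
assumes independent observations from one population — rejects far too
often. Body weight adds a second confounder: knockouts frequently differ in
weight, and most body-composition traits track weight, so a naive genotype
hit may be nothing more than the weight phenotype in disguise.

`phenomm` addresses both problems for anyone calling phenotypes from
per-animal tables: mixed-model analysts in phenotyping consortia, and
smaller labs whose experiments span multiple collection days.

## The model

For animal *i* in batch *j*, a trait *Y* is modelled as

    Y_ij = β₀ + β₁·genotype_i + β₂·sex_i + β₃·weight_i + β₄·genotype_i·sex_i + u_j + ε_ij

with batch intercepts `u_j ~ N(0, σ_u²)` iid and residuals
`ε_ij ~ N(0, σ_e²)` (optionally a separate σ_e² per genotype group).
Genotype is coded 0 = wildtype, 1 = knockout; sex 0 = female, 1 = male.
Two nested variants are run per trait: **eq1** without the weight term and
**eq2** with it. A trait significant under eq1 but not under eq2 is a
*weight-mediated* phenotype; significant under both with opposite signs is
*reversed after weight adjustment* (the change is less than the weight
change predicts); and so on.

Each model is built top-down: (1) keep or drop the batch random intercept
(REML LRT, boundary-corrected); (2) choose homogeneous vs per-genotype
residual variance (REML LRT); (3) drop non-significant covariates (ML LRTs,
respecting hierarchy — genotype terms are exempt, they are the hypothesis);
(4) test genotype: a REML Wald F test of {β₁, β₄} with Satterthwaite
denominator degrees of freedom when the random intercept is present (with
mutants in a handful of batches, a χ² reference is badly anticonservative),
or the ML likelihood-ratio test — ordinary regression — when it is not.
Genotype p-values are Benjamini–Hochberg adjusted across the analysis
family (FDR 0.05). Steps 5–6 are assumption diagnostics (Q-Q data for batch
means, BLUPs and conditional residuals; residual-vs-fitted; a runs test for
batch-mean autocorrelation).

The package also implements the **reference-range** (RR) caller used by
phenotyping portals: the central 95% percentile band of matched controls
per sex, with a cohort called abnormal when ≥ 60% of mutants fall beyond
the same side of the band, plus the exact false-positive arithmetic of that
rule (for 7 mutants: ~6×10⁻⁶ per sex by the usual pooled-binomial sketch,
~3.9×10⁻⁷ for the directional rule it actually applies).

## Worked example

Simulate a study whose knockout is a dwarf (−9 g) with a direct fat-mass
increase partially hidden by the weight loss, then analyse it:

```sh
phenomm simulate --scenario reversed_after_weight --seed 42 --out study.csv
phenomm analyze --input study.csv --line-id Demo1 --out-dir results
```

`results/calls.tsv` (abridged):

| trait    | equation | p        | p_adjusted | direction | effect | formula |
|----------|----------|----------|------------|-----------|--------|---------|
| fat_mass | eq1      | 1.2e-07  | 1.8e-07    | decrease  | −3.09  | y ~ 1 + genotype + sex + genotype:sex |
| fat_mass | eq2      | 4.6e-02  | 4.6e-02    | increase  | +1.26  | y ~ 1 + genotype + sex + weight + genotype:sex + (1\|batch) |
| weight   | eq1      | 3.8e-18  | 1.1e-17    | decrease  | −8.72  | y ~ 1 + genotype + sex + genotype:sex |
| weight   | eq2      | NA       |            | NA        |        | NA |

and `results/mediation.tsv` classifies fat_mass as
`reversed_after_weight`: without weight in the model the knockout's fat
mass is 3.1 g *lower* than controls (it is a small mouse), but *given its
weight* it carries 1.3 g more fat than expected — the biologically
interesting call, invisible to any method that cannot adjust for weight.
Weight itself is reported under eq1 only; `NA` marks that weight cannot be
its own covariate.

The same table can be produced from your own LIMS export by mapping column
roles: `--column-map roles.yaml` with entries like
`{animal_id: MOUSE_ID, genotype: Genotype, sex: Gender, batch: ASSAY_DATE}`.

## Layout

- `phenomm.data` — records, validation, delimited-table I/O
- `phenomm.lmm` — the mixed-model engine (profiled ML/REML, Satterthwaite)
- `phenomm.pipeline` — the top-down steps, FDR, mediation classification
- `phenomm.refrange` — percentile bands, the ≥60% call, exact FPR
- `phenomm.diagnostics` — variance fractions, runs test, Q-Q series
- `phenomm.simulate` — the study generator and named scenarios
- `phenomm.cli` — `phenomm analyze | rr | simulate | diagnose`

See `docs/methods.md` for the statistical details and design rationale.
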