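"""Top-down model-building pipeline for genotype phenotype calls.

Starting from the fully loaded model of the chosen equation (eq1: genotype,
sex, genotype:sex; eq2 additionally body weight), the pipeline

1. selects the random-effect structure (keep or drop the batch random
   intercept) by REML likelihood-ratio test with the boundary-corrected
   reference distribution;
2. selects the residual covariance structure (homogeneous vs per-genotype
   residual variance) by REML likelihood-ratio test;
3. reduces the fixed effects, removing non-significant non-genotype terms
   by ML likelihood-ratio tests while respecting the model hierarchy; the
   genotype terms (main effect and genotype:sex interaction) are the
   hypothesis of step 4 and are never screened here — pre-testing them
   would bias the genotype test;
4. tests the genotype effect: with a batch random intercept, a REML Wald
   t/F test of all genotype terms with Satterthwaite denominator degrees of
   freedom (mutants sit in few batches, so a chi-square reference would be
   anticonservative); without random effects, the joint ML likelihood-ratio
   test, identical to ordinary regression.  The final model is refitted by
   REML for reported estimates.

Steps 5–6 (assumption checks and diagnostic plots) live in
:mod:`phenomm.diagnostics`.

REML is used wherever fixed effects are identical between the compared
models (variance-structure selection, final estimates) and ML wherever they
differ (fixed-effect reduction and the genotype test), since REML
likelihoods are not comparable across fixed-effect structures.

Model-building decisions use an unadjusted p < 0.05 threshold.  The genotype
p-values — the hypothesis of primary interest — are adjusted across the
analysis family by Benjamini–Hochberg to control the false discovery rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data import TraitDataset
from .errors import InsufficientDataError, ValidationError
from .lmm import (HOMOGENEOUS, STRATIFIED, FitResult, ModelSpec, fit_model,
                  full_spec, lrt_pvalue, satterthwaite_genotype_test)

MODEL_BUILDING_ALPHA = 0.05

INCREASE = "increase"
DECREASE = "decrease"
NONE = "none"


@dataclass
class GenotypeCall:
    """The pipeline verdict for one trait x line x equation."""

    trait_name: str
    line_id: str
    equation: str
    p_value: float
    effect_estimate: float
    final_spec: ModelSpec
    n_mutant: int
    n_control: int
    n_batches: int
    p_adjusted: float | None = None
    effect_by_sex: dict[str, float] | None = None
    fit: FitResult | None = None
    log: list[dict] = field(default_factory=list)
    alpha: float = 0.05

    @property
    def p_effective(self) -> float:
        """Adjusted p when the family adjustment has been applied, else raw."""
        return self.p_value if self.p_adjusted is None else self.p_adjusted

    @property
    def significant(self) -> bool:
        return self.p_effective < self.alpha

    @property
    def direction(self) -> str:
        if not self.significant:
            return NONE
        return INCREASE if self.effect_estimate > 0 else DECREASE


MEDIATION_CATEGORIES = (
    "not_significant",
    "weight_mediated",
    "direct_beyond_weight",
    "reversed_after_weight",
    "direct_no_weight_phenotype",
)


@dataclass
class MediationCategory:
    """Eq.1-vs-Eq.2 comparison: is the trait change explained by body weight?"""

    category: str
    eq1_call: GenotypeCall
    eq2_call: GenotypeCall


def _fit_pair(data, spec_full, spec_reduced, objective, df, boundary=False):
    f1 = fit_model(data, spec_full, objective)
    f0 = fit_model(data, spec_reduced, objective)
    stat, p = lrt_pvalue(f1.loglik, f0.loglik, df, boundary=boundary)
    return f1, f0, stat, p


# ---------------------------------------------------------------------------
# the four model-building steps
# ---------------------------------------------------------------------------

def step1_select_random_effects(
    data: TraitDataset, spec: ModelSpec,
    alpha: float = MODEL_BUILDING_ALPHA, log: list | None = None,
) -> ModelSpec:
    """Keep the batch random intercept iff the boundary-corrected REML LRT rejects.

    With a single batch the intercept is not identifiable and is dropped
    without testing.
    """
    if not spec.random_intercept_batch:
        raise ValidationError("step 1 expects a spec with the batch random intercept")
    if data.n_batches < 2:
        if log is not None:
            log.append({"step": 1, "action": "drop_random_intercept",
                        "reason": "single batch, untestable"})
        return replace(spec, random_intercept_batch=False)
    _, _, stat, p = _fit_pair(
        data, spec, replace(spec, random_intercept_batch=False),
        "REML", df=1, boundary=True,
    )
    keep = p < alpha
    if log is not None:
        log.append({"step": 1, "action": "keep_random_intercept" if keep
                    else "drop_random_intercept", "lrt_stat": stat, "p": p})
    return spec if keep else replace(spec, random_intercept_batch=False)


def step2_select_residual_structure(
    data: TraitDataset, spec: ModelSpec,
    alpha: float = MODEL_BUILDING_ALPHA, log: list | None = None,
) -> ModelSpec:
    """Homogeneous vs genotype-stratified residual variance by REML LRT.

    With fewer than 3 observations in either genotype group the comparison is
    skipped and the homogeneous structure kept.
    """
    if min(data.n_knockout, data.n_wildtype) < 3:
        if log is not None:
            log.append({"step": 2, "action": "keep_homogeneous",
                        "reason": "a genotype group has < 3 observations"})
        return replace(spec, residual_structure=HOMOGENEOUS)
    strat = replace(spec, residual_structure=STRATIFIED)
    homo = replace(spec, residual_structure=HOMOGENEOUS)
    _, _, stat, p = _fit_pair(data, strat, homo, "REML", df=1)
    stratified = p < alpha
    if log is not None:
        log.append({"step": 2, "action": "stratified" if stratified
                    else "homogeneous", "lrt_stat": stat, "p": p})
    return strat if stratified else homo


def _removal_p(data, spec, term):
    _, _, _, p = _fit_pair(data, spec, spec.drop(term), "ML", df=1)
    return p


def step3_reduce_fixed_effects(
    data: TraitDataset, spec: ModelSpec,
    alpha: float = MODEL_BUILDING_ALPHA, log: list | None = None,
) -> ModelSpec:
    """Iteratively remove non-significant non-genotype fixed effects (ML LRTs).

    Candidates are removed one at a time, largest p first, re-testing after
    each removal.  Genotype terms — the main effect and the genotype:sex
    interaction — are exempt: they are the hypothesis tested at step 4, and
    screening them here would bias that test (a spuriously extreme
    interaction that survives a p < 0.05 screen is then all but guaranteed a
    small joint-test p-value).  While the interaction is present the sex
    main effect is protected by the model hierarchy, so in practice only
    weight (eq2) and, in interaction-free models, sex are removable.
    """
    while True:
        candidates = [t for t in ("weight", "sex")
                      if getattr(spec, f"include_{t}")
                      and not (t == "sex" and spec.include_interaction)]
        if not candidates:
            break
        pvals = {t: _removal_p(data, spec, t) for t in candidates}
        worst = max(pvals, key=pvals.get)
        if pvals[worst] >= alpha:
            spec = spec.drop(worst)
            if log is not None:
                log.append({"step": 3, "term": worst, "action": "removed",
                            "p": pvals[worst]})
        else:
            if log is not None:
                for t, p in pvals.items():
                    log.append({"step": 3, "term": t, "action": "retained", "p": p})
            break
    return spec


def step4_test_genotype(
    data: TraitDataset, spec: ModelSpec, equation: str = "eq1",
    alpha: float = 0.05, log: list | None = None,
) -> GenotypeCall:
    """Two-sided test of all genotype terms; REML refit for reported estimates.

    When the batch random intercept is retained the test is a REML Wald t
    (or joint F with the interaction) with Satterthwaite denominator degrees
    of freedom: mutants typically occupy only a few batches, so the genotype
    contrast has few effective degrees of freedom and a chi-square reference
    would reject far too often.  Without random effects the model is
    ordinary regression and the test is the joint ML likelihood-ratio test.
    """
    if not spec.include_genotype:
        raise ValidationError("step 4 requires the genotype term in the model")
    if spec.random_intercept_batch:
        stat, df, df_den, p, final = satterthwaite_genotype_test(data, spec)
        entry = {"step": 4, "test": "wald_satterthwaite", "stat": stat,
                 "df_num": df, "df_den": df_den, "p": p}
    else:
        null = spec.drop("interaction").drop("genotype") \
            if spec.include_interaction else spec.drop("genotype")
        df = 2 if spec.include_interaction else 1
        _, _, stat, p = _fit_pair(data, spec, null, "ML", df=df)
        final = fit_model(data, spec, "REML")
        entry = {"step": 4, "test": "ml_lrt", "lrt_stat": stat, "df": df, "p": p}
    effect = final.genotype_effect()
    by_sex = None
    if spec.include_interaction:
        by_sex = {"female": final.genotype_effect("female"),
                  "male": final.genotype_effect("male")}
    if log is not None:
        log.append({**entry, "effect": effect})
    counts = data.counts_by_group()
    return GenotypeCall(
        trait_name=data.trait_name, line_id=data.line_id, equation=equation,
        p_value=p, effect_estimate=effect, effect_by_sex=by_sex,
        final_spec=spec, fit=final, alpha=alpha,
        n_mutant=data.n_knockout, n_control=data.n_wildtype,
        n_batches=data.n_batches, log=list(log) if log is not None else [],
    )


def run_pipeline(
    data: TraitDataset, equation: str, alpha: float = 0.05,
    model_alpha: float = MODEL_BUILDING_ALPHA,
) -> GenotypeCall:
    """Run steps 1–4 from the full model of ``equation`` on one trait dataset.

    eq2 (weight as covariate) cannot be applied to weight itself, and
    excludes records with missing weight (exclusions are logged).
    """
    log: list[dict] = []
    if equation == "eq2":
        if data.trait_name == "weight":
            raise ValidationError(
                "weight as the variable of interest cannot be fitted with eq2 "
                "(weight is its covariate); report NA instead"
            )
        with_w = data.restrict(require_weight=True)
        n_dropped = len(data) - len(with_w)
        if n_dropped:
            log.append({"step": 0, "action": "excluded_missing_weight",
                        "n": n_dropped})
        try:
            data = TraitDataset(data.trait_name, data.line_id, with_w)
        except InsufficientDataError as exc:
            raise InsufficientDataError(f"step 0 (weight filter): {exc}") from exc
    spec = full_spec(equation)
    sexes = {r.sex for r in data.records}
    if len(sexes) == 1:
        # sex and the interaction are unidentifiable in a single-sex cohort
        spec = spec.drop("interaction").drop("sex")
        log.append({"step": 0, "action": "dropped_sex_terms",
                    "reason": f"single-sex dataset ({sexes.pop()})"})
    try:
        spec = step1_select_random_effects(data, spec, model_alpha, log)
        spec = step2_select_residual_structure(data, spec, model_alpha, log)
        spec = step3_reduce_fixed_effects(data, spec, model_alpha, log)
        call = step4_test_genotype(data, spec, equation, alpha, log)
    except InsufficientDataError as exc:
        step = next((e["step"] for e in reversed(log) if "step" in e), "?")
        raise InsufficientDataError(f"after step {step}: {exc}") from exc
    return call


# ---------------------------------------------------------------------------
# family-wise adjustment and mediation classification
# ---------------------------------------------------------------------------

def adjust_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order, capped at 1."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def apply_fdr(calls: Iterable[GenotypeCall]) -> list[GenotypeCall]:
    """Adjust genotype p-values across one analysis family, in place.

    The family is whatever collection of calls is passed — by convention all
    traits x equations analysed in one invocation.
    """
    calls = list(calls)
    adj = adjust_fdr([c.p_value for c in calls])
    for c, a in zip(calls, adj):
        c.p_adjusted = float(a)
    return calls


def classify_mediation(
    eq1_call: GenotypeCall, eq2_call: GenotypeCall, threshold: float = 0.05,
) -> MediationCategory:
    """Compare eq1 and eq2 calls for the same trait and line.

    significant under eq1 only            -> weight_mediated
    significant under both, same sign     -> direct_beyond_weight
    significant under both, opposite sign -> reversed_after_weight
    significant under eq2 only            -> direct_no_weight_phenotype
    neither                               -> not_significant
    """
    if (eq1_call.trait_name, eq1_call.line_id) != (eq2_call.trait_name, eq2_call.line_id):
        raise ValidationError("mediation classification requires calls for the "
                              "same trait and line")
    if (eq1_call.equation, eq2_call.equation) != ("eq1", "eq2"):
        raise ValidationError("expected one eq1 call and one eq2 call, in that order")
    s1 = eq1_call.p_effective < threshold
    s2 = eq2_call.p_effective < threshold
    if s1 and not s2:
        cat = "weight_mediated"
    elif s1 and s2:
        same = (eq1_call.effect_estimate > 0) == (eq2_call.effect_estimate > 0)
        cat = "direct_beyond_weight" if same else "reversed_after_weight"
    elif s2:
        cat = "direct_no_weight_phenotype"
    else:
        cat = "not_significant"
    return MediationCategory(category=cat, eq1_call=eq1_call, eq2_call=eq2_call)


def naive_pooled_test(data: TraitDataset) -> float:
    """Two-sided Student's t-test of knockout vs wildtype, ignoring batch and sex.

    The traditional comparison that treats all animals as independent.  Used
    as the contrast showing type-I inflation under batch confounding; not
    part of the calling pipeline.
    """
    ko = data.values(genotype="knockout")
    wt = data.values(genotype="wildtype")
    return float(stats.ttest_ind(ko, wt, equal_var=True).pvalue)
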