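"""Control-data characterisation and per-fit model diagnostics.

Two kinds of checks support the mixed-model assumptions (iid Gaussian batch
effects, iid Gaussian residuals, linear weight relationship):

* control-archive summaries — how much trait variance is attributable to
  sex, body weight and batch, whether batch means look Gaussian, and a runs
  test for autocorrelation of batch means over time;
* per-fit diagnostics — Q-Q series for batch means, BLUPs and conditional
  residuals (per genotype group), residual-vs-fitted scatter per genotype,
  and the weight-vs-trait scatter when weight is modelled.

Everything is emitted as numeric series; rendering plots is a separate,
optional concern.  There is no automated pass/fail gate — these are data
for visual inspection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb

import numpy as np
from scipy import stats

from .data import TraitDataset, WILDTYPE, batch_temporal_order
from .errors import InsufficientDataError, ValidationError
from .lmm import FitResult, ModelSpec, fit_model

#: above this many batch means the runs test switches to the normal approximation
RUNS_EXACT_CUTOFF = 30


@dataclass
class VarianceFractions:
    """Proportion of control trait variance attributed to each source.

    Sex and weight fractions are incremental explained sums of squares from
    sequential linear fits (order: sex, then weight — incremental fractions
    are order-dependent, so the order is fixed and recorded).  The batch
    fraction is the REML batch variance component over total variance, which
    avoids the degrees-of-freedom inflation of treating ~170 assay days as a
    fixed factor.  The residual takes the remainder so the four sum to 1.
    """

    trait_name: str
    frac_sex: float
    frac_weight: float
    frac_batch: float
    frac_residual: float
    n: int
    n_batches: int
    attribution_order: tuple[str, ...] = ("sex", "weight", "batch")
    warnings: list[str] = field(default_factory=list)


@dataclass
class DiagnosticBundle:
    """Numeric series behind the standard mixed-model diagnostic plots.

    Q-Q entries are (theoretical, sample) pairs with the sample axis sorted
    ascending; scatter entries are (x, y) pairs.
    """

    qq_batch_means: tuple[np.ndarray, np.ndarray]
    qq_blups: tuple[np.ndarray, np.ndarray]
    qq_residuals_per_genotype: dict[str, tuple[np.ndarray, np.ndarray]]
    residual_vs_fitted_per_genotype: dict[str, tuple[np.ndarray, np.ndarray]]
    weight_vs_trait: tuple[np.ndarray, np.ndarray] | None
    runs_test_p: float | None


def _qq(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    values = np.sort(np.asarray(values, dtype=float))
    n = values.size
    if n == 0:
        return np.array([]), np.array([])
    theo = stats.norm.ppf((np.arange(1, n + 1) - 0.5) / n)
    return theo, values


def variance_fractions(
    controls: TraitDataset, use_sex: bool = True, use_weight: bool = True,
) -> VarianceFractions:
    """Decompose control trait variance into sex, weight, batch and residual.

    Expects a wildtype-only dataset (knockout records are ignored with a
    warning).  A single-batch dataset gets frac_batch = 0 with a warning.
    """
    warnings: list[str] = []
    wt = controls.restrict(genotype=WILDTYPE)
    if len(wt) < len(controls):
        warnings.append(f"ignored {len(controls) - len(wt)} knockout records")
    ds = TraitDataset(controls.trait_name, controls.line_id, wt) \
        if len(wt) < len(controls) else controls
    df = ds.to_frame()
    y = df["y"].to_numpy(float)
    n = y.size
    if n < 3:
        raise InsufficientDataError("variance decomposition needs >= 3 controls")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValidationError("trait is constant; variance fractions undefined")

    def _rss(cols: list[np.ndarray]) -> float:
        X = np.column_stack([np.ones(n), *cols])
        resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
        return float(resid @ resid)

    cols: list[np.ndarray] = []
    rss_prev = ss_tot
    frac_sex = frac_weight = 0.0
    if use_sex:
        cols.append(df["sex"].to_numpy(float))
        rss = _rss(cols)
        frac_sex = (rss_prev - rss) / ss_tot
        rss_prev = rss
    if use_weight:
        w = df["weight"].to_numpy(float)
        if np.isnan(w).any():
            raise ValidationError("weight missing for some controls")
        cols.append(w)
        rss = _rss(cols)
        frac_weight = (rss_prev - rss) / ss_tot
        rss_prev = rss

    if ds.n_batches < 2:
        warnings.append("single batch: batch fraction set to 0")
        frac_batch = 0.0
    else:
        spec = ModelSpec(include_genotype=False, include_sex=use_sex,
                         include_interaction=False, include_weight=use_weight)
        fit = fit_model(ds, spec, "REML")
        frac_batch = fit.sigma_u_sq / (ss_tot / (n - 1))

    explained = frac_sex + frac_weight + frac_batch
    if explained > 1.0:  # sampling noise can overshoot; renormalise
        frac_sex, frac_weight, frac_batch = (
            f / explained for f in (frac_sex, frac_weight, frac_batch))
        explained = 1.0
        warnings.append("explained fractions exceeded 1; renormalised")
    return VarianceFractions(
        trait_name=ds.trait_name, frac_sex=frac_sex, frac_weight=frac_weight,
        frac_batch=frac_batch, frac_residual=1.0 - explained,
        n=n, n_batches=ds.n_batches, warnings=warnings,
    )


# ---------------------------------------------------------------------------
# runs test
# ---------------------------------------------------------------------------

def _runs_exact_pmf(n1: int, n2: int) -> dict[int, float]:
    total = comb(n1 + n2, n1)
    pmf: dict[int, float] = {}
    for k in range(1, n1 + 1):
        pmf[2 * k] = 2 * comb(n1 - 1, k - 1) * comb(n2 - 1, k - 1) / total
        odd = 0
        if k <= n2 - 1:
            odd += comb(n1 - 1, k - 1) * comb(n2 - 1, k)
        if k <= n1 - 1:
            odd += comb(n1 - 1, k) * comb(n2 - 1, k - 1)
        if odd:
            pmf[2 * k + 1] = odd / total
    return {r: p for r, p in pmf.items() if p > 0}


def runs_test_batch_means(batch_means) -> float:
    """Two-sided Wald–Wolfowitz runs test about the median of batch means.

    Tests whether a time-ordered sequence of batch means is serially random —
    the independence assumption behind treating batch as an iid random
    intercept.  Values equal to the median are dropped.  Exact runs
    distribution up to 30 retained values, normal approximation above.
    """
    x = np.asarray(list(batch_means), dtype=float)
    if x.size < 10:
        raise InsufficientDataError("runs test needs >= 10 batch means")
    if np.all(x == x[0]):
        raise ValidationError("all batch means identical; runs test undefined")
    med = np.median(x)
    signs = np.sign(x - med)
    signs = signs[signs != 0]
    n1 = int(np.sum(signs > 0))
    n2 = int(np.sum(signs < 0))
    if n1 == 0 or n2 == 0:
        raise ValidationError("batch means do not straddle their median")
    runs = 1 + int(np.sum(signs[1:] != signs[:-1]))
    n = n1 + n2
    if n <= RUNS_EXACT_CUTOFF:
        pmf = _runs_exact_pmf(n1, n2)
        lo = sum(p for r, p in pmf.items() if r <= runs)
        hi = sum(p for r, p in pmf.items() if r >= runs)
        return float(min(1.0, 2.0 * min(lo, hi)))
    mu = 1.0 + 2.0 * n1 * n2 / n
    var = 2.0 * n1 * n2 * (2.0 * n1 * n2 - n) / (n ** 2 * (n - 1))
    z = (runs - mu) / np.sqrt(var)
    return float(2.0 * stats.norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# per-fit diagnostics (pipeline steps 5–6)
# ---------------------------------------------------------------------------

def model_diagnostics(fit: FitResult, data: TraitDataset) -> DiagnosticBundle:
    """Assemble the Q-Q and scatter series for one fitted model.

    Batch means are ordered temporally when batch labels parse as ISO dates
    (first-appearance order otherwise) and fed to the runs test when at
    least 10 batches are present.
    """
    df = data.to_frame()
    y = df["y"].to_numpy(float)
    order = batch_temporal_order(df["batch"])
    means = np.array([y[(df["batch"] == b).to_numpy()].mean() for b in order])
    runs_p = None
    if means.size >= 10 and not np.all(means == means[0]):
        runs_p = runs_test_batch_means(means)

    geno_lab = np.where(df["genotype"].to_numpy(int) == 1, "knockout", "wildtype")
    qq_res = {}
    rvf = {}
    for g in ("wildtype", "knockout"):
        m = geno_lab == g
        qq_res[g] = _qq(fit.residuals[m])
        rvf[g] = (fit.fitted[m], fit.residuals[m])

    weight_vs_trait = None
    if fit.spec.include_weight:
        weight_vs_trait = (df["weight"].to_numpy(float), y)

    return DiagnosticBundle(
        qq_batch_means=_qq(means),
        qq_blups=_qq(np.array(list(fit.blups.values())))
        if fit.blups else (np.array([]), np.array([])),
        qq_residuals_per_genotype=qq_res,
        residual_vs_fitted_per_genotype=rvf,
        weight_vs_trait=weight_vs_trait,
        runs_test_p=runs_p,
    )
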