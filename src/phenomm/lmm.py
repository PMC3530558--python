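"""Gaussian linear mixed model with a batch random intercept.

The model for animal *i* in batch *j* is

    Y_ij = b0 + b1*genotype + b2*sex + b3*weight + b4*genotype*sex + u_j + e_ij

with u_j ~ N(0, sigma_u^2) iid across batches and e_ij ~ N(0, sigma_e^2),
where the residual variance is either shared (homogeneous) or separate per
genotype group (genotype-stratified, the nlme ``varIdent`` analogue).  Any
subset of the fixed terms can be present, subject to the model hierarchy
(the interaction requires both main effects).

Fitting maximises ML or REML by profiling out the residual scale and the
fixed effects analytically, leaving at most two free parameters: the
variance ratio gamma = sigma_u^2 / sigma_e^2(wildtype) >= 0 and the log
residual-variance ratio d = log(sigma_e^2(knockout)/sigma_e^2(wildtype)).
Because the random structure is a single intercept per batch, the marginal
covariance is block-diagonal and every likelihood evaluation reduces, via
the Woodbury identity, to per-batch and per-genotype sufficient statistics
— no per-observation work inside the optimiser.  Fits are deterministic.

The boundary gamma = 0 (no batch variance) is a valid estimate, reported as
exactly 0, never an error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Literal

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .data import TraitDataset, WILDTYPE, KNOCKOUT
from .errors import FittingError, InsufficientDataError, ValidationError

HOMOGENEOUS = "homogeneous"
STRATIFIED = "genotype_stratified"

_LOG2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class ModelSpec:
    """Structural description of one candidate mixed model."""

    include_genotype: bool = True
    include_sex: bool = True
    include_interaction: bool = True
    include_weight: bool = False
    random_intercept_batch: bool = True
    residual_structure: str = HOMOGENEOUS

    def __post_init__(self):
        if self.include_interaction and not (self.include_genotype and self.include_sex):
            raise ValidationError(
                "genotype:sex interaction requires both genotype and sex main effects"
            )
        if self.residual_structure not in (HOMOGENEOUS, STRATIFIED):
            raise ValidationError(
                f"unknown residual structure {self.residual_structure!r}"
            )

    def drop(self, term: str) -> "ModelSpec":
        """Return the spec without ``term`` (one of genotype/sex/weight/interaction)."""
        return replace(self, **{f"include_{term}": False})

    @property
    def fixed_terms(self) -> list[str]:
        terms = []
        if self.include_genotype:
            terms.append("genotype")
        if self.include_sex:
            terms.append("sex")
        if self.include_weight:
            terms.append("weight")
        if self.include_interaction:
            terms.append("genotype:sex")
        return terms

    def formula(self) -> str:
        rhs = " + ".join(["1", *self.fixed_terms])
        if self.random_intercept_batch:
            rhs += " + (1|batch)"
        if self.residual_structure == STRATIFIED:
            rhs += ", varIdent(genotype)"
        return f"y ~ {rhs}"


def full_spec(equation: str) -> ModelSpec:
    """The fully loaded starting model for eq1 (no weight) or eq2 (with weight)."""
    if equation not in ("eq1", "eq2"):
        raise ValidationError(f"equation must be 'eq1' or 'eq2', got {equation!r}")
    return ModelSpec(include_weight=(equation == "eq2"))


@dataclass
class FitResult:
    """Estimates from one mixed-model fit.

    ``params``/``se`` only contain the terms present in the spec — absent
    terms have no estimate rather than a zero.  ``sigma_e_sq`` is a float for
    homogeneous residuals and a ``{genotype: variance}`` dict when stratified.
    ``blups`` maps batch label to the predicted random intercept (empty when
    the model has none).  Fitted values include the BLUP contribution, so
    ``residuals`` are conditional residuals.
    """

    spec: ModelSpec
    objective: str
    n: int
    params: dict[str, float]
    se: dict[str, float]
    sigma_u_sq: float | None
    sigma_e_sq: float | dict[str, float]
    blups: dict[str, float]
    loglik: float
    fitted: np.ndarray
    residuals: np.ndarray
    weight_center: float | None = None
    converged: bool = True
    n_iter: int = 0

    @property
    def intercept_uncentered(self) -> float:
        """Intercept on the raw-weight parameterisation (weight = 0 g)."""
        if self.weight_center is None or "weight" not in self.params:
            return self.params["intercept"]
        return self.params["intercept"] - self.params["weight"] * self.weight_center

    def genotype_effect(self, sex: str | None = None) -> float:
        """Genotype effect in trait units; per sex when the interaction is present."""
        b1 = self.params["genotype"]
        b4 = self.params.get("genotype:sex", 0.0)
        if sex == "female":
            return b1
        if sex == "male":
            return b1 + b4
        return b1 + 0.5 * b4  # sex-averaged


# ---------------------------------------------------------------------------
# design matrix and sufficient statistics
# ---------------------------------------------------------------------------

def design_matrix(df: pd.DataFrame, spec: ModelSpec):
    """Build (X, names, weight_center) from a TraitDataset.to_frame() frame.

    Weight is centred at the control (wildtype) mean so the intercept is
    interpretable at a realistic body weight; this is a pure
    reparameterisation and leaves all tests invariant.
    """
    names = ["intercept"]
    cols = [np.ones(len(df))]
    wc = None
    if spec.include_genotype:
        names.append("genotype")
        cols.append(df["genotype"].to_numpy(float))
    if spec.include_sex:
        names.append("sex")
        cols.append(df["sex"].to_numpy(float))
    if spec.include_weight:
        w = df["weight"].to_numpy(float)
        if np.isnan(w).any():
            raise ValidationError(
                "weight requested in the model but missing for some records; "
                "exclude them before fitting"
            )
        ctrl = df["genotype"].to_numpy(float) == 0
        wc = float(w[ctrl].mean())
        names.append("weight")
        cols.append(w - wc)
    if spec.include_interaction:
        names.append("genotype:sex")
        cols.append(df["genotype"].to_numpy(float) * df["sex"].to_numpy(float))
    return np.column_stack(cols), names, wc


class _Suffstats:
    """Per-genotype and per-(batch, genotype) sufficient statistics."""

    def __init__(self, X: np.ndarray, y: np.ndarray, batch_idx: np.ndarray,
                 geno: np.ndarray, n_batches: int):
        self.n, self.p = X.shape
        self.B = n_batches
        self.XtX = []   # per genotype group, p x p
        self.Xty = []
        self.yty = []
        self.SX = []    # per genotype group, B x p batch sums
        self.Sy = []
        self.cnt = []   # per genotype group, B counts
        for t in (0, 1):
            m = geno == t
            Xt, yt, bt = X[m], y[m], batch_idx[m]
            self.XtX.append(Xt.T @ Xt)
            self.Xty.append(Xt.T @ yt)
            self.yty.append(float(yt @ yt))
            SX = np.zeros((n_batches, self.p))
            np.add.at(SX, bt, Xt)
            Sy = np.zeros(n_batches)
            np.add.at(Sy, bt, yt)
            self.SX.append(SX)
            self.Sy.append(Sy)
            self.cnt.append(np.bincount(bt, minlength=n_batches).astype(float))
        self.n_ko = int(self.cnt[1].sum())


def _profiled(ss: _Suffstats, gamma: float, d: float, reml: bool):
    """Profiled negative log-likelihood pieces at (gamma, d).

    Returns (loglik, beta, A, s, logdetW) where A = X' W^-1 X on the
    unit-scale covariance W, and s is the profiled wildtype residual variance.
    """
    w1 = math.exp(-d)  # inverse relative variance of the knockout group
    XtDX = ss.XtX[0] + w1 * ss.XtX[1]
    XtDy = ss.Xty[0] + w1 * ss.Xty[1]
    yDy = ss.yty[0] + w1 * ss.yty[1]
    a = ss.cnt[0] + w1 * ss.cnt[1]
    logdetW = ss.n_ko * d
    if gamma > 0.0:
        c = gamma / (1.0 + gamma * a)
        SXw = ss.SX[0] + w1 * ss.SX[1]
        Syw = ss.Sy[0] + w1 * ss.Sy[1]
        A = XtDX - (SXw * c[:, None]).T @ SXw
        bvec = XtDy - SXw.T @ (c * Syw)
        yWy = yDy - float(c @ (Syw ** 2))
        logdetW += float(np.sum(np.log1p(gamma * a)))
    else:
        A, bvec, yWy = XtDX, XtDy, yDy
    try:
        beta = np.linalg.solve(A, bvec)
    except np.linalg.LinAlgError:
        raise FittingError("singular design matrix") from None
    rss = max(yWy - float(beta @ bvec), 0.0)
    n, p = ss.n, ss.p
    dof = n - p if reml else n
    s = rss / dof if dof > 0 else 0.0
    if s <= 0.0:
        # perfect fit: likelihood unbounded; report a large finite value
        return 1e12, beta, A, 0.0, logdetW
    ll = -0.5 * (dof * (math.log(s) + _LOG2PI) + logdetW + dof)
    if reml:
        sign, logdetA = np.linalg.slogdet(A)
        if sign <= 0:
            raise FittingError("non-positive-definite X'V^-1X")
        ll -= 0.5 * logdetA
    return ll, beta, A, s, logdetW


def _moment_starts(ss, X, y, bidx, geno, n_batches):
    """Rough (gamma, d) starting values from OLS residual moments."""
    try:
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
    except np.linalg.LinAlgError:
        return 0.5, 0.0
    r = y - X @ beta
    s2 = float(r @ r) / max(len(r) - X.shape[1], 1)
    if s2 <= 0:
        return 0.5, 0.0
    d0 = 0.0
    r_ko, r_wt = r[geno == 1], r[geno == 0]
    if r_ko.size > 2 and r_wt.size > 2:
        v_ko, v_wt = float(np.var(r_ko)), float(np.var(r_wt))
        if v_ko > 0 and v_wt > 0:
            d0 = float(np.clip(math.log(v_ko / v_wt), -5.0, 5.0))
    cnt = np.bincount(bidx, minlength=n_batches).astype(float)
    sums = np.bincount(bidx, weights=r, minlength=n_batches)
    keep = cnt > 0
    bmeans = sums[keep] / cnt[keep]
    if bmeans.size > 1:
        v_between = float(np.var(bmeans, ddof=1))
        g0 = (v_between - s2 / float(cnt[keep].mean())) / s2
    else:
        g0 = 0.0
    return float(np.clip(g0, 1e-3, 1e4)), d0


def _prepare(data: TraitDataset, spec: ModelSpec):
    """Validate preconditions and build the design and sufficient statistics."""
    df = data.to_frame()
    X, names, wc = design_matrix(df, spec)
    y = df["y"].to_numpy(float)
    geno = df["genotype"].to_numpy(int)
    batches = data.batches
    if spec.random_intercept_batch and len(batches) < 2:
        raise InsufficientDataError(
            f"random batch intercept requires >= 2 batches, got {len(batches)}"
        )
    if spec.include_genotype or spec.residual_structure == STRATIFIED:
        data.ensure_both_genotypes()
    if spec.include_weight and spec.include_genotype:
        for t, lab in ((0, WILDTYPE), (1, KNOCKOUT)):
            if not np.any(geno == t):
                raise InsufficientDataError(f"no {lab} records with weight")
    bindex = {b: i for i, b in enumerate(batches)}
    bidx = np.array([bindex[b] for b in df["batch"]], dtype=int)
    ss = _Suffstats(X, y, bidx, geno, len(batches))
    if ss.n <= ss.p:
        raise InsufficientDataError(
            f"{ss.n} observations cannot identify {ss.p} fixed effects"
        )
    return df, X, names, wc, y, geno, batches, bindex, bidx, ss


def fit_model(
    data: TraitDataset,
    spec: ModelSpec,
    objective: Literal["ML", "REML"] = "REML",
) -> FitResult:
    """Fit the mixed model described by ``spec`` to ``data``.

    Raises :class:`InsufficientDataError` when the random intercept is
    requested with fewer than two batches, and :class:`FittingError` on
    optimizer failure.  A batch variance estimated at the boundary is
    reported as exactly 0, not an error.
    """
    if objective not in ("ML", "REML"):
        raise ValidationError(f"objective must be 'ML' or 'REML', got {objective!r}")
    reml = objective == "REML"
    df, X, names, wc, y, geno, batches, bindex, bidx, ss = _prepare(data, spec)

    free_gamma = spec.random_intercept_batch
    free_d = spec.residual_structure == STRATIFIED
    n_iter = 0

    if not free_gamma and not free_d:
        ll, beta, A, s, _ = _profiled(ss, 0.0, 0.0, reml)
    else:
        def nll(x):
            g = x[0] if free_gamma else 0.0
            dd = x[1] if free_gamma and free_d else (x[0] if free_d and not free_gamma else 0.0)
            return -_profiled(ss, g, dd, reml)[0]

        # moment-based starting values plus a fixed fallback for robustness
        g0, d0 = _moment_starts(ss, X, y, bidx, geno, len(batches))
        if free_gamma and free_d:
            starts = [(g0, d0), (0.5, 0.0), (max(10 * g0, 2.0), d0)]
            bounds = [(0.0, 1e8), (-20.0, 20.0)]
        elif free_gamma:
            starts = [(g0,), (0.5,), (max(10 * g0, 2.0),)]
            bounds = [(0.0, 1e8)]
        else:
            starts = [(d0,), (0.0,)]
            bounds = [(-20.0, 20.0)]
        starts = list(dict.fromkeys(starts))
        best = None
        for x0 in starts:
            res = optimize.minimize(
                nll, np.array(x0), method="L-BFGS-B", bounds=bounds,
                options={"ftol": 1e-12, "gtol": 1e-9, "maxiter": 200},
            )
            n_iter += int(res.nit)
            if best is None or res.fun < best.fun - 1e-10:
                best = res
        if best is None or not np.isfinite(best.fun):
            raise FittingError(
                "mixed-model optimisation failed to converge",
                diagnostics={"message": getattr(best, "message", "no result")},
            )
        if free_gamma:
            gamma = float(best.x[0])
            d = float(best.x[1]) if free_d else 0.0
            # snap to the boundary when the optimum is indistinguishable from 0
            if gamma < 1e-7:
                at0 = -nll(np.array([0.0, d][: len(best.x)]))
                if at0 >= -best.fun - 1e-9:
                    gamma = 0.0
        else:
            gamma, d = 0.0, float(best.x[0])
        ll, beta, A, s, _ = _profiled(ss, gamma, d, reml)

    if not (free_gamma or free_d):
        gamma, d = 0.0, 0.0

    # assemble estimates on the original scale
    sigma_e_wt = s
    cov_beta = s * np.linalg.inv(A)
    se = dict(zip(names, np.sqrt(np.maximum(np.diag(cov_beta), 0.0))))
    params = dict(zip(names, beta))
    sigma_u_sq = gamma * sigma_e_wt if spec.random_intercept_batch else None
    if spec.residual_structure == STRATIFIED:
        sigma_e_sq: float | dict[str, float] = {
            WILDTYPE: sigma_e_wt, KNOCKOUT: sigma_e_wt * math.exp(d)
        }
    else:
        sigma_e_sq = sigma_e_wt

    # BLUPs and conditional residuals
    xb = X @ beta
    blups: dict[str, float] = {}
    fitted = xb.copy()
    if spec.random_intercept_batch and gamma > 0.0:
        w1 = math.exp(-d)
        r = y - xb
        t = np.zeros(len(batches))
        wobs = np.where(geno == 1, w1, 1.0)
        np.add.at(t, bidx, wobs * r)
        a = ss.cnt[0] + w1 * ss.cnt[1]
        u = gamma * t / (1.0 + gamma * a)
        blups = {b: float(u[i]) for b, i in bindex.items()}
        fitted = xb + u[bidx]
    elif spec.random_intercept_batch:
        blups = {b: 0.0 for b in batches}

    return FitResult(
        spec=spec, objective=objective, n=ss.n, params=params, se=se,
        sigma_u_sq=sigma_u_sq, sigma_e_sq=sigma_e_sq, blups=blups,
        loglik=float(ll), fitted=fitted, residuals=y - fitted,
        weight_center=wc, converged=True, n_iter=n_iter,
    )


# ---------------------------------------------------------------------------
# Wald tests with Satterthwaite denominator degrees of freedom
# ---------------------------------------------------------------------------

def _loglik_at(ss: _Suffstats, su2: float, se2_wt: float, se2_ko: float,
               reml: bool, with_ri: bool):
    """Log-likelihood and X'V^-1 X at explicit variance-component values.

    Unlike :func:`_profiled` nothing is profiled out except the fixed
    effects; used for derivative-based degrees-of-freedom approximations.
    """
    w0, w1 = 1.0 / se2_wt, 1.0 / se2_ko
    XtDX = w0 * ss.XtX[0] + w1 * ss.XtX[1]
    XtDy = w0 * ss.Xty[0] + w1 * ss.Xty[1]
    yDy = w0 * ss.yty[0] + w1 * ss.yty[1]
    a = w0 * ss.cnt[0] + w1 * ss.cnt[1]
    n_wt = ss.n - ss.n_ko
    logdetV = n_wt * math.log(se2_wt) + ss.n_ko * math.log(se2_ko)
    if with_ri and su2 > 0.0:
        c = su2 / (1.0 + su2 * a)
        SXw = w0 * ss.SX[0] + w1 * ss.SX[1]
        Syw = w0 * ss.Sy[0] + w1 * ss.Sy[1]
        A = XtDX - (SXw * c[:, None]).T @ SXw
        bvec = XtDy - SXw.T @ (c * Syw)
        yWy = yDy - float(c @ (Syw ** 2))
        logdetV += float(np.sum(np.log1p(su2 * a)))
    else:
        A, bvec, yWy = XtDX, XtDy, yDy
    beta = np.linalg.solve(A, bvec)
    rss = max(yWy - float(beta @ bvec), 0.0)
    n, p = ss.n, ss.p
    if reml:
        sign, logdetA = np.linalg.slogdet(A)
        ll = -0.5 * ((n - p) * _LOG2PI + logdetV + logdetA + rss)
    else:
        ll = -0.5 * (n * _LOG2PI + logdetV + rss)
    return ll, beta, A


def _phi_from_fit(fit: FitResult):
    """Variance-component vector (those > 0 free) and an expander to
    (su2, se2_wt, se2_ko)."""
    strat = fit.spec.residual_structure == STRATIFIED
    se_wt = fit.sigma_e_sq[WILDTYPE] if strat else fit.sigma_e_sq
    se_ko = fit.sigma_e_sq[KNOCKOUT] if strat else fit.sigma_e_sq
    with_ri = fit.spec.random_intercept_batch and (fit.sigma_u_sq or 0.0) > 0.0
    phi = []
    if with_ri:
        phi.append(fit.sigma_u_sq)
    phi.append(se_wt)
    if strat:
        phi.append(se_ko)

    def expand(v):
        i = 0
        su2 = 0.0
        if with_ri:
            su2 = v[i]
            i += 1
        wt = v[i]
        ko = v[i + 1] if strat else wt
        return su2, wt, ko

    return np.array(phi, dtype=float), expand, with_ri


def satterthwaite_genotype_test(data: TraitDataset, spec: ModelSpec):
    """REML Wald test of the genotype terms with Satterthwaite denominator df.

    With a batch random intercept and mutants concentrated in a handful of
    batches, the genotype contrast is effectively identified by those few
    batches; chi-square-referenced tests then reject far too often.  The
    Satterthwaite approximation estimates the denominator degrees of freedom
    of each contrast from the curvature of the REML likelihood in the
    variance components (the correction popularised by lmerTest and SAS
    PROC MIXED).  Returns ``(stat, df_num, df_den, p, fit)`` where ``stat``
    is t (single contrast) or F (joint genotype + interaction).
    """
    fit = fit_model(data, spec, "REML")
    _, X, names, wc, y, geno, batches, bindex, bidx, ss = _prepare(data, spec)
    phi, expand, with_ri = _phi_from_fit(fit)

    def ll_of(v):
        return _loglik_at(ss, *expand(v), reml=True, with_ri=with_ri)[0]

    def cov_beta_of(v):
        _, _, A = _loglik_at(ss, *expand(v), reml=True, with_ri=with_ri)
        return np.linalg.inv(A)

    h = 1e-4 * np.maximum(phi, 1e-8)
    k = phi.size
    # observed REML information in the variance components
    H = np.zeros((k, k))
    f0 = ll_of(phi)
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = h[i]
            ej = np.zeros(k); ej[j] = h[j]
            if i == j:
                H[i, i] = (ll_of(phi + ei) - 2 * f0 + ll_of(phi - ei)) / h[i] ** 2
            else:
                H[i, j] = H[j, i] = (
                    ll_of(phi + ei + ej) - ll_of(phi + ei - ej)
                    - ll_of(phi - ei + ej) + ll_of(phi - ei - ej)
                ) / (4 * h[i] * h[j])
    try:
        W = np.linalg.inv(-H)
    except np.linalg.LinAlgError:
        W = None

    beta = np.array([fit.params[t] for t in names])
    terms = ["genotype"] + (["genotype:sex"] if spec.include_interaction else [])
    L = np.zeros((len(terms), len(names)))
    for r, t in enumerate(terms):
        L[r, names.index(t)] = 1.0

    Vb0 = cov_beta_of(phi)

    def sat_df(contrast):
        f_val = float(contrast @ Vb0 @ contrast)
        if W is None:
            return np.inf
        grad = np.zeros(k)
        for i in range(k):
            ei = np.zeros(k); ei[i] = h[i]
            up = float(contrast @ cov_beta_of(phi + ei) @ contrast)
            dn = float(contrast @ cov_beta_of(phi - ei) @ contrast)
            grad[i] = (up - dn) / (2 * h[i])
        denom = float(grad @ W @ grad)
        if denom <= 0:
            return np.inf
        return 2.0 * f_val ** 2 / denom

    if len(terms) == 1:
        c = L[0]
        se = math.sqrt(float(c @ Vb0 @ c))
        t_stat = float(c @ beta) / se
        df_den = sat_df(c)
        p = float(2.0 * stats.t.sf(abs(t_stat), df_den)) if np.isfinite(df_den) \
            else float(2.0 * stats.norm.sf(abs(t_stat)))
        return t_stat, 1, df_den, p, fit

    # joint F over {genotype, genotype:sex}: eigen-decompose the contrast
    # covariance and pool per-eigencontrast Satterthwaite dfs (lmerTest method)
    q = len(terms)
    M = L @ Vb0 @ L.T
    Minv = np.linalg.inv(M)
    F = float(beta @ L.T @ Minv @ L @ beta) / q
    evals, evecs = np.linalg.eigh(M)
    dfs = []
    for r in range(q):
        contrast = (evecs[:, r] @ L)
        dfr = sat_df(contrast)
        if np.isfinite(dfr) and dfr > 2.0:
            dfs.append(dfr)
    if dfs:
        E = sum(d / (d - 2.0) for d in dfs)
        df_den = 2.0 * E / (E - q) if E > q else np.inf
    else:
        df_den = np.inf
    p = float(stats.f.sf(F, q, df_den)) if np.isfinite(df_den) \
        else float(stats.chi2.sf(q * F, q))
    return F, q, df_den, p, fit


# ---------------------------------------------------------------------------
# likelihood-ratio machinery
# ---------------------------------------------------------------------------

def lrt_pvalue(ll_full: float, ll_reduced: float, df: int,
               boundary: bool = False) -> tuple[float, float]:
    """LRT statistic and p-value for nested models.

    ``boundary=True`` applies the 50:50 mixture of a point mass at zero and
    chi-square(1) appropriate for testing a variance component against its
    boundary (sigma_u^2 = 0); a plain chi-square would be conservative there.
    """
    stat = max(2.0 * (ll_full - ll_reduced), 0.0)
    if boundary:
        if df != 1:
            raise ValidationError("boundary correction implemented for df=1 only")
        p = 0.5 * stats.chi2.sf(stat, 1) if stat > 0 else 1.0
    else:
        p = float(stats.chi2.sf(stat, df))
    return stat, float(p)
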