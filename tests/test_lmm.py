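"""Mixed-model fitting: closed-form oracles, statsmodels cross-checks, invariants."""

import warnings

import numpy as np
import pytest

from phenomm.data import PhenotypeRecord, build_trait_dataset
from phenomm.errors import InsufficientDataError, ValidationError
from phenomm.lmm import (STRATIFIED, ModelSpec, fit_model, full_spec,
                         lrt_pvalue)
from phenomm.simulate import SimConfig, generate_dataset, scenario


def _two_group_single_batch(rng, n=12, shift=1.0):
    recs = []
    for i in range(n):
        ko = i >= n // 2
        recs.append(PhenotypeRecord(
            f"a{i}", "knockout" if ko else "wildtype", "female", "b0", 25.0,
            {"t": float(shift * ko + rng.normal())}))
    return build_trait_dataset(recs, "t", "L")


class TestClosedFormOracles:
    def test_single_batch_two_group_equals_group_means(self, rng):
        """OLS oracle: genotype-only fit reproduces group means exactly."""
        ds = _two_group_single_batch(rng)
        spec = ModelSpec(include_sex=False, include_interaction=False,
                         random_intercept_batch=False)
        fit = fit_model(ds, spec, "ML")
        wt = ds.values(genotype="wildtype").mean()
        ko = ds.values(genotype="knockout").mean()
        assert fit.params["intercept"] == pytest.approx(wt, abs=1e-12)
        assert fit.params["genotype"] == pytest.approx(ko - wt, abs=1e-12)

    def test_constant_data_boundary_handled(self):
        recs = [PhenotypeRecord(f"a{i}", "knockout" if i % 2 else "wildtype",
                                "female", "b0", 25.0, {"t": 5.0})
                for i in range(8)]
        ds = build_trait_dataset(recs, "t", "L")
        spec = ModelSpec(include_genotype=False, include_sex=False,
                         include_interaction=False,
                         random_intercept_batch=False)
        fit = fit_model(ds, spec, "ML")
        assert fit.params["intercept"] == pytest.approx(5.0)
        assert fit.sigma_e_sq == pytest.approx(0.0, abs=1e-12)

    def test_ml_loglik_equals_ols_llf(self, direct_effect_ds):
        """Without the random intercept, ML is ordinary least squares."""
        import statsmodels.api as sm
        spec = ModelSpec(include_interaction=False,
                         random_intercept_batch=False)
        fit = fit_model(direct_effect_ds, spec, "ML")
        df = direct_effect_ds.to_frame()
        X = sm.add_constant(df[["genotype", "sex"]])
        ols = sm.OLS(df["y"], X).fit()
        assert fit.loglik == pytest.approx(ols.llf, abs=1e-8)
        assert fit.params["genotype"] == pytest.approx(
            ols.params["genotype"], abs=1e-10)


class TestStatsmodelsCrossCheck:
    @pytest.mark.parametrize("seed", [3, 7, 11])
    def test_reml_matches_mixedlm(self, seed):
        """Independent mixed-model implementation agrees on the homogeneous model."""
        import statsmodels.formula.api as smf
        recs = generate_dataset(scenario("direct_effect", seed=seed))
        ds = build_trait_dataset(recs, "fat_mass", "L")
        fit = fit_model(ds, ModelSpec(include_interaction=False), "REML")
        df = ds.to_frame()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = smf.mixedlm("y ~ genotype + sex", df,
                            groups=df["batch"]).fit(reml=True)
        assert fit.params["genotype"] == pytest.approx(
            float(m.fe_params["genotype"]), abs=1e-5)
        assert fit.sigma_u_sq == pytest.approx(float(m.cov_re.iloc[0, 0]),
                                               abs=1e-3)
        assert fit.sigma_e_sq == pytest.approx(float(m.scale), rel=1e-4)
        assert fit.loglik == pytest.approx(float(m.llf), abs=1e-6)
        assert fit.se["genotype"] == pytest.approx(
            float(m.bse_fe["genotype"]), rel=1e-3)


class TestParameterRecovery:
    def test_estimates_tighten_with_study_size(self):
        """Consistency: RMSE of beta1 and sigma_u^2 shrinks as batches grow."""
        import dataclasses
        rmse = {}
        for nb, bs in ((8, 3), (30, 10)):
            b1, su2 = [], []
            for seed in range(60):
                cfg = dataclasses.replace(scenario("direct_effect", seed=seed),
                                          n_batches_control=nb,
                                          batch_size_control=bs)
                ds = build_trait_dataset(generate_dataset(cfg), "fat_mass", "L")
                fit = fit_model(ds, ModelSpec(include_interaction=False), "REML")
                b1.append(fit.params["genotype"])
                su2.append(fit.sigma_u_sq)
            rmse[(nb, bs)] = (np.sqrt(np.mean((np.array(b1) - 1.5) ** 2)),
                              np.sqrt(np.mean((np.array(su2) - 1.0) ** 2)))
        small, large = rmse[(8, 3)], rmse[(30, 10)]
        assert large[0] < small[0]
        assert large[1] < small[1]

    def test_beta1_recovered_over_replicates(self):
        """Mean genotype estimate over 60 fits near the generating 1.5."""
        est = []
        for seed in range(60):
            cfg = scenario("direct_effect", seed=seed)
            recs = generate_dataset(cfg)
            ds = build_trait_dataset(recs, "fat_mass", "L")
            fit = fit_model(ds, ModelSpec(include_interaction=False), "REML")
            est.append(fit.params["genotype"])
        mean, se = np.mean(est), np.std(est, ddof=1) / np.sqrt(len(est))
        assert abs(mean - 1.5) < 3 * se


class TestInvariants:
    def test_absent_terms_have_no_estimate(self, direct_effect_ds):
        spec = ModelSpec(include_sex=False, include_interaction=False)
        fit = fit_model(direct_effect_ds, spec, "REML")
        assert "sex" not in fit.params and "weight" not in fit.params
        assert "genotype:sex" not in fit.se

    def test_blup_count_and_balanced_sum(self):
        cfg = SimConfig(seed=9, sigma_u=1.0, sigma_e=1.0, beta3=0.0,
                        mutant_batches_shared_with_controls=True,
                        n_mutant_batches=20, n_mutants_per_sex=10)
        ds = build_trait_dataset(generate_dataset(cfg), "fat_mass", "L")
        fit = fit_model(ds, ModelSpec(include_interaction=False), "REML")
        assert len(fit.blups) == ds.n_batches
        # BLUPs shrink residual batch means toward zero; overall they centre
        assert abs(sum(fit.blups.values())) < 1e-6 * ds.n_batches or \
            abs(sum(fit.blups.values())) < 0.5

    def test_variances_nonnegative(self, null_ds):
        fit = fit_model(null_ds, full_spec("eq1"), "REML")
        assert fit.sigma_u_sq >= 0.0
        se2 = fit.sigma_e_sq
        assert (se2 > 0 if isinstance(se2, float)
                else all(v > 0 for v in se2.values()))

    def test_affine_equivariance(self, direct_effect_ds):
        """Fitting a*Y + b scales the genotype effect by a, p-value unchanged."""
        spec = ModelSpec(include_interaction=False)
        base_full = fit_model(direct_effect_ds, spec, "ML")
        base_null = fit_model(direct_effect_ds, spec.drop("genotype"), "ML")
        _, p0 = lrt_pvalue(base_full.loglik, base_null.loglik, 1)
        a, b = -2.5, 7.0
        recs = [
            PhenotypeRecord(r.animal_id, r.genotype, r.sex, r.batch, r.weight,
                            {"t": a * direct_effect_ds.trait_value(r) + b})
            for r in direct_effect_ds.records
        ]
        ds2 = build_trait_dataset(recs, "t", "L")
        f2 = fit_model(ds2, spec, "ML")
        n2 = fit_model(ds2, spec.drop("genotype"), "ML")
        _, p1 = lrt_pvalue(f2.loglik, n2.loglik, 1)
        assert f2.params["genotype"] == pytest.approx(
            a * base_full.params["genotype"], rel=1e-6)
        assert p1 == pytest.approx(p0, abs=1e-6)

    def test_stratified_residuals_recovered(self):
        """Per-genotype residual variances estimated near their 3x ratio."""
        cfg = SimConfig(seed=2, sigma_u=0.5, sigma_e=(1.0, 3.0), beta3=0.0,
                        n_mutants_per_sex=50, n_mutant_batches=10)
        ds = build_trait_dataset(generate_dataset(cfg), "fat_mass", "L")
        spec = ModelSpec(include_interaction=False,
                         residual_structure=STRATIFIED)
        fit = fit_model(ds, spec, "REML")
        ratio = fit.sigma_e_sq["knockout"] / fit.sigma_e_sq["wildtype"]
        assert 4.0 < ratio < 20.0  # true ratio 9


class TestPreconditions:
    def test_random_intercept_needs_two_batches(self, rng):
        ds = _two_group_single_batch(rng)
        with pytest.raises(InsufficientDataError):
            fit_model(ds, ModelSpec(include_sex=False,
                                    include_interaction=False))

    def test_interaction_requires_main_effects(self):
        with pytest.raises(ValidationError):
            ModelSpec(include_sex=False, include_interaction=True)

    def test_weight_model_rejects_missing_weight(self, rng):
        recs = [PhenotypeRecord(f"a{i}", "knockout" if i % 2 else "wildtype",
                                "female", f"b{i % 3}",
                                None if i == 0 else 25.0 + rng.normal(),
                                {"t": float(rng.normal())})
                for i in range(12)]
        ds = build_trait_dataset(recs, "t", "L")
        with pytest.raises(ValidationError):
            fit_model(ds, ModelSpec(include_interaction=False,
                                    include_weight=True))
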