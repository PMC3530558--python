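"""Variance decomposition, runs test, and per-fit diagnostic series."""

import numpy as np
import pytest
from scipy import stats

from phenomm.data import PhenotypeRecord, build_trait_dataset
from phenomm.diagnostics import (model_diagnostics, runs_test_batch_means,
                                 variance_fractions)
from phenomm.errors import InsufficientDataError, ValidationError
from phenomm.lmm import ModelSpec, fit_model
from phenomm.simulate import SimConfig, generate_dataset


def _controls_only(cfg):
    recs = [r for r in generate_dataset(cfg) if r.genotype == "wildtype"]
    return build_trait_dataset(recs, cfg.trait_name,
                               require_both_genotypes=False)


class TestVarianceFractions:
    def test_batch_half_of_total(self):
        """Y = mu + u + e with sigma_u = sigma_e: batch explains ~50%."""
        fracs = []
        for seed in range(30):
            cfg = SimConfig(seed=seed, sigma_u=1.0, sigma_e=1.0, beta2=0.0,
                            beta3=0.0, n_batches_control=30,
                            batch_size_control=10)
            ds = _controls_only(cfg)
            vf = variance_fractions(ds, use_sex=False, use_weight=False)
            fracs.append(vf.frac_batch)
        assert np.mean(fracs) == pytest.approx(0.5, abs=0.05)

    def test_single_batch_gives_zero_batch_fraction(self):
        cfg = SimConfig(seed=1, n_batches_control=1, batch_size_control=40)
        vf = variance_fractions(_controls_only(cfg), use_weight=False)
        assert vf.frac_batch == 0.0
        assert any("single batch" in w for w in vf.warnings)

    def test_pure_sex_signal(self):
        cfg = SimConfig(seed=2, sigma_u=0.0, sigma_e=1e-4, beta2=5.0,
                        beta3=0.0, n_batches_control=10, batch_size_control=10)
        vf = variance_fractions(_controls_only(cfg), use_weight=False)
        assert vf.frac_sex == pytest.approx(1.0, abs=0.01)
        assert vf.frac_batch == pytest.approx(0.0, abs=0.01)

    def test_fractions_sum_to_one_and_in_range(self):
        cfg = SimConfig(seed=3, n_batches_control=25, batch_size_control=6)
        vf = variance_fractions(_controls_only(cfg))
        parts = [vf.frac_sex, vf.frac_weight, vf.frac_batch, vf.frac_residual]
        assert all(0.0 <= f <= 1.0 for f in parts)
        assert sum(parts) == pytest.approx(1.0, abs=1e-6)

    def test_affine_invariance(self):
        cfg = SimConfig(seed=4, n_batches_control=20, batch_size_control=6)
        ds = _controls_only(cfg)
        v0 = variance_fractions(ds, use_weight=False)
        recs = [PhenotypeRecord(r.animal_id, r.genotype, r.sex, r.batch,
                                r.weight, {"t": 3.0 * r.traits[cfg.trait_name] - 11.0})
                for r in ds.records]
        ds2 = build_trait_dataset(recs, "t", require_both_genotypes=False)
        v1 = variance_fractions(ds2, use_weight=False)
        assert v1.frac_batch == pytest.approx(v0.frac_batch, abs=1e-6)
        assert v1.frac_sex == pytest.approx(v0.frac_sex, abs=1e-6)


class TestRunsTest:
    def test_alternating_sequence_rejects(self):
        p = runs_test_batch_means([1, 2] * 10)
        assert p < 0.001

    def test_two_blocks_reject(self):
        p = runs_test_batch_means([0.0] * 10 + [1.0] * 10)
        assert p < 0.001

    def test_exact_matches_enumeration_n12(self):
        """Exact two-sided p for 2 runs of 6+6 about the median."""
        from math import comb
        seq = [0.0] * 6 + [1.0] * 6
        # P(R = 2) = 2 / C(12,6); one-sided tail doubled
        expected = 2 * (2 / comb(12, 6))
        assert runs_test_batch_means(seq) == pytest.approx(expected)

    def test_calibrated_under_iid_null(self, rng):
        rej = 0
        n_rep = 300
        for _ in range(n_rep):
            rej += runs_test_batch_means(rng.normal(size=100)) < 0.05
        assert 0.03 <= rej / n_rep <= 0.07

    def test_needs_ten_values(self):
        with pytest.raises(InsufficientDataError):
            runs_test_batch_means([1.0, 2.0, 3.0])

    def test_constant_sequence_undefined(self):
        with pytest.raises(ValidationError):
            runs_test_batch_means([5.0] * 20)


class TestModelDiagnostics:
    def test_structure_follows_spec(self, direct_effect_ds):
        fit = fit_model(direct_effect_ds,
                        ModelSpec(include_interaction=False,
                                  random_intercept_batch=False), "REML")
        bundle = model_diagnostics(fit, direct_effect_ds)
        assert bundle.qq_blups[0].size == 0
        assert set(bundle.qq_residuals_per_genotype) == {"wildtype", "knockout"}
        assert bundle.weight_vs_trait is None

    def test_blup_series_length_matches_batches(self, direct_effect_ds):
        fit = fit_model(direct_effect_ds,
                        ModelSpec(include_interaction=False), "REML")
        bundle = model_diagnostics(fit, direct_effect_ds)
        assert bundle.qq_blups[1].size == direct_effect_ds.n_batches

    def test_perfect_fit_residuals_zero(self):
        recs = []
        for i in range(20):
            ko = i % 2 == 1
            recs.append(PhenotypeRecord(f"a{i}", "knockout" if ko else "wildtype",
                                        "female", f"b{i % 2}", 25.0,
                                        {"t": 2.0 + 1.0 * ko}))
        ds = build_trait_dataset(recs, "t", "L")
        fit = fit_model(ds, ModelSpec(include_sex=False,
                                      include_interaction=False,
                                      random_intercept_batch=False), "ML")
        bundle = model_diagnostics(fit, ds)
        for g in ("wildtype", "knockout"):
            assert np.allclose(bundle.qq_residuals_per_genotype[g][1], 0.0,
                               atol=1e-10)

    def test_qq_series_sorted_and_equal_length(self, direct_effect_ds):
        fit = fit_model(direct_effect_ds,
                        ModelSpec(include_interaction=False), "REML")
        bundle = model_diagnostics(fit, direct_effect_ds)
        theo, samp = bundle.qq_residuals_per_genotype["wildtype"]
        assert theo.size == samp.size
        assert np.all(np.diff(samp) >= 0)

    def test_gaussian_residuals_track_normal_quantiles(self):
        hits = 0
        n_rep = 50
        for seed in range(n_rep):
            cfg = SimConfig(seed=seed, n_batches_control=20,
                            batch_size_control=8)
            ds = build_trait_dataset(generate_dataset(cfg), cfg.trait_name, "L")
            fit = fit_model(ds, ModelSpec(include_interaction=False), "REML")
            theo, samp = model_diagnostics(fit, ds) \
                .qq_residuals_per_genotype["wildtype"]
            r2 = stats.pearsonr(theo, samp).statistic ** 2
            hits += r2 > 0.95
        assert hits / n_rep >= 0.9

    def test_conditional_residuals_near_zero_per_batch_when_shrunk(self):
        """With strong batch signal, BLUP-adjusted residuals centre per batch."""
        cfg = SimConfig(seed=7, sigma_u=3.0, sigma_e=0.3, beta3=0.0,
                        n_batches_control=15, batch_size_control=20)
        ds = build_trait_dataset(generate_dataset(cfg), cfg.trait_name, "L")
        fit = fit_model(ds, ModelSpec(include_interaction=False), "REML")
        df = ds.to_frame()
        for b in ds.batches[:5]:
            m = (df["batch"] == b).to_numpy()
            assert abs(fit.residuals[m].mean()) < 0.15
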