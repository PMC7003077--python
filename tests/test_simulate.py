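"""Synthetic-data generator: structure, calibration and determinism."""

import math

import numpy as np
import pandas as pd
import pytest

from ryegp import SimulationConfig, TraitModel, simulate_gbs_reads, simulate_population_set, simulate_trial
from ryegp.simulate import _ztp_lambda

from conftest import SODIUM


def _cfg(**kw):
    defaults = dict(
        n_populations=1,
        families_per_population=30,
        n_snps=60,
        n_qtl=20,
        seed=1,
        traits={"y": TraitModel(sigma2_g=1.0, sigma2_gs=0.1, sigma2_e=1.0)},
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestPopulationSet:
    def test_degenerate_single_parent(self):
        fo = simulate_population_set(_cfg(families_per_population=1, n_snps=10, n_qtl=5))
        assert fo.n_parents == 1
        assert set(np.unique(fo.genotypes)) <= {0, 1, 2}

    def test_study_scale_family_counts(self):
        counts = (102, 104, 117, 110, 84)
        fo = simulate_population_set(
            _cfg(n_populations=5, families_per_population=counts, n_snps=30)
        )
        assert fo.n_parents == sum(counts) == 517
        assert pd.Series(fo.populations).value_counts().sort_index().tolist() == sorted(
            counts, key=lambda c: counts.index(c)
        ) or pd.Series(fo.populations).nunique() == 5

    def test_realized_maf_within_binomial_error(self):
        # unrelated founders, no drift: realized frequency is Binomial(2n, p)
        cfg = _cfg(families_per_population=500, n_snps=3000, fst=0.0,
                   ancestral_pool_size=None, maf_range=(0.05, 0.5), seed=3)
        fo = simulate_population_set(cfg)
        p_hat = fo.genotypes.mean(axis=0) / 2.0
        maf_hat = np.minimum(p_hat, 1 - p_hat)
        # fold the drawn targets the same way and compare per SNP at 4 sigma
        rng = np.random.default_rng(np.random.SeedSequence(entropy=3, spawn_key=(0,)))
        target = rng.uniform(0.05, 0.5, 3000)
        flip = rng.random(3000) < 0.5
        p_target = np.where(flip, 1 - target, target)
        se = np.sqrt(p_target * (1 - p_target) / (2 * 500))
        frac_in = np.mean(np.abs(p_hat - p_target) <= 4 * se)
        assert frac_in > 0.99
        assert maf_hat.max() <= 0.5

    def test_population_drift_differentiates_frequencies(self):
        cfg = _cfg(n_populations=2, families_per_population=200, n_snps=500,
                   fst=0.1, ancestral_pool_size=None, seed=4)
        fo = simulate_population_set(cfg)
        pops = np.asarray(fo.populations)
        p1 = fo.genotypes[pops == "Pop1"].mean(0) / 2
        p2 = fo.genotypes[pops == "Pop2"].mean(0) / 2
        # drift variance ~ 2 fst p(1-p) far exceeds binomial sampling noise
        assert np.mean((p1 - p2) ** 2) > 4 * np.mean((p1 * (1 - p1) + p2 * (1 - p2)) / 400)

    def test_breeding_values_centered_per_population_with_target_variance(self):
        cfg = _cfg(n_populations=2, families_per_population=150, n_snps=300, seed=5)
        fo = simulate_population_set(cfg)
        bv = fo.breeding_values["y"]
        for pop in ("Pop1", "Pop2"):
            sub = bv[np.asarray(fo.populations) == pop]
            assert abs(sub.mean()) < 1e-10
        # maternal BV variance is scaled to exactly 2 sigma2_g
        assert np.isclose(bv.to_numpy().std() ** 2, 2.0, rtol=1e-10)

    @pytest.mark.parametrize(
        "kw,match",
        [
            (dict(maf_range=(0.0, 0.5)), "maf_range"),
            (dict(maf_range=(0.1, 0.6)), "maf_range"),
            (dict(missing_rate=1.0), "missing_rate"),
            (dict(families_per_population=0), "families_per_population"),
            (dict(effect_distribution="laplace"), "effect_distribution"),
            (dict(mean_depth=0.5), "mean_depth"),
            (dict(ancestral_pool_size=1), "ancestral_pool_size"),
        ],
    )
    def test_invalid_config_names_offending_field(self, kw, match):
        with pytest.raises(ValueError, match=match):
            _cfg(**kw)

    def test_deterministic_under_seed(self):
        a = simulate_population_set(_cfg(seed=9))
        b = simulate_population_set(_cfg(seed=9))
        np.testing.assert_array_equal(a.genotypes, b.genotypes)
        pd.testing.assert_frame_equal(a.breeding_values, b.breeding_values)


class TestGBSReads:
    def test_deep_sequencing_recovers_true_dosages(self):
        fo = simulate_population_set(_cfg(families_per_population=40, n_snps=200))
        reads = simulate_gbs_reads(fo, mean_depth=40.0, missing_rate=0.0, seed=2)
        np.testing.assert_array_equal(reads.naive_calls(), fo.genotypes.astype(float))

    def test_depth_one_heterozygotes_always_called_homozygous(self):
        # mean_depth = 1 forces every covered cell to exactly one read
        fo = simulate_population_set(_cfg(families_per_population=60, n_snps=200))
        reads = simulate_gbs_reads(fo, mean_depth=1.0, missing_rate=0.0, seed=2)
        assert (reads.depth == 1).all()
        het = fo.genotypes == 1
        calls = reads.naive_calls()
        assert np.isin(calls[het], [0.0, 2.0]).all()

    def test_het_undercall_rate_at_depth_three(self):
        # heterozygote observed homozygous with probability 2^(1-d) = 0.25 at d=3
        fo = simulate_population_set(_cfg(families_per_population=300, n_snps=400, seed=6))
        reads = simulate_gbs_reads(fo, mean_depth=3.0, missing_rate=0.0, seed=6)
        het = fo.genotypes == 1
        at3 = het & (np.asarray(reads.depth) == 3)
        calls = reads.naive_calls()
        frac_hom = np.isin(calls[at3], [0.0, 2.0]).mean()
        n = at3.sum()
        assert n > 5000
        assert abs(frac_hom - 0.25) < 4 * math.sqrt(0.25 * 0.75 / n)

    def test_depth_and_missingness_match_study_targets(self):
        # zero-inflated depth reproduces mean depth 2.98 and ~23% missing jointly
        fo = simulate_population_set(_cfg(families_per_population=250, n_snps=400, seed=8))
        reads = simulate_gbs_reads(fo, mean_depth=2.98, missing_rate=0.23, seed=8)
        depth = np.asarray(reads.depth)
        assert abs((depth == 0).mean() - 0.23) < 0.005
        assert abs(depth[depth > 0].mean() - 2.98) < 0.02

    def test_missingness_independent_of_genotype(self):
        fo = simulate_population_set(_cfg(families_per_population=200, n_snps=300, seed=9))
        reads = simulate_gbs_reads(fo, mean_depth=3.0, missing_rate=0.25, seed=9)
        depth = np.asarray(reads.depth)
        rates = [
            (depth[fo.genotypes == g] == 0).mean() for g in (0, 1, 2)
        ]
        for r in rates:
            n = min((fo.genotypes == g).sum() for g in (0, 1, 2))
            assert abs(r - 0.25) < 4 * math.sqrt(0.25 * 0.75 / n)

    def test_ztp_mean_calibration(self):
        for target in (1.5, 2.98, 6.0):
            lam = _ztp_lambda(target)
            assert abs(lam / (1 - math.exp(-lam)) - target) < 1e-8


class TestTrial:
    def test_null_variances_give_pure_fixed_effects(self):
        cfg = _cfg(
            n_populations=2,
            families_per_population=10,
            traits={"y": TraitModel(sigma2_g=0.0, sigma2_gs=0.0, sigma2_e=0.0, mean=5.0)},
        )
        fo = simulate_population_set(cfg)
        trial = simulate_trial(fo)
        # every plot in one location x population cell has the identical value
        assert (trial.groupby(["location", "population"])["y"].nunique() == 1).all()
        # all variance components zero -> fixed offsets are zero -> grand mean
        assert np.allclose(trial["y"], 5.0)

    def test_balanced_design_one_plot_per_family_rep_location(self):
        fo = simulate_population_set(_cfg(n_populations=2, families_per_population=12))
        trial = simulate_trial(fo)
        counts = trial.groupby(["family", "location", "replicate"]).size()
        assert (counts == 1).all()
        assert len(trial) == 24 * 2 * 3

    def test_refuses_undersized_grid(self):
        cfg = _cfg(families_per_population=30, n_rows=2, n_cols=2)
        fo = simulate_population_set(cfg)
        with pytest.raises(ValueError, match="grid"):
            simulate_trial(fo)

    def test_family_variance_matches_anova_oracle(self):
        # expected-mean-squares ANOVA on family x location means recovers sigma2_g
        cfg = SimulationConfig(
            n_populations=1, families_per_population=500, n_snps=20, n_qtl=10, seed=12,
            traits={"Na": TraitModel(**SODIUM)},
        )
        fo = simulate_population_set(cfg)
        trial = simulate_trial(fo)
        cell = trial.groupby(["family", "location"])["Na"].mean().unstack()
        fam_means = cell.mean(axis=1)
        s, b = 2, 3
        ms_fam = s * fam_means.var(ddof=1)
        ms_int = ((cell.sub(cell.mean(0), axis=1).sub(fam_means, axis=0)
                   + fam_means.mean()) ** 2).to_numpy().sum() / (len(cell) - 1)
        # E[MS_fam] = s*sigma2_g + sigma2_gs + sigma2_e/b ; E[MS_int] = sigma2_gs + sigma2_e/b
        est_g = (ms_fam - ms_int) / s
        nf = len(fam_means)
        se = SODIUM["sigma2_g"] * math.sqrt(2.0 / (nf - 1)) * 1.5
        assert abs(est_g - SODIUM["sigma2_g"]) < 2 * se

    def test_family_effect_variance_coverage(self):
        # over replicate simulations the realized family-effect variance covers
        # the configured sigma2_g at the chi-square 95% rate
        hits, reps, nf = 0, 120, 60
        for r in range(reps):
            cfg = SimulationConfig(
                n_populations=1, families_per_population=nf, n_snps=10, n_qtl=4,
                seed=1000 + r, n_locations=1, n_replicates=1,
                traits={"y": TraitModel(sigma2_g=1.0, sigma2_gs=0.0, sigma2_e=0.0)},
            )
            fo = simulate_population_set(cfg)
            trial = simulate_trial(fo)
            # with all other variances zero each plot is mean+fixed+family effect
            v = trial.groupby("family")["y"].mean().var(ddof=1)
            from scipy.stats import chi2

            lo, hi = chi2.ppf([0.025, 0.975], nf - 1) / (nf - 1)
            hits += lo <= v <= hi
        assert hits / reps > 0.88

    def test_trial_deterministic_and_decoupled_from_marker_stream(self):
        a = simulate_trial(simulate_population_set(_cfg(seed=21)))
        b = simulate_trial(simulate_population_set(_cfg(seed=21)))
        pd.testing.assert_frame_equal(a, b)
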