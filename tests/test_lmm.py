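"""REML engine, BLUPs, significance tests and the heritability family."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ryegp import (
    ModelSpec,
    RandomTerm,
    RelationshipMatrix,
    SimulationConfig,
    TraitModel,
    extract_blups,
    genomic_heritability,
    heritability_from_components,
    model2_spec,
    model3_spec,
    reml_fit,
    repeatability,
    simulate_population_set,
    simulate_trial,
    variance_significance,
)

from conftest import SODIUM


def one_way(nf=40, r=5, s2g=1.0, s2e=0.64, seed=1):
    rng = np.random.default_rng(seed)
    fam = np.repeat([f"F{i:02d}" for i in range(nf)], r)
    y = np.repeat(rng.normal(0, np.sqrt(s2g), nf), r) + rng.normal(0, np.sqrt(s2e), nf * r)
    return pd.DataFrame(
        {"family": fam, "population": "P", "location": "L",
         "replicate": np.tile(np.arange(r), nf), "row": 1, "column": 1, "y": y}
    )


def ems_one_way(df, r):
    gm = df.groupby("family")["y"].mean()
    msb = r * gm.var(ddof=1)
    msw = ((df["y"] - df["family"].map(gm)) ** 2).sum() / (len(gm) * (r - 1))
    return (msb - msw) / r, msw


class TestREML:
    def test_balanced_one_way_equals_ems_anova(self):
        r = 5
        df = one_way(r=r)
        fit = reml_fit(df, ModelSpec("y", [], [RandomTerm("family", ("family",))]), tol=1e-10)
        s2g, s2e = ems_one_way(df, r)
        assert fit.components["family"] == pytest.approx(s2g, abs=1e-8)
        assert fit.components["residual"] == pytest.approx(s2e, abs=1e-8)

    def test_constant_response_all_components_at_zero_boundary(self):
        df = one_way()
        df["y"] = 3.14
        fit = reml_fit(df, ModelSpec("y", [], [RandomTerm("family", ("family",))]))
        assert (fit.components == 0).all()
        assert (fit.blups["family"] == 0).all()

    def test_singular_fixed_design_raises_named_error(self):
        df = one_way()
        df["copy"] = df["family"].str[-1]
        df["copy2"] = df["copy"]
        with pytest.raises(ValueError, match="singular"):
            reml_fit(df, ModelSpec("y", ["copy", "copy2"], [RandomTerm("family", ("family",))]))

    def test_model2_recovers_simulation_truth(self):
        cfg = SimulationConfig(
            n_populations=1, families_per_population=200, n_snps=30, n_qtl=10, seed=77,
            traits={"Na": TraitModel(**SODIUM, sigma2_b=2e-4, sigma2_r=2e-4, sigma2_c=2e-4)},
        )
        trial = simulate_trial(simulate_population_set(cfg))
        fit = reml_fit(trial, model2_spec("Na"))
        assert abs(fit.components["family"] - SODIUM["sigma2_g"]) < 3 * fit.se["family"]
        assert abs(fit.components["residual"] - SODIUM["sigma2_e"]) < 3 * fit.se["residual"]
        assert fit.converged

    def test_row_order_invariance(self):
        df = one_way(nf=25, r=4, seed=3)
        spec = ModelSpec("y", [], [RandomTerm("family", ("family",))])
        a = reml_fit(df, spec)
        b = reml_fit(df.sample(frac=1.0, random_state=9).reset_index(drop=True), spec)
        pd.testing.assert_series_equal(a.components, b.components, atol=1e-6, rtol=1e-6)
        pd.testing.assert_series_equal(a.blups["family"], b.blups["family"], atol=1e-6, rtol=1e-6)

    def test_loglik_nondecreasing_along_trace(self):
        df = one_way(nf=30, r=3, seed=4)
        fit = reml_fit(df, ModelSpec("y", [], [RandomTerm("family", ("family",))]))
        lls = [t["loglik"] for t in fit.iteration_trace]
        assert all(b >= a - 1e-6 for a, b in zip(lls, lls[1:]))


class TestBLUPs:
    def test_shrinkage_matches_closed_form(self):
        r = 4
        df = one_way(nf=30, r=r, seed=5)
        fit = reml_fit(df, ModelSpec("y", [], [RandomTerm("family", ("family",))]), tol=1e-10)
        s2g, s2e = fit.components["family"], fit.components["residual"]
        shrink = s2g / (s2g + s2e / r)
        gm = df.groupby("family")["y"].mean()
        expected = shrink * (gm - df["y"].mean())
        got = fit.blups["family"]
        np.testing.assert_allclose(got.loc[expected.index], expected, atol=1e-6)

    def test_blups_sum_to_zero_and_preserve_mean_ordering(self):
        df = one_way(nf=30, r=4, seed=6)
        fit = reml_fit(df, ModelSpec("y", [], [RandomTerm("family", ("family",))]))
        u = fit.blups["family"]
        assert abs(u.sum()) < 1e-6
        gm = df.groupby("family")["y"].mean()
        assert (u.loc[gm.sort_values().index].diff().dropna() >= -1e-12).all()

    def test_extract_blups_adds_intercept_and_validates_term(self):
        df = one_way(nf=20, r=3, seed=7)
        fit = reml_fit(df, ModelSpec("y", [], [RandomTerm("family", ("family",))]))
        adj = extract_blups(fit)
        raw = extract_blups(fit, add_intercept=False)
        assert np.allclose(adj - raw, fit.intercept)
        with pytest.raises(KeyError, match="nonexistent"):
            extract_blups(fit, term="nonexistent")


class TestSignificance:
    def test_boundary_estimate_gives_half(self):
        # a fit whose family component sits at the zero boundary has LR = 0
        rng = np.random.default_rng(8)
        df = one_way(nf=30, r=3, s2g=0.0, seed=8)
        fit = reml_fit(df, ModelSpec("y", [], [RandomTerm("family", ("family",))]))
        if fit.components["family"] == 0:
            res = variance_significance(fit, "family")
            assert res["p_value"] == pytest.approx(0.5)
        else:  # this seed produced a positive estimate; p must still exceed 0.05
            assert variance_significance(fit, "family")["p_value"] > 0.05

    def test_strong_family_variance_detected(self):
        df = one_way(nf=60, r=4, s2g=1.0, s2e=1.0, seed=9)
        fit = reml_fit(df, ModelSpec("y", [], [RandomTerm("family", ("family",))]))
        res = variance_significance(fit, "family")
        assert res["p_value"] < 1e-6
        assert res["lr_statistic"] > 0


class TestHeritability:
    @pytest.mark.parametrize(
        "comps,expected",
        [
            ((2.32e-3, 0.25e-3, 3.93e-3), 0.75),  # sodium row
            ((0.50, 0.16, 1.36), 0.62),           # neutral detergent fiber row
        ],
    )
    def test_family_mean_formula_reproduces_printed_rows(self, comps, expected):
        est = heritability_from_components(*comps, s=2, b=3)
        assert round(est.value, 2) == expected

    def test_no_noise_gives_unity(self):
        assert heritability_from_components(1.0, 0.0, 0.0, s=3, b=2).value == 1.0

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            heritability_from_components(0.0, 0.0, 0.0, s=2, b=3)

    def test_invalid_design_rejected(self):
        with pytest.raises(ValueError):
            heritability_from_components(1.0, 0.1, 1.0, s=0, b=3)
        with pytest.raises(ValueError):
            heritability_from_components(-1.0, 0.1, 1.0, s=2, b=3)

    @given(
        g=st.floats(0.0, 1e4),
        gs=st.floats(0.0, 1e4),
        e=st.floats(1e-12, 1e4),
        s=st.integers(1, 10),
        b=st.integers(1, 10),
    )
    @settings(deadline=None, max_examples=200, derandomize=True)
    def test_value_bounded_in_unit_interval(self, g, gs, e, s, b):
        v = heritability_from_components(g, gs, e, s=s, b=b).value
        assert 0.0 <= v <= 1.0
        # adding location or replicate effort can only raise a family-mean h2
        more = heritability_from_components(g, gs, e, s=s, b=b + 1).value
        assert more >= v - 1e-12


class TestGenomicHeritability:
    def test_identity_matrix_reduces_to_repeatability(self, small_trial):
        fams = sorted(small_trial["family"].unique())
        I = RelationshipMatrix(fams, np.eye(len(fams)), "identity")
        fit = reml_fit(small_trial, model2_spec("Na"))
        R = repeatability(fit)
        h2g, _ = genomic_heritability(small_trial, I, "Na")
        assert h2g.value == pytest.approx(R.value, abs=1e-8)
        assert h2g.kind == "genomic"

    def test_tracks_repeatability_across_trait_architectures(self, standard_panel):
        founders, reads, _, grm, _ = standard_panel
        traits = {
            "low": TraitModel(sigma2_g=0.4e-3, sigma2_gs=0.25e-3, sigma2_e=3.93e-3),
            "high": TraitModel(**SODIUM),
        }
        cfg = SimulationConfig(
            n_populations=2, families_per_population=80, n_snps=600, n_qtl=200,
            ancestral_pool_size=15, seed=31, traits=traits,
        )
        fo = simulate_population_set(cfg)
        trial = simulate_trial(fo)
        from ryegp import calls_to_dosages, mean_impute, simulate_gbs_reads, vanraden_grm

        G = vanraden_grm(mean_impute(calls_to_dosages(simulate_gbs_reads(fo, 8.0, 0.1, 31))))
        vals = {}
        for t in traits:
            fit = reml_fit(trial, model2_spec(t))
            h2g, _ = genomic_heritability(trial, G, t)
            vals[t] = (repeatability(fit).value, h2g.value)
        # genomic h2 tracks repeatability: same ranking, similar magnitude
        assert vals["high"][1] > vals["low"][1]
        for R, h2 in vals.values():
            assert h2 == pytest.approx(R, abs=0.15)

    def test_missing_family_in_grm_raises(self, small_trial):
        fams = sorted(small_trial["family"].unique())[:-1]
        I = RelationshipMatrix(fams, np.eye(len(fams)), "identity")
        with pytest.raises(KeyError, match="absent"):
            genomic_heritability(small_trial, I, "Na")


class TestModelSpecs:
    def test_model3_drops_population_fixed_effect(self):
        spec = model3_spec("y")
        assert "population" not in spec.fixed
        assert {t.name for t in spec.random} >= {"family", "family_location"}

    def test_single_level_fixed_factor_is_ignored(self):
        # one population present: its fixed term carries no contrast
        df = one_way(nf=20, r=3, seed=10)
        fit = reml_fit(df, ModelSpec("y", ["population"], [RandomTerm("family", ("family",))]))
        assert list(fit.fixed_effects.index) == ["intercept"]
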