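"""Tests for the growth models: mixed model, LLR tests, hierarchical VB."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
import statsmodels.formula.api as smf
from scipy import stats

from esoxtrace import synthgen
from esoxtrace.growthmod import (
    LMM_TERMS,
    MCMCConfig,
    _gamma_logpdf,
    fit_increment_lmm,
    fit_vb_hierarchical,
    group_differences,
    llr_term_tests,
    nakagawa_r2,
    vb_radius,
)


@pytest.fixture(scope="module")
def growth_records():
    cfg = synthgen.SynthConfig(n_fish=(15, 15, 15, 15), seed=4)
    truth = []
    rng = np.random.default_rng(10)
    i = 0
    for phe, n in zip(synthgen.PHENOTYPES, cfg.n_fish):
        for _ in range(n):
            i += 1
            truth.append({"fish_id": f"F{i:03d}",
                          "age": int(rng.integers(3, 10)),
                          "sex": "F" if rng.random() < 0.6 else "M",
                          "phenotype": phe})
    return synthgen.simulate_increments(
        pd.DataFrame(truth), cfg, np.random.default_rng(11))


@pytest.fixture(scope="module")
def vb_post():
    """Short-chain hierarchical fit on two planted groups."""
    cfg = synthgen.SynthConfig(n_fish=(8, 8, 1, 1), seed=3)
    ds = synthgen.simulate_population(cfg)
    keep = ds.truth["true_phenotype"].isin(["FW_RESIDENT", "ANADROMOUS"])
    ids = ds.truth.loc[keep, "fish_id"]
    radii = ds.radii[ds.radii["fish_id"].isin(set(ids))]
    groups = ds.truth.set_index("fish_id")["true_phenotype"].loc[ids]
    mcmc = MCMCConfig(chains=2, draws=150, warmup=300, thin=2, seed=1)
    return fit_vb_hierarchical(radii, groups, mcmc=mcmc)


class TestVbRadius:
    def test_hand_value(self):
        # R(3) = 2.68 * (1 - exp(-0.11 * (3 + 0.81)))
        expect = 2.68 * (1.0 - np.exp(-0.11 * 3.81))
        assert vb_radius(3.0, 2.68, 0.11, -0.81) == pytest.approx(expect)

    def test_vectorised_monotone(self):
        t = np.arange(1, 14)
        r = vb_radius(t, 2.7, 0.12, -0.8)
        assert np.all(np.diff(r) > 0)
        assert np.all(r < 2.7)

    def test_validation(self):
        with pytest.raises(ValueError, match="must be > 0"):
            vb_radius(1.0, -1.0, 0.1, 0.0)
        with pytest.raises(ValueError, match="must be > 0"):
            vb_radius(1.0, 1.0, 0.0, 0.0)


class TestGammaParameterisation:
    def test_matches_scipy(self):
        """shape = mu^2 tau, rate = mu tau against scipy's gamma logpdf."""
        rng = np.random.default_rng(0)
        for _ in range(20):
            mu = float(rng.uniform(0.1, 5.0))
            tau = float(rng.uniform(0.5, 50.0))
            x = float(rng.uniform(0.05, 8.0))
            ref = stats.gamma.logpdf(x, a=mu * mu * tau, scale=1.0 / (mu * tau))
            assert _gamma_logpdf(x, mu, tau) == pytest.approx(ref, abs=1e-10)

    def test_moments(self):
        # the (mu, tau) gamma has mean mu and variance 1/tau by design
        mu, tau = 2.68, 25.0
        shape, rate = mu * mu * tau, mu * tau
        assert shape / rate == pytest.approx(mu)
        assert shape / rate ** 2 == pytest.approx(1.0 / tau)


class TestMixedModel:
    def test_fit_structure(self, growth_records):
        fit = fit_increment_lmm(growth_records)
        assert fit.terms == list(LMM_TERMS)
        assert fit.random_intercept_var >= 0
        assert fit.residual_var > 0
        assert 0 <= fit.r2_marginal <= fit.r2_conditional <= 1
        assert "Intercept" in fit.params.index

    def test_recovers_planted_coefficients(self, growth_records):
        fit = fit_increment_lmm(growth_records)
        beta = dict(synthgen.SynthConfig().increment_coefs)
        assert fit.params["age"] == pytest.approx(beta["age"], abs=0.03)
        assert fit.params["I(age ** 2)"] == pytest.approx(
            beta["age2"], abs=0.005)
        assert fit.params["annual_d18o_res"] == pytest.approx(
            beta["d18o_res"], abs=0.03)
        assert fit.params["annual_srca_z"] == pytest.approx(
            beta["sr_z"], abs=0.03)

    def test_ols_limit(self, growth_records):
        """The GLS fixed effects of the mixed model reduce to plain OLS
        when the random-intercept variance is zero."""
        fit = fit_increment_lmm(growth_records, terms=["age", "d18o", "sr"])
        model = fit.result.model
        beta0, _ = model.get_fe_params(np.array([[1e-10]]), np.empty(0))
        prep = growth_records.copy()
        prep["log10_increment"] = np.log10(prep["increment_um"])
        prep["age"] = prep["lifeyear"].astype(float)
        ols = smf.ols("log10_increment ~ age + annual_d18o_res + "
                      "annual_srca_z", prep).fit()
        np.testing.assert_allclose(np.asarray(beta0),
                                   ols.params.to_numpy(), atol=1e-6)
        # and the reported estimates sit at the fitted variance ratio
        ratio = fit.random_intercept_var / fit.residual_var
        beta_fit, _ = model.get_fe_params(np.array([[ratio]]), np.empty(0))
        np.testing.assert_allclose(np.asarray(beta_fit),
                                   fit.params.to_numpy(), atol=1e-6)

    def test_identifiability_errors(self, growth_records):
        one_phe = growth_records[growth_records["phenotype"]
                                 == "FW_RESIDENT"]
        with pytest.raises(ValueError, match="phenotype is constant"):
            fit_increment_lmm(one_phe, terms=["age", "phenotype"])
        one_sex = growth_records[growth_records["sex"] == "F"]
        with pytest.raises(ValueError, match="sex is constant"):
            fit_increment_lmm(one_sex, terms=["age", "sex"])

    def test_positive_increments_required(self, growth_records):
        df = growth_records.copy()
        df.loc[df.index[0], "increment_um"] = 0.0
        with pytest.raises(ValueError, match="> 0"):
            fit_increment_lmm(df, terms=["age"])

    def test_nakagawa_by_hand(self, growth_records):
        fit = fit_increment_lmm(growth_records, terms=["age", "age2", "sr"])
        X = fit.result.model.exog
        eta = X @ fit.params.to_numpy()
        vf = np.var(eta, ddof=1)
        denom = vf + fit.random_intercept_var + fit.residual_var
        r2m, r2c = nakagawa_r2(fit)
        assert r2m == pytest.approx(vf / denom)
        assert r2c == pytest.approx(
            (vf + fit.random_intercept_var) / denom)


class TestLlrTests:
    def test_table_structure(self, growth_records):
        tab = llr_term_tests(growth_records,
                             terms=["age", "age2", "d18o", "sr"],
                             test_terms=["age", "d18o"])
        assert list(tab["term"]) == ["age", "d18o"]
        assert (tab["llr"] >= 0).all()
        assert ((tab["p"] >= 0) & (tab["p"] <= 1)).all()
        assert (tab["df"] == 1).all()

    def test_marginality(self, growth_records):
        tab = llr_term_tests(
            growth_records,
            terms=["age", "phenotype", "age_phenotype"],
            test_terms=["age", "phenotype", "age_phenotype"])
        by_term = tab.set_index("term")
        # dropping a marginal term removes the interaction too
        assert by_term.loc["age", "dropped_with"] == ["age_phenotype"]
        assert by_term.loc["phenotype", "dropped_with"] == ["age_phenotype"]
        assert by_term.loc["age_phenotype", "dropped_with"] == []
        # df: age drops 1 + 3 interaction columns
        assert by_term.loc["age", "df"] == 4
        assert by_term.loc["phenotype", "df"] == 6
        assert by_term.loc["age_phenotype", "df"] == 3

    def test_strong_term_detected(self, growth_records):
        tab = llr_term_tests(growth_records, terms=["age", "age2", "sr"],
                             test_terms=["age"])
        assert tab["p"].iloc[0] < 1e-6

    def test_unknown_term(self, growth_records):
        with pytest.raises(ValueError, match="not in the fitted model"):
            llr_term_tests(growth_records, terms=["age"],
                           test_terms=["sex"])


class TestHierarchicalVb:
    def test_posterior_structure(self, vb_post):
        post = vb_post
        assert post.groups == ["ANADROMOUS", "FW_RESIDENT"]
        for p in ("r_inf", "k", "s0"):
            for g in post.groups:
                assert post.draws[f"mu_{p}[{g}]"].shape == (2, 150)
                assert post.draws[f"tau_{p}[{g}]"].shape == (2, 150)
        assert post.draws["sigma_obs"].shape == (2, 150)
        assert np.all(post.draws["sigma_obs"] > 0)
        assert set(post.rhat) == set(post.ess)
        assert 0 < post.accept_rates["individual_blocks"] < 1

    def test_group_interval(self, vb_post):
        lo, hi, med = vb_post.group_interval("r_inf", "FW_RESIDENT")
        assert lo < med < hi
        lo50, hi50, _ = vb_post.group_interval("r_inf", "FW_RESIDENT",
                                               prob=0.5)
        assert lo <= lo50 < hi50 <= hi

    def test_individual_frame(self, vb_post):
        ind = vb_post.individual
        assert {"fish_id", "r_inf", "k", "s0", "t0", "group"} <= set(
            ind.columns)
        np.testing.assert_allclose(ind["t0"], -ind["s0"])
        assert (ind["r_inf"] > 0).all() and (ind["k"] > 0).all()

    def test_estimates_in_plausible_range(self, vb_post):
        cfg = synthgen.SynthConfig()
        for g in vb_post.groups:
            mu = cfg.vb_means[g]
            _, _, med_r = vb_post.group_interval("r_inf", g)
            _, _, med_k = vb_post.group_interval("k", g)
            assert med_r == pytest.approx(mu[0], rel=0.5)
            assert med_k == pytest.approx(mu[1], rel=1.0)

    def test_deterministic(self):
        cfg = synthgen.SynthConfig(n_fish=(4, 4, 1, 1), seed=6)
        ds = synthgen.simulate_population(cfg)
        keep = ds.truth["true_phenotype"].isin(
            ["FW_RESIDENT", "ANADROMOUS"])
        ids = ds.truth.loc[keep, "fish_id"]
        radii = ds.radii[ds.radii["fish_id"].isin(set(ids))]
        groups = ds.truth.set_index("fish_id")["true_phenotype"].loc[ids]
        mcmc = MCMCConfig(chains=2, draws=50, warmup=100, thin=1, seed=9)
        a = fit_vb_hierarchical(radii, groups, mcmc=mcmc)
        b = fit_vb_hierarchical(radii, groups, mcmc=mcmc)
        for key in a.draws:
            np.testing.assert_array_equal(a.draws[key], b.draws[key])

    def test_input_validation(self, vb_post):
        radii = pd.DataFrame({
            "fish_id": ["A", "A", "B"], "age": [1, 2, 1],
            "radius": [0.5, 0.9, 0.4]})
        with pytest.raises(ValueError, match="< 2 radius"):
            fit_vb_hierarchical(radii, {"A": "g", "B": "g"},
                                mcmc=MCMCConfig(chains=1, draws=10,
                                                warmup=10, thin=1))
        radii2 = pd.DataFrame({
            "fish_id": ["A", "A", "B", "B"], "age": [1, 2, 1, 2],
            "radius": [0.5, 0.9, 0.4, 0.8]})
        with pytest.raises(ValueError, match="no group for fish"):
            fit_vb_hierarchical(radii2, {"A": "g"},
                                mcmc=MCMCConfig(chains=1, draws=10,
                                                warmup=10, thin=1))

    def test_group_differences(self, vb_post):
        tab = group_differences(vb_post)
        assert set(tab["parameter"]) == {"r_inf", "k", "t0"}
        assert len(tab) == 3  # one pair, three parameters
        assert ((tab["different"]) == (~tab["overlap"])).all()
        assert (tab["lo_a"] <= tab["hi_a"]).all()
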