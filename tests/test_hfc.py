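"""Body condition, design construction, the Gibbs sampler and diagnostics."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from bearlink.datatypes import ValidationError
from bearlink.hfc import (
    DEFAULT_SUITE,
    HierarchicalHFCModel,
    ModelSpec,
    build_design,
    compute_bci,
    gelman_rubin,
    run_model_suite,
    single_locus_ftest,
)
from bearlink.simulate import SimulationConfig, generate_genotypes, \
    generate_phenotypes


def records(n=200, seed=0, hl=None, **cfg_kwargs):
    cfg = SimulationConfig(n_individuals=n, seed=seed, **cfg_kwargs)
    g, truth = generate_genotypes(cfg.with_(n_loci=2))
    if hl is None:
        hl = np.random.default_rng(seed + 5000).beta(2, 2, n)
    return generate_phenotypes(cfg, truth, hl), truth, hl


class TestBCI:
    def test_points_on_regression_line_give_zero(self):
        sll = np.array([100.0, 150, 200, 250])
        mass = np.exp(0.5 + 2.0 * np.log(sll))
        assert np.allclose(compute_bci(mass, sll), 0.0, atol=1e-10)

    def test_standardisation_by_construction(self):
        rng = np.random.default_rng(0)
        sll = rng.uniform(120, 220, 50)
        mass = np.exp(1.0 + 1.8 * np.log(sll) + rng.normal(0, 0.1, 50))
        bci = compute_bci(mass, sll)
        assert abs(bci.mean()) < 1e-10
        assert bci.std(ddof=1) == pytest.approx(1.0, abs=1e-10)

    def test_matches_hand_computed_ols(self):
        sll = np.array([100.0, 120, 140, 160, 180])
        mass = np.array([80.0, 95, 130, 150, 160])
        x, y = np.log(sll), np.log(mass)
        slope = np.cov(x, y, ddof=1)[0, 1] / np.var(x, ddof=1)
        resid = y - (y.mean() + slope * (x - x.mean()))
        expected = resid / resid.std(ddof=1)
        assert np.allclose(compute_bci(mass, sll), expected, atol=1e-12)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValidationError):
            compute_bci(np.array([1.0, -2, 3]), np.array([1.0, 2, 3]))


class TestBuildDesign:
    def test_season_reference_is_fall(self):
        ph, _, _ = records(50, seed=1)
        d = build_design(ph, ModelSpec())
        assert "spring" in d.names and "summer" in d.names
        assert "fall" not in d.names
        fall_rows = ph["season"].to_numpy() == "fall"
        sp = d.X[:, d.names.index("spring")]
        su = d.X[:, d.names.index("summer")]
        assert ((sp[fall_rows] == 0) & (su[fall_rows] == 0)).all()

    def test_three_level_cluster_two_dummies(self):
        ph, truth, _ = records(60, seed=2, k_gen=3)
        d = build_design(ph, ModelSpec(include_genetic_k=True),
                         genetic_k=truth.genetic_cluster)
        dummies = [n for n in d.names if n.startswith("gen_k")]
        assert dummies == ["gen_k1", "gen_k2"]  # third cluster = reference

    def test_continuous_covariates_standardised(self):
        ph, _, _ = records(80, seed=3)
        d = build_design(ph, ModelSpec())
        for name in ("age", "northing", "hl"):
            col = d.X[:, d.names.index(name)]
            assert abs(col.mean()) < 1e-10
            assert col.std(ddof=1) == pytest.approx(1.0, abs=1e-10)

    def test_complete_cases_dropped_and_counted(self):
        ph, _, _ = records(40, seed=4)
        ph.loc[3, "mass"] = np.nan
        ph.loc[7, "hl"] = np.nan
        d = build_design(ph, ModelSpec())
        assert d.n_dropped == 2
        assert len(d.y) == 38


class TestGelmanRubin:
    def test_hand_computed_toy(self):
        c = np.array([[1.0, 2, 3, 4], [2.0, 3, 4, 5]])
        n = 4
        W = (c.var(axis=1, ddof=1)).mean()
        B = n * c.mean(axis=1).var(ddof=1)
        expected = math.sqrt(((n - 1) / n * W + B / n) / W)
        assert gelman_rubin(c) == pytest.approx(expected, abs=1e-12)

    def test_iid_chains_converged(self):
        rng = np.random.default_rng(1)
        c = rng.normal(size=(4, 500))
        assert gelman_rubin(c) < 1.1

    def test_divergent_chains_flagged(self):
        rng = np.random.default_rng(2)
        c = np.vstack([rng.normal(0, 1, 200), rng.normal(10, 1, 200)])
        assert gelman_rubin(c) > 2.0

    def test_zero_within_variance_inf(self):
        assert math.isinf(gelman_rubin(np.array([[1.0] * 10, [2.0] * 10])))


class TestSampler:
    def test_same_seed_identical_draws(self):
        ph, _, _ = records(60, seed=5)
        spec = ModelSpec(iterations=400, burn_in=200, seed=9)
        r1 = HierarchicalHFCModel.from_dataframe(ph, spec).fit()
        r2 = HierarchicalHFCModel.from_dataframe(ph, spec).fit()
        assert np.array_equal(r1.chains, r2.chains)

    def test_posterior_matches_mixedlm_oracle(self):
        """Fixed effects agree with a REML random-intercept fit."""
        import statsmodels.formula.api as smf

        ph, _, _ = records(400, seed=6)
        spec = ModelSpec(response="log_mass", iterations=2000, burn_in=500,
                         standardize=False, seed=3)
        res = HierarchicalHFCModel.from_dataframe(ph, spec).fit()

        df = ph.copy()
        df["log_mass"] = np.log(df["mass"])
        df["male"] = (df["sex"] == "M").astype(float)
        df["spring_d"] = (df["season"] == "spring").astype(float)
        df["summer_d"] = (df["season"] == "summer").astype(float)
        ml = smf.mixedlm(
            "log_mass ~ male + age + y + spring_d + summer_d + hl",
            df, groups=df["unit"]).fit(reml=True)
        pairs = {"sex": "male", "age": "age", "northing": "y",
                 "spring": "spring_d", "summer": "summer_d", "hl": "hl"}
        for ours, theirs in pairs.items():
            se = ml.bse[theirs]
            assert abs(res.means[ours] - ml.params[theirs]) < 4 * se

    def test_normal_means_special_case(self):
        """With no covariates the unit means are recovered (little
        shrinkage at large per-unit n)."""
        rng = np.random.default_rng(7)
        U, per = 6, 120
        alpha_true = rng.normal(0, 1.0, U)
        groups = np.repeat(np.arange(U), per)
        y = alpha_true[groups] + rng.normal(0, 0.5, U * per)
        spec = ModelSpec(iterations=1500, burn_in=500, seed=1)
        model = HierarchicalHFCModel(y, np.empty((U * per, 0)), groups, spec,
                                     names=[])
        res = model.fit()
        for u in range(U):
            sample_mean = y[groups == u].mean()
            post = res.means[f"alpha[unit{u}]"]
            assert abs(post - sample_mean) < 3 * 0.5 / math.sqrt(per)

    def test_zero_variance_group_structure_shrinks(self):
        """sigma_unit = 0 truth -> posterior sigma_alpha concentrates near 0."""
        ph, _, _ = records(500, seed=8, sigma_unit=0.0, sigma_resid=0.2)
        spec = ModelSpec(iterations=2000, burn_in=500, seed=2)
        res = HierarchicalHFCModel.from_dataframe(ph, spec).fit()
        sigma_alpha = np.median(res.chain("sigma_alpha"))
        sigma_resid = np.median(res.chain("sigma_resid"))
        assert sigma_alpha < 0.5 * sigma_resid

    def test_hl_recovery_single_fit(self):
        ph, truth, _ = records(500, seed=9)
        spec = ModelSpec(response="log_mass", standardize=False,
                         iterations=2000, burn_in=500, seed=4)
        res = HierarchicalHFCModel.from_dataframe(ph, spec).fit()
        assert abs(res.means["hl"] - truth.hl_effect) < 0.1
        lo, hi = res.ci["hl"]
        assert lo < truth.hl_effect < hi
        assert res.converged

    def test_unit_varying_slopes_fit(self):
        ph, _, _ = records(300, seed=10)
        spec = ModelSpec(unit_varying_hl=True, iterations=1500, burn_in=500,
                         seed=5)
        res = HierarchicalHFCModel.from_dataframe(ph, spec).fit()
        assert "mu_gamma" in res.means
        assert any(n.startswith("gamma[") for n in res.param_names)

    def test_single_chain_rejected(self):
        ph, _, _ = records(30, seed=11)
        model = HierarchicalHFCModel.from_dataframe(ph, ModelSpec())
        with pytest.raises(ValidationError):
            model.fit(chains=1)


class TestDIC:
    def test_independent_recomputation_from_chains(self):
        ph, _, _ = records(120, seed=12)
        spec = ModelSpec(iterations=1200, burn_in=400, seed=6)
        model = HierarchicalHFCModel.from_dataframe(ph, spec)
        res = model.fit()
        flat = res.chains.reshape(-1, res.chains.shape[2])
        p = len(model.names)
        U = model.n_units
        devs = []
        for row in flat:
            mu = model.X @ row[:p] + row[p:p + U][model.groups]
            var = row[-1] ** 2
            devs.append(-2 * stats.norm.logpdf(model.y, mu,
                                               math.sqrt(var)).sum())
        dbar = np.mean(devs)
        mean_row = flat.mean(axis=0)
        mu_hat = model.X @ mean_row[:p] + mean_row[p:p + U][model.groups]
        var_hat = (flat[:, -1] ** 2).mean()
        dhat = -2 * stats.norm.logpdf(model.y, mu_hat,
                                      math.sqrt(var_hat)).sum()
        assert res.dbar == pytest.approx(dbar, rel=1e-9)
        assert res.dic == pytest.approx(2 * dbar - dhat, rel=1e-9)
        assert res.pd_eff > 0

    def test_thinning_invariance(self):
        ph, _, _ = records(150, seed=13)
        base = ModelSpec(iterations=4200, burn_in=200, seed=7)
        r1 = HierarchicalHFCModel.from_dataframe(ph, base).fit()
        r2 = HierarchicalHFCModel.from_dataframe(
            ph, base).fit(thin=4, iterations=4200)
        assert abs(r1.dic - r2.dic) < 2.0

    def test_selects_generating_model(self):
        """DIC prefers the HL model when the HL effect is strong."""
        wins = 0
        for seed in range(5):
            ph, _, _ = records(200, seed=700 + seed)
            m1 = ModelSpec(model_id="M1", include_hl=False,
                           iterations=1200, burn_in=400, seed=seed)
            m2 = ModelSpec(model_id="M2", iterations=1200, burn_in=400,
                           seed=seed)
            d1 = HierarchicalHFCModel.from_dataframe(ph, m1).fit().dic
            d2 = HierarchicalHFCModel.from_dataframe(ph, m2).fit().dic
            wins += d2 < d1
        assert wins >= 4


class TestSingleLocusFtest:
    @staticmethod
    def locus_data(n, L, seed, beta_general=0.0, beta_local=None):
        rng = np.random.default_rng(seed)
        H = (rng.random((n, L)) < 0.3).astype(float)
        base = rng.normal(size=(n, 2))
        y = base @ np.array([0.5, -0.2]) + rng.normal(0, 0.5, n)
        y = y + beta_general * H.mean(axis=1)
        if beta_local is not None:
            y = y + beta_local * H[:, 0]
        return y, base, H

    def test_df_for_fifteen_loci(self):
        y, X, H = self.locus_data(100, 15, 0)
        F, df1, df2, p = single_locus_ftest(y, X, H)
        assert df1 == 14

    def test_calibrated_under_general_effect(self):
        """A uniform per-locus effect keeps the local-effect test null."""
        rej = 0
        reps = 100
        for seed in range(reps):
            y, X, H = self.locus_data(150, 10, seed, beta_general=1.0)
            F, df1, df2, p = single_locus_ftest(y, X, H)
            rej += p <= 0.05
        assert abs(rej / reps - 0.05) < 0.06

    def test_power_against_planted_local_effect(self):
        rej = 0
        for seed in range(25):
            y, X, H = self.locus_data(200, 10, 1000 + seed, beta_local=1.0)
            F, df1, df2, p = single_locus_ftest(y, X, H)
            rej += p <= 0.05
        assert rej >= 20

    def test_collinear_locus_dropped(self):
        y, X, H = self.locus_data(80, 5, 3)
        H2 = np.column_stack([H, H[:, 0]])  # duplicate locus column
        F, df1, df2, p = single_locus_ftest(y, X, H2)
        assert df1 == 4  # 6 loci - 1 - 1 dropped


class TestModelSuite:
    def test_bookkeeping_rows(self):
        ph, truth, _ = records(80, seed=14, k_gen=3)
        small = tuple(
            ModelSpec(model_id=m.model_id, include_hl=m.include_hl,
                      include_genetic_k=m.include_genetic_k,
                      include_genetic_pc=m.include_genetic_pc,
                      include_habitat_k=m.include_habitat_k,
                      include_habitat_pc=m.include_habitat_pc,
                      iterations=400, burn_in=200)
            for m in DEFAULT_SUITE)
        rng = np.random.default_rng(0)
        out = run_model_suite(
            ph, responses=("log_mass", "bci"), specs=small, seed=1,
            extend_best=False,
            genetic_k=truth.genetic_cluster,
            genetic_pc=rng.normal(size=(80, 2)),
            habitat_k=(truth.genetic_cluster > 1).astype(int) + 1,
            habitat_pc=rng.normal(size=(80, 2)),
        )
        assert len(out) == 2 * 4
        assert set(out["response"]) == {"log_mass", "bci"}
        assert (out.groupby("response")["dic_rank"].min() == 1).all()
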