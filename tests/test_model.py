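import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import expit, logit

from hospclimate.linkage import CONFOUNDER_COLUMNS
from hospclimate.model import (ClimateSignificance, ConvergenceError,
                               ModelConfig, ModelInputs, PosteriorSummary,
                               back_transform_covariates, build_model_inputs,
                               climate_effect_table, climate_significance, fit,
                               log_likelihood, recentred_gamma_draws,
                               standardize_covariates)

QUICK = ModelConfig(chains=2, iterations=1000, seed=17)


def confounder_frame(n, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame({
        "income": np.exp(rng.normal(10.9, 0.3, n)),
        "households": rng.uniform(1e3, 1e5, n),
        "pct_renter": rng.uniform(10, 60, n),
        "pct_uninsured": rng.uniform(2, 30, n),
        "pct_english_very_well": rng.uniform(60, 99, n),
        "pct_white_alone": rng.uniform(20, 95, n),
    })


def sim_inputs(climate_sizes, alpha=(-2.0,), sigma_u=0.1, gamma=None,
               denom=300, seed=0):
    """Simulate binomial cells directly at the ModelInputs level."""
    rng = np.random.default_rng(seed)
    H = sum(climate_sizes)
    M = len(alpha)
    C = len(climate_sizes)
    gamma = np.zeros(C) if gamma is None else np.asarray(gamma, float)
    hclim = np.repeat(np.arange(C), climate_sizes)
    u = rng.normal(0, sigma_u, H)
    cov = rng.standard_normal((H, 6))
    cov = (cov - cov.mean(0)) / cov.std(0, ddof=1)
    deaths, denoms, hidx, midx, cidx = [], [], [], [], []
    for h in range(H):
        for m in range(M):
            eta = alpha[m] + u[h] + gamma[hclim[h]]
            deaths.append(rng.binomial(denom, expit(eta)))
            denoms.append(denom)
            hidx.append(h)
            midx.append(m)
            cidx.append(hclim[h])
    return ModelInputs(
        deaths=np.array(deaths), denominators=np.array(denoms),
        hospital_index=np.array(hidx), measure_index=np.array(midx),
        climate_index=np.array(cidx), covariates=cov,
        provider_ids=[f"P{h:03d}" for h in range(H)],
        measure_ids=[f"M{m}" for m in range(M)],
        climate_codes=[f"C{c}" for c in range(C)])


class TestStandardize:
    def test_constant_column_rejected(self):
        df = confounder_frame(10)
        df["pct_renter"] = 30.0
        with pytest.raises(ValueError, match="pct_renter"):
            standardize_covariates(df)

    def test_two_point_column_sample_sd(self):
        df = confounder_frame(2, seed=1)
        df["pct_renter"] = [0.0, 10.0]
        z, _ = standardize_covariates(df)
        j = list(CONFOUNDER_COLUMNS).index("pct_renter")
        # sd with the n-1 denominator: sd([0,10]) = 10/sqrt(2)
        assert z[:, j] == pytest.approx([-np.sqrt(0.5), np.sqrt(0.5)])

    def test_round_trip(self):
        df = confounder_frame(40, seed=2)
        z, scaler = standardize_covariates(df)
        back = back_transform_covariates(z, scaler)
        assert np.allclose(back.to_numpy(), df[list(CONFOUNDER_COLUMNS)].to_numpy(),
                           rtol=1e-10)

    def test_columns_are_zscores(self):
        z, _ = standardize_covariates(confounder_frame(60, seed=3))
        assert np.allclose(z.mean(0), 0.0, atol=1e-8)
        assert np.allclose(z.std(0, ddof=1), 1.0, atol=1e-8)


class TestBuildInputs:
    def test_cell_count_with_one_unavailable(self, small_cohort):
        inputs = build_model_inputs(small_cohort)
        assert inputs.n_cells == sum(h.n_available for h in small_cohort.hospitals)

    def test_index_round_trip(self, small_inputs, small_cohort):
        frame = small_inputs.to_frame()
        by_provider = {h.provider_id: h for h in small_cohort.hospitals}
        for row in frame.sample(50, random_state=0).itertuples():
            h = by_provider[row.provider_id]
            (o,) = [o for o in h.observations
                    if o.measure_id == row.measure_id and o.available]
            assert (o.deaths, o.denominator) == (row.deaths, row.denominator)
            assert h.climate == row.climate

    def test_cells_match_generator(self, small_data, small_inputs):
        frame = small_inputs.to_frame().set_index(["provider_id", "measure_id"])
        truth = small_data.cells[small_data.cells["available"]]
        kept = truth[truth["provider_id"].isin(small_inputs.provider_ids)]
        assert len(frame) == len(kept)
        for row in kept.sample(60, random_state=1).itertuples():
            cell = frame.loc[(row.provider_id, row.measure_id)]
            assert (cell["deaths"], cell["denominator"]) == (row.deaths, row.denominator)

    def test_single_climate_rejected(self, small_cohort):
        clone = dataclasses.replace(small_cohort)
        clone.hospitals = [h for h in small_cohort.hospitals
                           if h.climate == small_cohort.hospitals[0].climate]
        with pytest.raises(ValueError, match="climate"):
            build_model_inputs(clone)

    def test_ordering_is_stable(self, small_cohort):
        a = build_model_inputs(small_cohort)
        b = build_model_inputs(small_cohort)
        assert a.provider_ids == b.provider_ids
        assert np.array_equal(a.deaths, b.deaths)


class TestLogLikelihoodOracle:
    def test_matches_binomial_logpmf_sum(self):
        """3 hospitals, 2 measures: the model log-likelihood equals an
        independent sum of scipy binomial log-pmfs to 1e-8."""
        inputs = sim_inputs([2, 1], alpha=(-1.5, -2.5), sigma_u=0.2, seed=5)
        rng = np.random.default_rng(7)
        alpha = rng.normal(-2, 0.5, 2)
        beta = rng.normal(0, 0.1, 6)
        gamma = rng.normal(0, 0.3, 2)
        u = rng.normal(0, 0.2, 3)
        ours = log_likelihood(inputs, alpha, beta, gamma, u)
        eta = (alpha[inputs.measure_index] + u[inputs.hospital_index]
               + gamma[inputs.climate_index]
               + inputs.covariates[inputs.hospital_index] @ beta)
        oracle = stats.binom.logpmf(inputs.deaths, inputs.denominators,
                                    expit(eta)).sum()
        assert ours == pytest.approx(float(oracle), abs=1e-8)


class TestFit:
    def test_intercept_only_recovers_pooled_rate(self):
        """Single measure, no climate block, hospitals at a common
        rate: the intercept posterior sits at the pooled logit."""
        inputs = sim_inputs([30], alpha=(-2.0,), sigma_u=0.0, seed=9)
        cfg = dataclasses.replace(QUICK, include_climate=False)
        post = fit(inputs, cfg)
        pooled = logit(inputs.deaths.sum() / inputs.denominators.sum())
        a = post.parameter("alpha[M0]")
        assert abs(a["mean"] - pooled) < 4 * a["sd"]
        assert not any(p.startswith("gamma") for p in post.summary["parameter"])

    def test_seed_determinism(self):
        inputs = sim_inputs([6, 6], alpha=(-2.0,), seed=3)
        cfg = ModelConfig(chains=2, iterations=400, seed=123)
        a = fit(inputs, cfg)
        b = fit(inputs, cfg)
        pd.testing.assert_frame_equal(a.summary, b.summary)

    def test_different_seeds_differ(self):
        inputs = sim_inputs([6, 6], alpha=(-2.0,), seed=3)
        a = fit(inputs, ModelConfig(chains=2, iterations=400, seed=1))
        b = fit(inputs, ModelConfig(chains=2, iterations=400, seed=2))
        assert not a.summary["mean"].equals(b.summary["mean"])

    def test_shrinkage_stronger_for_small_climates(self):
        """Matched true effects, unmatched sample sizes: the 4-hospital
        climates shrink toward zero harder than the 60-hospital ones."""
        inputs = sim_inputs([60, 60, 4, 4], alpha=(-2.0,), sigma_u=0.05,
                            gamma=(0.25, -0.25, 0.25, -0.25), denom=400, seed=31)
        post = fit(inputs, QUICK)
        g = recentred_gamma_draws(post).mean(0)
        big = (abs(g[0]) + abs(g[1])) / 2
        small = (abs(g[2]) + abs(g[3])) / 2
        assert small < big

    def test_parameter_recovery_small_cohort(self, small_data, small_inputs, small_fit):
        """Climate effects recovered within 3 posterior sds on the
        recentred scale (200-hospital cohort)."""
        assert small_fit.converged
        codes = small_data.truth["climate_codes"]
        kept = [codes.index(c) for c in small_inputs.climate_codes]
        g_true = np.array(small_data.truth["gamma"])[kept]
        g_true = g_true - g_true.mean()
        g = recentred_gamma_draws(small_fit)
        gm, gsd = g.mean(0), g.std(0, ddof=1)
        assert np.all(np.abs(gm - g_true) < 3 * gsd)
        b_true = np.array(small_data.truth["beta_effective"])
        for j, col in enumerate(CONFOUNDER_COLUMNS):
            b = small_fit.parameter(f"beta[{col}]")
            assert abs(b["mean"] - b_true[j]) < 4 * b["sd"]

    def test_normal_likelihood_variant_runs(self):
        inputs = sim_inputs([8, 8], alpha=(-2.0,), seed=3)
        cfg = dataclasses.replace(QUICK, likelihood="normal-on-logit-rate")
        post = fit(inputs, cfg)
        assert "sigma_e" in set(post.summary["parameter"])

    def test_unknown_likelihood_rejected(self):
        inputs = sim_inputs([4, 4], seed=3)
        with pytest.raises(ValueError):
            fit(inputs, dataclasses.replace(QUICK, likelihood="poisson"))


class TestClimateEffectTable:
    def test_recentred_effects_sum_to_zero(self, small_fit):
        table = climate_effect_table(small_fit)
        assert table["mean"].sum() == pytest.approx(0.0, abs=1e-10)

    def test_rank_orders_means(self, small_fit):
        table = climate_effect_table(small_fit)
        assert list(table["rank"]) == list(range(1, len(table) + 1))
        assert table["mean"].is_monotonic_increasing

    def test_refuses_nonconverged_fit(self, small_fit):
        bad = dataclasses.replace(small_fit, converged=False)
        with pytest.raises(ConvergenceError, match="R-hat"):
            climate_effect_table(bad)

    def test_single_draw_degenerate_interval(self):
        inputs = sim_inputs([4, 4], seed=3)
        cfg = ModelConfig(chains=1, iterations=2, warmup_frac=0.5, seed=0)
        post = fit(inputs, cfg)
        table = climate_effect_table(post, require_converged=False)
        assert np.allclose(table["q2.5"], table["mean"])
        assert np.allclose(table["q97.5"], table["mean"])


class TestClimateSignificance:
    def test_one_level_climate_is_vacuous(self):
        """A single-level climate block cannot beat the no-climate
        model: the comparison lands within two standard errors of zero."""
        inputs = sim_inputs([40], alpha=(-2.0,), sigma_u=0.25, denom=500, seed=19)
        sig = climate_significance(inputs, dataclasses.replace(QUICK, iterations=2000))
        assert isinstance(sig, ClimateSignificance)
        assert abs(sig.elpd_diff) <= max(2 * sig.se_diff, 2.0)
        assert not sig.climate_preferred
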