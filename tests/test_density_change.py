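"""Density estimation, the hierarchical Poisson model and its sampler."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import sswdkit as sk
from sswdkit.density_change import ModelParams, PosteriorDraws


def make_counts(rows):
    return pd.DataFrame(
        rows, columns=["transect_id", "taxon", "count", "area_m2", "year01"])


class TestDensityTable:
    def _tables(self, counts_2014, counts_2015, area=100.0):
        t_rows, s_rows = [], []
        for year, counts in [(2014, counts_2014), (2015, counts_2015)]:
            for i, c in enumerate(counts):
                tid = f"{year}-{i}"
                t_rows.append({"transect_id": tid, "site": "X",
                               "date": f"{year}-06-01", "year": year,
                               "month": "June", "area_m2": area})
                s_rows += [{"transect_id": tid, "taxon": "t",
                            "sswd_status": "healthy", "year": year,
                            "month": "June"}] * c
        return pd.DataFrame(t_rows), pd.DataFrame(s_rows)

    def test_simple_density(self):
        tr, st = self._tables([1, 1, 1, 1] + [0] * 16, [], area=100.0)
        out = sk.density_table(tr, st, taxa=["t"])
        row = out[(out["taxon"] == "t") & (out["year"] == 2014)]
        assert row["density_per_100m2"].iloc[0] == pytest.approx(0.2)

    def test_zero_counts_distinct_from_not_surveyed(self):
        tr, st = self._tables([0, 0], [], area=100.0)
        out = sk.density_table(tr, st, taxa=["t"])
        assert (out["year"] == 2015).sum() == 0  # not surveyed: no row
        row = out[out["year"] == 2014]
        assert row["density_per_100m2"].iloc[0] == 0.0  # surveyed, zero

    def test_study_scale_arithmetic(self):
        # 118 stars over 2,160 m^2 -> 5.46 per 100 m^2
        counts = [6] * 19 + [4]  # 118 stars across 20 transects of 108 m^2
        tr, st = self._tables(counts, [], area=108.0)
        out = sk.density_table(tr, st, taxa=["t"])
        assert out["density_per_100m2"].iloc[0] == pytest.approx(
            100 * 118 / 2160, abs=1e-9)


class TestLogPosterior:
    def _params(self, J, N, **kw):
        base = dict(alpha=np.full(J, -1.0), beta=np.zeros(J), eps=np.zeros(N),
                    mu_alpha=0.0, mu_beta=0.0, sigma_alpha=1.0,
                    sigma_beta=1.0, sigma_eps=0.5, rho=0.2)
        base.update(kw)
        return ModelParams(**base)

    def test_zero_counts_zero_rate_limit_finite(self):
        data = make_counts([("t0", "a", 0, 100.0, 0)])
        lp = sk.log_posterior(self._params(1, 1, alpha=np.array([-30.0])), data)
        assert np.isfinite(lp)  # log Poisson(0; mu) = -mu stays finite

    def test_degenerate_correlation_rejected(self):
        data = make_counts([("t0", "a", 1, 100.0, 0)])
        for rho in (-1.0, 1.0):
            assert sk.log_posterior(self._params(1, 1, rho=rho), data) == -math.inf

    def test_nonfinite_input_never_raises(self):
        data = make_counts([("t0", "a", 1, 100.0, 0)])
        lp = sk.log_posterior(self._params(1, 1, mu_alpha=math.nan), data)
        assert lp == -math.inf

    def test_matches_term_by_term_oracle(self):
        # independent composition from scipy building blocks
        data = make_counts([
            ("t0", "a", 3, 100.0, 0), ("t1", "a", 0, 80.0, 1),
            ("t2", "b", 7, 100.0, 0), ("t3", "b", 2, 120.0, 1),
        ])
        params = ModelParams(
            alpha=np.array([-3.1, -2.4]), beta=np.array([-0.7, 0.2]),
            eps=np.array([0.1, -0.2, 0.05, 0.3]),
            mu_alpha=-2.5, mu_beta=-0.5, sigma_alpha=1.3, sigma_beta=0.9,
            sigma_eps=0.4, rho=-0.3)
        priors = sk.PriorConfig()

        taxon_index = {"a": 0, "b": 1}
        expected = 0.0
        for i, row in data.iterrows():
            j = taxon_index[row["taxon"]]
            log_mu = (math.log(row["area_m2"]) + params.alpha[j]
                      + params.beta[j] * row["year01"] + params.eps[i])
            expected += sps.poisson.logpmf(row["count"], math.exp(log_mu))
        cov = np.array([
            [params.sigma_alpha**2,
             params.rho * params.sigma_alpha * params.sigma_beta],
            [params.rho * params.sigma_alpha * params.sigma_beta,
             params.sigma_beta**2]])
        for j in range(2):
            expected += sps.multivariate_normal.logpdf(
                [params.alpha[j], params.beta[j]],
                mean=[params.mu_alpha, params.mu_beta], cov=cov)
        expected += sps.norm.logpdf(params.eps, 0, params.sigma_eps).sum()
        expected += sps.norm.logpdf(params.mu_alpha, 0, priors.mu_sd)
        expected += sps.norm.logpdf(params.mu_beta, 0, priors.mu_sd)
        expected += 3 * sps.uniform.logpdf(0.5, 0, priors.sigma_upper)
        expected += sps.uniform.logpdf(0.0, -1, 2)

        assert sk.log_posterior(params, data, priors) == pytest.approx(
            expected, abs=1e-8)


class TestGelmanRubin:
    def test_identical_chains_near_one(self):
        rng = np.random.default_rng(0)
        chain = rng.normal(size=1000)
        assert sk.gelman_rubin(np.tile(chain, (3, 1))) == pytest.approx(1.0, abs=1e-3)

    def test_separated_chains_large(self):
        rng = np.random.default_rng(1)
        chains = np.stack([rng.normal(0, 1, 500), rng.normal(10, 1, 500)])
        assert sk.gelman_rubin(chains) > 1.1 * 5

    def test_iid_long_chains_converged(self):
        rng = np.random.default_rng(2)
        chains = rng.normal(size=(3, 5000))
        assert sk.gelman_rubin(chains) < 1.05

    def test_direct_formula_evaluation(self):
        chains = np.array([[1.0, 2.0, 3.0], [2.0, 4.0, 6.0]])
        m, n = 2, 3
        W = np.mean([np.var(c, ddof=1) for c in chains])
        B = n * np.var([np.mean(c) for c in chains], ddof=1)
        expected = math.sqrt(((n - 1) / n * W + (m + 1) / (m * n) * B) / W)
        assert sk.gelman_rubin(chains) == pytest.approx(expected, rel=1e-12)


class TestEffectiveSampleSize:
    def test_iid_near_n(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=20_000)
        assert sk.effective_sample_size(x) == pytest.approx(len(x), rel=0.1)

    def test_constant_draws_minimal(self):
        assert sk.effective_sample_size(np.ones(100)) == 1.0

    def test_ar1_closed_form(self):
        rng = np.random.default_rng(4)
        phi = 0.5
        x = np.zeros(60_000)
        for t in range(1, len(x)):
            x[t] = phi * x[t - 1] + rng.normal()
        ratio = sk.effective_sample_size(x) / len(x)
        assert ratio == pytest.approx((1 - phi) / (1 + phi), rel=0.1)


class TestRunMcmc:
    @pytest.fixture(scope="class")
    def small_data(self):
        rng = np.random.default_rng(10)
        rows = []
        for j, taxon in enumerate(["a", "b", "c"]):
            alpha, beta = -3.0 + 0.5 * j, -1.0 + 0.6 * j
            for i in range(24):
                year = i % 2
                lam = 100.0 * math.exp(alpha + beta * year)
                rows.append((f"t{i}", taxon, rng.poisson(lam), 100.0, year))
        return make_counts(rows)

    def test_deterministic_replay(self, small_data):
        cfg = sk.ChainConfig(n_chains=2, iterations=400, burn_in=100, thin=2, seed=5)
        a = sk.run_mcmc(small_data, chains=cfg)
        b = sk.run_mcmc(small_data, chains=cfg)
        for name in a.parameters:
            np.testing.assert_array_equal(a.draws[name], b.draws[name])

    def test_retained_draw_count(self, small_data):
        cfg = sk.ChainConfig(n_chains=3, iterations=600, burn_in=100, thin=5, seed=6)
        draws = sk.run_mcmc(small_data, chains=cfg)
        assert draws.draws["mu_alpha"].shape == (3, 120)
        assert cfg.retained_per_chain * 3 == 360

    def test_support_invariants(self, small_data):
        draws = sk.run_mcmc(small_data, chains=sk.ChainConfig(
            n_chains=2, iterations=1000, burn_in=200, thin=1, seed=7))
        for name in ("sigma_alpha", "sigma_beta", "sigma_eps"):
            flat = draws.combined(name)
            assert (flat > 0).all() and (flat < 100).all()
        rho = draws.combined("rho")
        assert (rho > -1).all() and (rho < 1).all()

    def test_offset_contract(self, small_data):
        # scaling every area by c shifts alpha by -log c, leaves beta alone
        cfg = sk.ChainConfig(n_chains=2, iterations=3000, burn_in=800, thin=2, seed=8)
        base = sk.run_mcmc(small_data, chains=cfg, fix_sigma_eps=0.0)
        scaled_data = small_data.assign(area_m2=small_data["area_m2"] * 10.0)
        scaled = sk.run_mcmc(scaled_data, chains=cfg, fix_sigma_eps=0.0)
        for taxon in ("a", "b", "c"):
            a0 = base.combined(f"alpha[{taxon}]").mean()
            a1 = scaled.combined(f"alpha[{taxon}]").mean()
            assert a1 - a0 == pytest.approx(-math.log(10.0), abs=0.08)
            b0 = base.combined(f"beta[{taxon}]").mean()
            b1 = scaled.combined(f"beta[{taxon}]").mean()
            assert b1 == pytest.approx(b0, abs=0.08)

    def test_single_taxon_warns(self):
        data = make_counts([("t0", "a", 3, 100.0, 0), ("t1", "a", 1, 100.0, 1)])
        with pytest.warns(UserWarning, match="single taxon"):
            sk.run_mcmc(data, chains=sk.ChainConfig(
                n_chains=1, iterations=200, burn_in=50, thin=5, seed=9))


class TestSummarize:
    def _draws_from(self, beta_values):
        arr = np.asarray(beta_values, dtype=float).reshape(1, -1)
        return PosteriorDraws(
            draws={"beta[t]": arr}, taxa=("t",),
            chain_config=sk.ChainConfig(n_chains=1, iterations=len(beta_values),
                                        burn_in=0, thin=1, seed=0))

    def test_all_negative_is_credible_decline(self):
        summary = sk.summarize(self._draws_from(-np.abs(np.random.default_rng(0)
                                                        .normal(size=500)) - 0.1))
        assert summary.change_flags["t"] == "credible decline"
        assert summary.decline_probability["t"] == 1.0

    def test_symmetric_draws_not_credible(self):
        rng = np.random.default_rng(1)
        summary = sk.summarize(self._draws_from(rng.normal(0, 1, 2000)))
        assert summary.change_flags["t"] == "not credible"
        assert summary.decline_probability["t"] == pytest.approx(0.5, abs=0.05)

    def test_percentile_ordering(self):
        rng = np.random.default_rng(2)
        summary = sk.summarize(self._draws_from(rng.normal(size=1000)))
        row = summary.table.loc["beta[t]"]
        assert row["2.5%"] <= row["50%"] <= row["97.5%"]
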