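"""Sampler building blocks, summaries, diagnostics, and cross-route agreement."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import arviz as az

from relapse_frailty.data import GapRecord, RecurrentEventDataset
from relapse_frailty.inference import (
    MCMCConfig,
    PosteriorDraws,
    PriorSpec,
    diagnostics,
    gibbs_update_frailties,
    mh_update_block,
    recover,
    run_mcmc,
    run_mcmc_marginal,
    summarize,
    update_theta,
)
from relapse_frailty.model import FrailtyVector, ModelParams
from relapse_frailty.simulate import GeneratorConfig, default_truth, simulate_cohort
from .conftest import make_covariates


def params(theta=0.5, gamma=1.0, alpha=1.0, beta=None, intercept=0.0):
    return ModelParams(
        beta=np.zeros(6) if beta is None else beta,
        gamma=gamma, alpha=alpha, theta=theta, intercept=intercept,
    )


def replicated_subject_dataset(n, gaps_events):
    """n identical subjects, each with the given (gap, event) sequence."""
    records, covs = [], {}
    for i in range(n):
        sid = f"S{i:06d}"
        covs[sid] = make_covariates(age=1.0, gender=0, marital=0, mode=0, head=0, fam=0)
        for k, (t, ev) in enumerate(gaps_events, start=1):
            records.append(GapRecord(sid, k, t, ev))
    return RecurrentEventDataset(records=records, covariates=covs)


class TestFrailtyGibbs:
    def test_draws_match_conjugate_gamma(self, rng):
        # β=0, γ=α=1 ⇒ B=t: three events (Σt=2.0) + censored 0.5 ⇒ d=3, ΣB=2.5
        ds = replicated_subject_dataset(100_000, [(0.5, 1), (0.7, 1), (0.8, 1), (0.5, 0)])
        fr = gibbs_update_frailties(ds, params(theta=0.5), rng)
        draws = np.array(list(fr.nu.values()))
        # full conditional: Gamma(1/θ+d, rate 1/θ+ΣB) = Gamma(5, 4.5)
        p = stats.kstest(draws, "gamma", args=(5.0, 0.0, 1.0 / 4.5)).pvalue
        assert p > 0.01

    def test_posterior_mean_monotone_in_event_count(self, rng):
        means = []
        for extra_events in (1, 2, 3):
            gaps = [(0.5, 1)] * extra_events + [(2.5 - 0.5 * extra_events, 0)]
            ds = replicated_subject_dataset(20_000, gaps)
            fr = gibbs_update_frailties(ds, params(theta=0.5), np.random.default_rng(0))
            means.append(np.mean(list(fr.nu.values())))
        assert means[0] < means[1] < means[2]

    def test_theta_zero_returns_unit_frailties(self, toy_ds, rng):
        fr = gibbs_update_frailties(toy_ds, params(theta=0.0), rng)
        assert all(v == 1.0 for v in fr.nu.values())

    def test_prior_recovered_without_events(self, rng):
        # degenerate conditional (d=0, ΣB→0) is the Gamma(1/θ, 1/θ) prior, mean 1
        from relapse_frailty.inference import _gibbs_nu

        draws = _gibbs_nu(rng, 0.5, np.zeros(50_000), np.zeros(50_000))
        assert abs(draws.mean() - 1.0) < 4 * np.sqrt(0.5 / 50_000)


class TestMHBlocks:
    def test_vanishing_proposal_scale_always_accepts(self, toy_ds, rng):
        p = params(theta=0.3)
        fr = FrailtyVector.ones(toy_ds.subject_ids)
        accepted = [
            mh_update_block(p, "beta", toy_ds, fr, PriorSpec(), rng, scale=1e-14)[1]
            for _ in range(200)
        ]
        assert np.mean(accepted) > 0.95

    def test_fixed_seed_gives_identical_trajectory(self, toy_ds):
        def chain(seed):
            rng = np.random.default_rng(seed)
            p = params(theta=0.3)
            fr = FrailtyVector.ones(toy_ds.subject_ids)
            out = []
            for _ in range(50):
                for block in ("beta", "log_gamma", "log_alpha"):
                    p, _ = mh_update_block(p, block, toy_ds, fr, PriorSpec(), rng, scale=0.2)
                out.append(p.to_dict())
            return out

        assert chain(7) == chain(7)

    def test_unknown_block_rejected(self, toy_ds, rng):
        with pytest.raises(ValueError):
            mh_update_block(params(), "theta", toy_ds, FrailtyVector.ones(["A", "B"]),
                            PriorSpec(), rng)


class TestThetaUpdate:
    def _chain(self, frailties, n_iter, rng, start=0.5):
        p = params(theta=start)
        fr = FrailtyVector(frailties)
        ds = RecurrentEventDataset()  # θ's conditional depends on the frailties only
        out = np.empty(n_iter)
        for i in range(n_iter):
            p, _ = update_theta(p, ds, fr, PriorSpec(), rng, scale=0.3)
            out[i] = p.theta
        return out

    def test_unit_frailties_concentrate_theta_near_zero(self, rng):
        fr = {f"S{i}": 1.0 for i in range(500)}
        draws = self._chain(fr, 3000, rng)
        assert np.quantile(draws[500:], 0.9) < 0.05

    def test_large_sample_consistency_at_study_heterogeneity(self, rng):
        theta0 = 0.206
        nu = rng.gamma(1 / theta0, theta0, size=10_000)
        draws = self._chain({f"S{i}": float(v) for i, v in enumerate(nu)}, 4000, rng, start=0.3)
        post = draws[1000:]
        assert abs(post.mean() - theta0) < max(0.02, 4 * post.std())


class TestRunMCMC:
    def test_deterministic_under_seed_and_subject_order(self):
        ds = simulate_cohort(config=GeneratorConfig(n_subjects=25, seed=2))
        shuffled = RecurrentEventDataset(
            records=list(reversed(ds.records)), covariates=dict(ds.covariates)
        )
        cfg = MCMCConfig(n_chains=2, n_iterations=400, n_burnin=200, seed=9)
        d1 = run_mcmc(ds, config=cfg)
        d2 = run_mcmc(ds, config=cfg)
        d3 = run_mcmc(shuffled, config=cfg)
        pd.testing.assert_frame_equal(d1.draws, d2.draws)
        pd.testing.assert_frame_equal(d1.draws, d3.draws)

    def test_invalid_dataset_rejected_before_sampling(self):
        bad = RecurrentEventDataset(
            records=[GapRecord("A", 1, -1.0, 1)], covariates={"A": make_covariates()}
        )
        from relapse_frailty.data import ValidationError

        with pytest.raises(ValidationError):
            run_mcmc(bad, config=MCMCConfig(n_chains=1, n_iterations=10, n_burnin=1))

    def test_doubled_data_shrinks_beta_sd_by_sqrt2(self):
        # duplicating the cohort (fresh subject ids) doubles the likelihood
        # information exactly, so posterior sds shrink by ≈ 1/√2
        ds = simulate_cohort(config=GeneratorConfig(n_subjects=80, seed=5))
        records = list(ds.records) + [
            GapRecord("R" + r.subject_id, r.rank, r.gap_time, r.event) for r in ds.records
        ]
        covs = dict(ds.covariates)
        covs.update({"R" + s: v for s, v in ds.covariates.items()})
        doubled = RecurrentEventDataset(records=records, covariates=covs)
        cfg = MCMCConfig(n_chains=2, n_iterations=3000, n_burnin=1000, seed=3)
        sd1 = summarize(run_mcmc(ds, config=cfg)).table["sd"]
        sd2 = summarize(run_mcmc(doubled, config=cfg)).table["sd"]
        ratios = (sd2 / sd1)[[f"beta.{c}" for c in
                              ("age_onset", "gender", "marital", "mode_onset")]]
        assert np.all(np.abs(ratios * np.sqrt(2) - 1) < 0.2)

    def test_row_count_matches_design(self):
        ds = simulate_cohort(config=GeneratorConfig(n_subjects=15, seed=4))
        cfg = MCMCConfig(n_chains=3, n_iterations=300, n_burnin=100, thin=2, seed=1)
        draws = run_mcmc(ds, config=cfg)
        assert draws.n_draws == 3 * (300 - 100) // 2
        assert (draws.draws[["gamma", "alpha"]] > 0).all().all()
        assert (draws.draws["theta"] >= 0).all()


class TestSummarize:
    def _draws_from(self, x):
        df = pd.DataFrame({"chain": 0, "iteration": np.arange(len(x)), "gamma": x})
        return PosteriorDraws(df, ["gamma"], pd.DataFrame(), MCMCConfig(seed=0))

    def test_constant_draws(self):
        s = summarize(self._draws_from(np.full(500, 3.3))).table.loc["gamma"]
        assert s["mean"] == pytest.approx(3.3) and s["sd"] == pytest.approx(0.0, abs=1e-12)
        assert s["ci_2.5%"] == s["ci_97.5%"] == 3.3

    def test_normal_quantiles(self, rng):
        x = rng.standard_normal(100_000)
        s = summarize(self._draws_from(x)).table.loc["gamma"]
        assert s["ci_2.5%"] == pytest.approx(-1.96, abs=0.02)
        assert s["ci_97.5%"] == pytest.approx(1.96, abs=0.02)

    def test_interval_excluding_null_is_significant(self, rng):
        # mimics a reported gender interval of (0.146, 0.686): excludes 0
        x = rng.normal(0.418, 0.137, 50_000)
        df = pd.DataFrame({"chain": 0, "iteration": np.arange(len(x)), "beta.gender": x})
        s = summarize(PosteriorDraws(df, ["beta.gender"], pd.DataFrame(), MCMCConfig(seed=0)))
        assert bool(s.table.loc["beta.gender", "significant"])

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValueError):
            summarize(self._draws_from(np.ones(50)))


class TestDiagnostics:
    def _two_chain_draws(self, x0, x1):
        n = len(x0)
        df = pd.DataFrame(
            {
                "chain": np.repeat([0, 1], n),
                "iteration": np.tile(np.arange(n), 2),
                "gamma": np.concatenate([x0, x1]),
            }
        )
        return PosteriorDraws(df, ["gamma"], pd.DataFrame(), MCMCConfig(seed=0))

    def test_iid_chains_have_unit_rhat_and_full_ess(self, rng):
        x = rng.standard_normal((2, 4000))
        d = diagnostics(self._two_chain_draws(x[0], x[1]))
        assert abs(d.loc["gamma", "rhat"] - 1.0) < 0.01
        assert abs(d.loc["gamma", "ess"] - 8000) < 0.2 * 8000

    def test_disjoint_chains_flagged(self, rng):
        d = diagnostics(
            self._two_chain_draws(rng.normal(0, 1, 1000), rng.normal(10, 1, 1000))
        )
        assert d.loc["gamma", "rhat"] > 1.1
        assert "rhat" in d.loc["gamma", "flag"]

    def test_single_chain_omits_rhat(self, rng):
        x = rng.standard_normal(1000)
        df = pd.DataFrame({"chain": 0, "iteration": np.arange(1000), "gamma": x})
        d = diagnostics(PosteriorDraws(df, ["gamma"], pd.DataFrame(), MCMCConfig(seed=0)))
        assert np.isnan(d.loc["gamma", "rhat"])


class TestCrossRouteAgreement:
    def test_gibbs_and_marginal_samplers_agree(self):
        """The latent-frailty Gibbs route and the analytically marginalized
        route target the same posterior; their means must agree within
        Monte-Carlo error on a 50-subject cohort."""
        ds = simulate_cohort(config=GeneratorConfig(n_subjects=50, seed=3))
        cfg = MCMCConfig(n_chains=2, n_iterations=4000, n_burnin=1500, seed=5)
        d1 = run_mcmc(ds, config=cfg)
        d2 = run_mcmc_marginal(ds, config=cfg)
        for n in d1.param_names:
            x1, x2 = d1.draws[n].to_numpy(), d2.draws[n].to_numpy()
            a1 = d1.to_array()[:, :, d1.param_names.index(n)]
            a2 = d2.to_array()[:, :, d2.param_names.index(n)]
            e1 = float(az.ess(az.convert_to_dataset({n: a1}))[n].values)
            e2 = float(az.ess(az.convert_to_dataset({n: a2}))[n].values)
            mcse = np.hypot(x1.std() / np.sqrt(e1), x2.std() / np.sqrt(e2))
            tol = 4 * mcse + 0.05 * max(x1.std(), x2.std())
            assert abs(x1.mean() - x2.mean()) < tol, n


class TestRecover:
    def test_report_schema_and_theta_zero_truth(self):
        truth = ModelParams(np.zeros(6), 1.0, 1.5, 0.0, intercept=np.log(1 / 20))
        cfg = MCMCConfig(n_chains=2, n_iterations=1500, n_burnin=500)
        rep = recover(truth, n=60, config=cfg, seed=4)
        assert set(rep.table.columns) >= {"truth", "mean", "sd", "abs_error", "covered"}
        assert len(rep.table) == 9
        # no heterogeneity in truth: posterior θ concentrated near zero
        assert rep.table.loc["theta", "mean"] < 0.15
        assert rep.table.loc["theta", "ci_2.5%"] < 0.02
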