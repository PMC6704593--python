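import numpy as np
import pytest
from scipy import stats

from anaerodyn import HierarchicalGrowthModel, build_deltas, density_series
from anaerodyn.deltas import DeltaObservation
from anaerodyn.io import EMPIRICAL_LABELS, PROPHYLACTIC_LABELS
from anaerodyn.model import (FIXED_LABELS, PosteriorDraws, build_design,
                             log_likelihood, summarize)

from conftest import FAST_SAMPLER, make_point_posterior


def _obs(pid="p1", t0=0, t1=1, y=0.0, nss=0.1, p1=0, p2=0, emp=(), pro=()):
    return DeltaObservation(
        patient_id=pid, t_start=t0, t_end=t1, y=y, n_start_scaled=nss,
        phase1=p1, phase2=p2,
        empirical=tuple(int(lbl in emp) for lbl in EMPIRICAL_LABELS),
        prophylactic=tuple(int(lbl in pro) for lbl in PROPHYLACTIC_LABELS))


class TestBuildDesign:
    def test_two_toy_rows_match_hand_written_matrix(self):
        obs = [
            _obs("a", 0, 1, y=-1.0, nss=0.5, p2=1,
                 emp=("meropenem",), pro=("fluoroquinolones",)),
            _obs("b", -3, -2, y=0.2, nss=0.9, p1=1),
        ]
        d = build_design(obs)
        mero = FIXED_LABELS.index("meropenem")
        row0 = np.zeros(10); row0[0] = 1; row0[2] = 1; row0[mero] = 1
        row1 = np.zeros(10); row1[0] = 1; row1[1] = 1
        assert np.array_equal(d.x_fixed, np.vstack([row0, row1]))
        assert np.array_equal(d.o_mat[:, 0], [1, 0])
        assert np.allclose(d.n_scaled, [0.5, 0.9])
        assert d.patient_ids == ("a", "b")
        assert np.array_equal(d.patient_idx, [0, 1])
        assert np.allclose(d.y, [-1.0, 0.2])

    def test_unexposed_covariates_are_flagged(self):
        d = build_design([_obs(emp=("meropenem",)), _obs()])
        assert "piperacillin-tazobactam" in d.flagged
        assert "fluoroquinolones" in d.flagged
        assert "meropenem" not in d.flagged

    def test_single_patient_has_one_grouping_level(self):
        d = build_design([_obs(), _obs(t0=1, t1=2)])
        assert d.n_patients == 1


class TestLikelihoodOracle:
    def test_matches_hand_coded_gaussian_at_random_points(self, default_deltas):
        """Model log-density vs an independent Gaussian log-likelihood."""
        design = build_design(default_deltas)
        rng = np.random.default_rng(42)
        for _ in range(50):
            params = {
                "r": rng.normal(), "phase1": rng.normal(),
                "phase2": rng.normal(), "beta_a": rng.normal(size=7),
                "beta_o": rng.normal(scale=0.3),
                "o_dev": rng.normal(scale=0.3, size=4),
                "patient_intercept": rng.normal(
                    scale=0.3, size=design.n_patients),
                "beta_c": rng.normal(scale=0.3),
                "sigma_m": float(rng.uniform(0.2, 2.0)),
            }
            # independent oracle: per-observation normal logpdf, looped
            mu = []
            for j in range(design.n_obs):
                m = (params["r"]
                     + params["phase1"] * design.x_fixed[j, 1]
                     + params["phase2"] * design.x_fixed[j, 2]
                     + float(design.x_fixed[j, 3:] @ params["beta_a"])
                     + float(design.o_mat[j] @ (params["beta_o"]
                                                + params["o_dev"]))
                     + params["patient_intercept"][design.patient_idx[j]]
                     + params["beta_c"] * design.n_scaled[j])
                mu.append(m)
            oracle = float(np.sum(stats.norm.logpdf(
                design.y, loc=mu, scale=params["sigma_m"])))
            assert log_likelihood(design, params) == pytest.approx(
                oracle, abs=1e-8)


class TestSummarize:
    def test_point_mass_draws_collapse_to_the_point(self):
        post = make_point_posterior(n_draws=200, r=0.7)
        s = summarize(post).set_index("parameter")
        assert s.loc["r", "mean"] == pytest.approx(0.7)
        assert s.loc["r", "lo_2.5"] == pytest.approx(0.7)
        assert s.loc["r", "hi_97.5"] == pytest.approx(0.7)

    def test_standard_normal_draws_recover_196_interval(self):
        rng = np.random.default_rng(3)
        post = make_point_posterior(n_draws=10)
        post.params["r"] = rng.standard_normal((3, 10_000))
        s = summarize(post).set_index("parameter")
        assert s.loc["r", "lo_2.5"] == pytest.approx(-1.96, abs=0.05)
        assert s.loc["r", "hi_97.5"] == pytest.approx(1.96, abs=0.05)

    def test_prophylactic_drugs_reported_as_pooled_plus_deviation(self):
        post = make_point_posterior(
            n_draws=100, prophylactic_pooled=-0.2,
            **{"o_dev[fluoroquinolones]": 0.05})
        s = summarize(post).set_index("parameter")
        assert s.loc["fluoroquinolones", "mean"] == pytest.approx(-0.15)

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValueError):
            summarize(make_point_posterior(n_draws=10))


class TestFit:
    def test_prior_returned_when_no_data(self):
        """With no observations the sampler must reproduce the prior."""
        est = HierarchicalGrowthModel(chains=3, draws=9000, warmup=300,
                                      steps=700, seed=5)
        est.fit([])
        r = est.posterior_.flat("r")
        ks = stats.kstest(r, "norm", args=(0.0, 100.0)).statistic
        assert ks < 0.05

    def test_same_seed_reproduces_identical_draws(self, default_deltas):
        kw = dict(chains=2, draws=400, warmup=200, steps=200, seed=9)
        a = HierarchicalGrowthModel(**kw).fit(default_deltas).posterior_
        b = HierarchicalGrowthModel(**kw).fit(default_deltas).posterior_
        for k in a.params:
            assert np.array_equal(a.params[k], b.params[k])

    def test_chain_order_invariance_of_summaries(self, fitted_model):
        post = fitted_model.posterior_
        permuted = PosteriorDraws(
            params={k: v[::-1].copy() for k, v in post.params.items()},
            patient_ids=post.patient_ids)
        a = summarize(post).set_index("parameter")
        b = summarize(permuted).set_index("parameter")
        assert np.allclose(a["mean"], b["mean"])
        assert np.allclose(a["lo_2.5"], b["lo_2.5"])

    def test_duplicating_observations_shrinks_posterior_sd(self, default_deltas):
        kw = dict(seed=11, **FAST_SAMPLER)
        single = HierarchicalGrowthModel(**kw).fit(default_deltas).posterior_
        double = HierarchicalGrowthModel(**kw).fit(
            list(default_deltas) * 2).posterior_
        name = "piperacillin-tazobactam"
        ratio = double.flat(name).std() / single.flat(name).std()
        # information doubles -> sd shrinks roughly by 1/sqrt(2)
        assert 0.5 < ratio < 0.95

    def test_convergence_diagnostics_attached(self, fitted_model):
        finite = {k: v for k, v in fitted_model.rhat_.items()
                  if np.isfinite(v)}
        assert finite
        assert max(finite.values()) < 1.05

    def test_sklearn_param_interface(self):
        est = HierarchicalGrowthModel(draws=123)
        assert est.get_params()["draws"] == 123
        est.set_params(chains=5)
        assert est.chains == 5
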