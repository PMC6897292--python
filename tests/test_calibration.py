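"""Likelihood, Metropolis-Hastings sampler and posterior summaries."""

import math

import numpy as np
import pandas as pd
import pytest

from dinchpbpk import calibration, priors, synth
from dinchpbpk.calibration import CalibrationSpec, PosteriorChain
from dinchpbpk.exceptions import InputError

THETA_TRUE = {
    "FracDOSE": 0.74, "MPY": 38.0, "K1_OH": 0.15, "K1_cx": 0.10,
    "FracMetabOH": 0.23, "FracMetabcx": 0.05,
    "Rurine_A": 0.104, "Creat_A": 1.278,
}


class TestLogLikelihood:
    def test_zero_residuals_unit_sigma(self, volunteer_a_noiseless):
        data, _ = volunteer_a_noiseless
        n_obs = (data.long()["concentration"] > 0).sum()
        ll = calibration.log_likelihood(THETA_TRUE, 1.0, data)
        assert ll == pytest.approx(n_obs * (-0.5 * math.log(2 * math.pi)), rel=1e-9)

    def test_factor_two_residuals(self, volunteer_a_noiseless):
        data, _ = volunteer_a_noiseless
        doubled = data.observations.copy()
        for c in ("conc_OH_mg_per_g_creat", "conc_cx_mg_per_g_creat"):
            doubled[c] *= 2.0
        from dinchpbpk.io import VoidDataset

        data2 = VoidDataset(doubled)
        n_obs = (data2.long()["concentration"] > 0).sum()
        ll = calibration.log_likelihood(THETA_TRUE, 1.0, data2)
        expected = n_obs * (-0.5 * math.log(2 * math.pi) - 0.5 * math.log(2.0) ** 2)
        assert ll == pytest.approx(expected, rel=1e-9)

    def test_large_sigma_limit(self, volunteer_a_noiseless):
        data, _ = volunteer_a_noiseless
        lls = [
            calibration.log_likelihood(THETA_TRUE, s, data)
            for s in (1.0, 10.0, 1e4)
        ]
        assert lls[0] > lls[1] > lls[2]

    def test_sigma_nonpositive_raises(self, volunteer_a_noiseless):
        data, _ = volunteer_a_noiseless
        with pytest.raises(InputError):
            calibration.log_likelihood(THETA_TRUE, 0.0, data)

    def test_loop_and_vectorised_routes_agree(self, volunteer_a_noisy):
        """The sampler's vectorised likelihood equals the per-observation
        reference loop to full precision on random parameter draws."""
        data, _ = volunteer_a_noisy
        fast = calibration._fast_likelihood_factory(data, None, None)
        rng = np.random.default_rng(8)
        for _ in range(5):
            theta = dict(THETA_TRUE)
            theta["MPY"] = rng.uniform(20, 50)
            theta["K1_OH"] = rng.uniform(0.05, 0.5)
            sigma = rng.uniform(0.1, 1.0)
            assert fast(theta, sigma) == pytest.approx(
                calibration.log_likelihood(theta, sigma, data), rel=1e-10
            )

    def test_zero_concentrations_excluded(self, volunteer_a_noisy):
        data, _ = volunteer_a_noisy
        obs = data.observations.copy()
        obs.loc[obs.index[-1], "conc_cx_mg_per_g_creat"] = 0.0
        from dinchpbpk.io import VoidDataset

        trimmed, n_zero = calibration._observation_arrays(VoidDataset(obs))
        assert n_zero == 1
        assert (trimmed["concentration"] > 0).all()


def _gaussian_spec(names_means_sds):
    marg = {
        nm: priors.normal(nm, mu, sd, positive=False)
        for nm, mu, sd in names_means_sds
    }
    return CalibrationSpec(prior=priors.PriorSpec(marginals=marg), n_burn=2000,
                           n_iter=50000, thin=1)


class TestMetropolisHastings:
    def test_recovers_known_gaussian(self):
        """Bypassing the kinetic model, the sampler reproduces a known
        one-dimensional Gaussian target within Monte-Carlo error."""
        spec = _gaussian_spec([("mu", 1.0, 0.5)])

        def target(theta):
            z = (theta["mu"] - 1.0) / 0.5
            s = theta["sigma"]
            if s <= 0:
                return -math.inf
            zs = (s - 2.0) / 0.3
            return -0.5 * (z * z + zs * zs)

        chain = calibration.metropolis_hastings(
            spec, data=None, seed=5, log_target=target
        )
        draws = chain.draws["mu"].to_numpy()
        n_eff = len(draws) / 20  # generous autocorrelation allowance
        mc_se = 0.5 / math.sqrt(n_eff)
        assert draws.mean() == pytest.approx(1.0, abs=3 * mc_se)
        assert draws.std() == pytest.approx(0.5, rel=0.1)
        assert chain.draws["sigma"].mean() == pytest.approx(2.0, abs=0.05)

    def test_2d_gaussian_covariance(self):
        """Detailed-balance smoke test: empirical covariance of a correlated
        2-D Gaussian target matches the truth within 5%."""
        cov = np.array([[1.0, 0.5], [0.5, 1.0]])
        prec = np.linalg.inv(cov)
        spec = _gaussian_spec([("a", 0.0, 1.0), ("b", 0.0, 1.0)])
        spec = CalibrationSpec(prior=spec.prior, n_burn=5000, n_iter=100000, thin=1)

        def target(theta):
            if theta["sigma"] <= 0:
                return -math.inf
            v = np.array([theta["a"], theta["b"]])
            return float(-0.5 * v @ prec @ v - 0.5 * (theta["sigma"] - 1.0) ** 2 / 0.04)

        chain = calibration.metropolis_hastings(
            spec, data=None, seed=11, log_target=target
        )
        emp = np.cov(chain.draws[["a", "b"]].to_numpy().T)
        assert np.abs(emp - cov).max() < 0.05 * 1.0 + 0.05

    def test_acceptance_rate_in_adapted_window(self):
        spec = _gaussian_spec([("mu", 0.0, 1.0)])
        spec = CalibrationSpec(prior=spec.prior, n_burn=2000, n_iter=20000, thin=1)

        def target(theta):
            if theta["sigma"] <= 0:
                return -math.inf
            return -0.5 * theta["mu"] ** 2 - 0.5 * (theta["sigma"] - 1.0) ** 2

        chain = calibration.metropolis_hastings(
            spec, data=None, seed=2, log_target=target
        )
        assert 0.1 < chain.acceptance_rate < 0.5

    def test_degenerate_prior_concentrates_posterior(self, volunteer_a_noisy):
        """A near-point-mass prior pins its parameter at the prior mean."""
        data, _ = volunteer_a_noisy
        prior = priors.prior_set("table4_fixed_dose", volunteers=("A",))
        tight = dict(prior.marginals)
        tight["MPY"] = priors.normal("MPY", 34.0, 1e-4)
        spec = CalibrationSpec(
            prior=priors.PriorSpec(
                marginals=tight, mvn_pairs=prior.mvn_pairs
            ),
            n_burn=200, n_iter=600, thin=2,
        )
        chain = calibration.metropolis_hastings(spec, data, seed=3)
        assert chain.draws["MPY"].std() < 0.01
        assert chain.draws["MPY"].mean() == pytest.approx(34.0, abs=0.005)

    def test_draws_respect_uniform_supports(self, volunteer_a_noisy):
        data, _ = volunteer_a_noisy
        prior = priors.prior_set("table4_fixed_dose", volunteers=("A",))
        spec = CalibrationSpec(prior=prior, n_burn=200, n_iter=800, thin=2)
        chain = calibration.metropolis_hastings(spec, data, seed=4)
        assert chain.draws["FracDOSE"].between(0.0, 1.0).all()
        assert chain.draws["K1_OH"].between(0.05, 2.0).all()
        assert (chain.draws["sigma"] > 0.0).all()

    def test_seed_reproducibility(self, volunteer_a_noisy):
        data, _ = volunteer_a_noisy
        prior = priors.prior_set("table4_fixed_dose", volunteers=("A",))
        spec = CalibrationSpec(prior=prior, n_burn=50, n_iter=200, thin=2)
        a = calibration.metropolis_hastings(spec, data, seed=9)
        b = calibration.metropolis_hastings(spec, data, seed=9)
        pd.testing.assert_frame_equal(a.draws, b.draws)


class TestPosteriorSummary:
    def test_constant_chain(self):
        chain = PosteriorChain(
            draws=pd.DataFrame({"a": [2.0] * 200}), acceptance_rate=0.3,
            n_burn=0, thin=1, seed=0,
        )
        s = calibration.posterior_summary(chain)
        assert s.loc["a", "median"] == 2.0
        assert s.loc["a", "ci5"] == s.loc["a", "ci95"] == 2.0

    def test_uniform_pseudo_chain_order_statistics(self):
        rng = np.random.default_rng(0)
        chain = PosteriorChain(
            draws=pd.DataFrame({"u": rng.uniform(0, 1, 100_000)}),
            acceptance_rate=1.0, n_burn=0, thin=1, seed=0,
        )
        s = calibration.posterior_summary(chain)
        assert s.loc["u", "ci5"] == pytest.approx(0.05, abs=0.01)
        assert s.loc["u", "ci95"] == pytest.approx(0.95, abs=0.01)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=1000)
        a = PosteriorChain(pd.DataFrame({"x": x}), 0.3, 0, 1, 0)
        b = PosteriorChain(pd.DataFrame({"x": rng.permutation(x)}), 0.3, 0, 1, 0)
        pd.testing.assert_frame_equal(
            calibration.posterior_summary(a), calibration.posterior_summary(b)
        )

    def test_empty_chain_raises(self):
        chain = PosteriorChain(pd.DataFrame(), 0.0, 0, 1, 0)
        with pytest.raises(InputError):
            calibration.posterior_summary(chain)


class TestPredictiveBand:
    def test_single_draw_band_collapses(self, volunteer_a_noiseless):
        data, _ = volunteer_a_noiseless
        chain = PosteriorChain(
            draws=pd.DataFrame([{**THETA_TRUE, "sigma": 0.28}]),
            acceptance_rate=1.0, n_burn=0, thin=1, seed=0,
        )
        band = calibration.predictive_band(chain, data)
        assert band["q5"].to_numpy() == pytest.approx(band["q95"].to_numpy())
        # with the ground-truth draw the band median equals the noiseless data
        oh = band[band["metabolite"] == "OH"].sort_values("time_h")
        obs = data.observations.sort_values("time_h")
        assert oh["q50"].to_numpy() == pytest.approx(
            obs["conc_OH_mg_per_g_creat"].to_numpy(), rel=1e-9
        )


class TestReverseDosimetry:
    def test_requires_free_dose(self, volunteer_a_noisy):
        data, _ = volunteer_a_noisy
        prior = priors.prior_set("table4_fixed_dose", volunteers=("A",))
        spec = CalibrationSpec(prior=prior, n_burn=10, n_iter=20, thin=1)
        with pytest.raises(InputError):
            calibration.reverse_dosimetry(spec, data, seed=0)

    def test_fixed_dose_chain_has_no_dose_column(self, volunteer_a_noisy):
        data, _ = volunteer_a_noisy
        prior = priors.prior_set("table4_fixed_dose", volunteers=("A",))
        spec = CalibrationSpec(prior=prior, n_burn=50, n_iter=100, thin=2)
        chain = calibration.metropolis_hastings(spec, data, seed=1)
        assert "PORALDOSE" not in chain.draws.columns
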