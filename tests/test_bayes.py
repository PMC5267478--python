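"""Inference tests: prior, likelihood oracles, sampler behavior, PPDs."""

import numpy as np
import pytest
from scipy import stats

from mapkqb.bayes import (Dataset, PosteriorSample, _delta_sd, log_posterior,
                          log_prior, loglik_grc, loglik_timecourse,
                          mcmc_sample, posterior_predict)
from mapkqb.model import Condition, ParamVec, normalize, simulate
from mapkqb.mra import simulated_grc
from mapkqb.synth import DesignSpec, generate_dataset, load_fixture

from conftest import search_box_draws

_LOGNORM_CONST = -0.5 * np.log(2.0 * np.pi) - np.log(0.2)


class TestLogPrior:
    def test_outside_support_is_minus_inf(self):
        good = search_box_draws(50, 1)[0]
        assert log_prior(good) == 0.0
        assert log_prior(ParamVec.from_dict({**good.to_dict(), "k1p": 1e5})) == -np.inf
        assert log_prior(ParamVec.from_dict({**good.to_dict(), "K": 0.1})) == -np.inf
        assert log_prior(ParamVec.from_dict({**good.to_dict(), "g": 9.0})) == -np.inf

    def test_flat_on_log_scale_inside_support(self):
        a = search_box_draws(51, 1)[0]
        b = ParamVec.from_dict({**a.to_dict(), "k2m": a.k2m * 13.7})
        assert log_prior(a) == log_prior(b)


def _noiseless_dataset(theta, times=(2.0, 5.0, 15.0, 60.0)):
    design = DesignSpec(theta_star=theta, times=times, sigma_log=1e-12,
                        seed=0)
    ds = generate_dataset(design)
    return Dataset(timecourse=ds.timecourse, grc=ds.grc, sigma_log=0.2)


class TestLoglikTimecourse:
    def test_zero_residual_attains_mode_density(self, theta_Q):
        ds = _noiseless_dataset(theta_Q)
        n = len(ds.timecourse)
        expected = n * _LOGNORM_CONST
        assert loglik_timecourse(theta_Q, ds) == pytest.approx(expected, abs=1e-4)

    def test_one_sigma_shift_costs_half(self, theta_Q):
        ds = _noiseless_dataset(theta_Q)
        base = loglik_timecourse(theta_Q, ds)
        bumped = ds.timecourse.copy()
        bumped.loc[bumped.index[0], "value"] *= np.exp(0.2)
        ds2 = Dataset(timecourse=bumped, grc=ds.grc, sigma_log=0.2)
        assert loglik_timecourse(theta_Q, ds2) == pytest.approx(base - 0.5,
                                                                abs=1e-4)

    def test_matches_normal_on_logs_oracle(self, theta_Q, dataset):
        """Brute-force normal density on log-transformed values, point by point."""
        total = 0.0
        for gf, block in dataset.timecourse.groupby("growth_factor"):
            cond = Condition.for_growth_factor(gf)
            t_grid = np.unique(np.concatenate(
                [block["time_min"].to_numpy(), [5.0]]))
            z = normalize(simulate(theta_Q, cond, t_grid), 5.0)
            for _, row in block.iterrows():
                i_t = int(np.where(t_grid == row["time_min"])[0][0])
                i_sp = {"pRaf": 0, "ppMEK": 1, "ppERK": 2}[row["species"]]
                total += stats.norm.logpdf(np.log(row["value"]),
                                           np.log(z[i_t, i_sp]), 0.2)
        got = loglik_timecourse(theta_Q, dataset, ode_tol=(1e-8, 1e-10))
        assert got == pytest.approx(total, abs=1e-6)


class TestLoglikGRC:
    def test_exact_match_beats_perturbed_parameters(self, theta_Q):
        ds = _noiseless_dataset(theta_Q)
        base = loglik_grc(theta_Q, ds)
        for name in ("k2p", "kFp", "k3m"):
            worse = loglik_grc(theta_Q.scaled(name, 3.0), ds)
            assert worse <= base + 1e-9

    def test_doubling_sd_halves_quadratic_term(self, theta_Q):
        ds = _noiseless_dataset(theta_Q)
        # shift one observed cell by delta so the quadratic term is nonzero
        grc = ds.grc.copy()
        i = grc.index[0]
        sd0 = 0.1
        delta = 0.2
        grc.loc[i, "R_mean"] += delta
        grc.loc[:, "R_sd"] = sd0
        a = loglik_grc(theta_Q, Dataset(ds.timecourse, grc, 0.2))
        grc2 = grc.copy()
        grc2.loc[i, "R_sd"] = 2 * sd0
        b = loglik_grc(theta_Q, Dataset(ds.timecourse, grc2, 0.2))
        # only that cell changed: quadratic part shrinks by 3/4 delta^2/(2 sd0^2),
        # and the normalization of that one cell pays log(2)
        quad = 0.5 * (delta / sd0) ** 2
        assert b - a == pytest.approx(0.75 * quad - np.log(2.0), abs=1e-6)

    def test_delta_sd_matches_monte_carlo_transformation(self):
        """Delta-method sd of R agrees with a simulated transformation."""
        rng = np.random.default_rng(60)
        for sigma in (0.1, 0.2, 0.3):
            rho_true = 1.4
            v_c = 0.8
            n = 400_000
            vs = rho_true * v_c * np.exp(sigma * rng.standard_normal(n))
            vc = v_c * np.exp(sigma * rng.standard_normal(n))
            R = 2.0 * (vs - vc) / (vs + vc)
            R_sim = 2.0 * (rho_true - 1.0) / (rho_true + 1.0)
            sd = _delta_sd(R_sim, sigma, 1)
            # first-order approximation: within 0.02 up to sigma = 0.3
            assert sd == pytest.approx(R.std(), abs=2e-2)


class TestLogPosterior:
    def test_additivity_and_support(self, dataset):
        for th in search_box_draws(52, 10):
            lp = log_posterior(th, dataset)
            parts = (log_prior(th) + loglik_timecourse(th, dataset)
                     + loglik_grc(th, dataset))
            if np.isfinite(lp):
                assert lp == pytest.approx(parts, abs=1e-9)
        bad = ParamVec.from_dict({**search_box_draws(53, 1)[0].to_dict(),
                                  "K": 1000.0})
        assert log_posterior(bad, dataset) == -np.inf

    def test_invariant_to_data_block_order(self, theta_Q, dataset):
        shuffled = Dataset(
            timecourse=dataset.timecourse.sample(frac=1.0, random_state=1),
            grc=dataset.grc.sample(frac=1.0, random_state=2),
            sigma_log=dataset.sigma_log)
        assert log_posterior(theta_Q, shuffled) == pytest.approx(
            log_posterior(theta_Q, dataset), abs=1e-9)


class TestSampler:
    def test_gaussian_target_sanity(self):
        """The adaptive walk recovers a known isotropic Gaussian target."""
        from mapkqb.bayes import adaptive_metropolis

        mu = np.array([1.0, -0.5, 2.0, 0.0])

        def log_target(eta):
            return -0.5 * float(np.sum((eta - mu) ** 2))

        chain, lps, acc = adaptive_metropolis(
            log_target, np.zeros(4), 50_000, np.random.default_rng(0))
        kept = chain[25_000:]
        np.testing.assert_allclose(kept.mean(axis=0), mu, atol=0.08)
        np.testing.assert_allclose(np.cov(kept.T), np.eye(4), atol=0.15)
        assert 0.1 < acc < 0.6

    def test_same_seed_reproduces_chain(self, dataset):
        a = mcmc_sample(dataset, n_steps=500, seed=9, n_retain=100)
        b = mcmc_sample(dataset, n_steps=500, seed=9, n_retain=100)
        np.testing.assert_array_equal(a.draws, b.draws)
        assert a.acceptance_rate == b.acceptance_rate

    def test_acceptance_rate_and_metadata(self, chains):
        for seed, sample in chains.items():
            assert 0.1 < sample.acceptance_rate < 0.6
            assert sample.meta["seed"] == seed
            assert np.all(np.isfinite(sample.log_post))
            assert len(sample) >= 500

    def test_target_constant_shift_invariance(self):
        """Adding a constant to the log target leaves the walk unchanged."""
        from mapkqb.bayes import adaptive_metropolis

        def target(eta):
            return -0.5 * float(eta @ eta)

        a, _, _ = adaptive_metropolis(target, np.ones(3), 2000,
                                      np.random.default_rng(7))
        b, _, _ = adaptive_metropolis(lambda e: target(e) + 123.4, np.ones(3),
                                      2000, np.random.default_rng(7))
        np.testing.assert_array_equal(a, b)

    def test_kfp_k1p_correlation_logged(self, posterior):
        """Positive rank correlation between feedback and input strength (logged)."""
        j_kfp = list(posterior.to_frame().columns).index("kFp") - 1
        j_k1p = list(posterior.to_frame().columns).index("k1p") - 1
        rho = stats.spearmanr(posterior.draws[:, j_kfp],
                              posterior.draws[:, j_k1p]).statistic
        print(f"spearman(kFp, k1p) = {rho:.3f}")


class TestPosteriorPredict:
    def test_degenerate_posterior_band_is_noise_band(self, theta_Q):
        n = 400
        sample = PosteriorSample(draws=np.tile(theta_Q.to_array(), (n, 1)),
                                 log_post=np.zeros(n), acceptance_rate=0.3)
        t = np.array([15.0, 60.0])
        band, n_failed = posterior_predict(sample, Condition.ngf_control(), t,
                                           sigma_log=0.2, seed=1)
        assert n_failed == 0
        z = normalize(simulate(theta_Q, Condition.ngf_control(),
                               np.array([0.0, 5.0, 15.0, 60.0])), 5.0)[:, 2]
        pred = z[2:]
        lo = pred * np.exp(-1.96 * 0.2)
        hi = pred * np.exp(1.96 * 0.2)
        np.testing.assert_allclose(band["q0.025"], lo, rtol=0.15)
        np.testing.assert_allclose(band["q0.975"], hi, rtol=0.15)

    def test_median_tracks_mean_for_symmetric_draws(self, theta_Q):
        n = 500
        sample = PosteriorSample(draws=np.tile(theta_Q.to_array(), (n, 1)),
                                 log_post=np.zeros(n), acceptance_rate=0.3)
        t = np.array([30.0])
        band, _ = posterior_predict(sample, Condition.ngf_control(), t,
                                    quantiles=(0.5,), sigma_log=0.05, seed=2)
        assert band["q0.5"].iloc[0] == pytest.approx(band["mean"].iloc[0],
                                                     rel=0.02)

    def test_ppd_covers_synthetic_data(self, posterior, dataset):
        """Calibration-scenario PPDs cover the data they were fitted to."""
        n_inside = 0
        n_total = 0
        for gf, block in dataset.timecourse.groupby("growth_factor"):
            for sp, sub in block.groupby("species"):
                t = np.sort(sub["time_min"].unique())
                band, _ = posterior_predict(posterior,
                                            Condition.for_growth_factor(gf),
                                            t, species=sp, seed=3)
                for _, row in sub.iterrows():
                    r = band[band["time_min"] == row["time_min"]].iloc[0]
                    n_total += 1
                    n_inside += bool(r["q0.025"] <= row["value"] <= r["q0.975"])
        assert n_total == len(dataset.timecourse)
        assert n_inside / n_total >= 0.9


class TestDatasetIO:
    def test_round_trip(self, dataset, tmp_path):
        dataset.save(tmp_path / "ds")
        back = Dataset.load(tmp_path / "ds")
        assert back.sigma_log == dataset.sigma_log
        assert len(back.timecourse) == len(dataset.timecourse)
        assert len(back.grc) == len(dataset.grc)

    def test_posterior_round_trip(self, tmp_path, theta_M):
        sample = PosteriorSample(draws=np.tile(theta_M.to_array(), (3, 1)),
                                 log_post=np.arange(3.0), acceptance_rate=0.25,
                                 meta={"seed": 0})
        sample.save(tmp_path / "fit")
        back = PosteriorSample.load(tmp_path / "fit")
        np.testing.assert_allclose(back.draws, sample.draws)
        assert back.acceptance_rate == 0.25
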