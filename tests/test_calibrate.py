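"""Likelihood algebra, Metropolis sampler behavior, and chain diagnostics."""

import dataclasses

import numpy as np
import pytest

from mousemetab import (
    ModelParameters,
    ObservationSet,
    PosteriorSample,
    geweke_z,
    log_posterior,
    predict_EE_interval,
    run_metropolis,
)
from mousemetab.calibrate import DEFAULT_THETA, THETA_NAMES
from mousemetab.synth import generate_study, recovery_protocols

TRUTH = np.array([2.1, 0.22, 0.27, 0.19, 0.13])


def _quiet_protocols():
    """Single chow/HF/chow arm with negligible intake noise."""
    proto = recovery_protocols()[2]  # the 'hfc' arm informs all parameters
    return (dataclasses.replace(proto, ei_se=1e-6),)


@pytest.fixture(scope="module")
def noise_free_obs():
    study = generate_study(_quiet_protocols(), seed=0, bw_se=0.0, fm_se=0.0)
    obs = study.observation_sets()[0]
    # likelihood SEs must be positive; use realistic ones on exact data
    obs.BW_se[:] = 0.5
    obs.FM_se[:] = 0.4
    return obs


@pytest.fixture(scope="module")
def small_fit():
    study = generate_study(recovery_protocols()[2:], seed=42)
    sample, diag = run_metropolis(
        study.observation_sets(), n_iter=6000, burn_in=2000, thin=5, seed=7
    )
    return sample, diag


class TestLogPosterior:
    def test_truth_maximizes_on_grid(self, noise_free_obs):
        """On noise-free data each parameter's 1-d profile through the true
        point peaks at the true value (grid oracle)."""
        for i in range(5):
            grid = TRUTH[i] * np.linspace(0.8, 1.2, 9)
            vals = []
            for g in grid:
                theta = TRUTH.copy()
                theta[i] = g
                vals.append(log_posterior(theta, noise_free_obs))
            assert np.argmax(vals) == 4  # center of the grid = truth

    def test_doubled_residuals_quadruple_the_deficit(self, noise_free_obs):
        lp0 = log_posterior(TRUTH, noise_free_obs)
        shifted = []
        for k in (1, 2):
            obs = dataclasses.replace(
                noise_free_obs,
                BW_mean=noise_free_obs.BW_mean + 0.3 * k,
                FM_mean=noise_free_obs.FM_mean + 0.2 * k,
            )
            shifted.append(log_posterior(TRUTH, obs))
        deficit1 = lp0 - shifted[0]
        deficit2 = lp0 - shifted[1]
        # small tolerance absorbs the (tiny) nonzero residual of the
        # fixed-step forward model at the true parameters
        assert deficit2 == pytest.approx(4.0 * deficit1, rel=1e-3)

    def test_invariant_to_observation_row_order(self, noise_free_obs):
        rng = np.random.default_rng(5)
        perm = rng.permutation(len(noise_free_obs.times))
        shuffled = dataclasses.replace(
            noise_free_obs,
            times=noise_free_obs.times[perm],
            BW_mean=noise_free_obs.BW_mean[perm],
            FM_mean=noise_free_obs.FM_mean[perm],
            BW_se=noise_free_obs.BW_se[perm],
            FM_se=noise_free_obs.FM_se[perm],
        )
        assert log_posterior(TRUTH, shuffled) == log_posterior(TRUTH, noise_free_obs)

    def test_nonpositive_parameters_excluded(self, noise_free_obs):
        theta = TRUTH.copy()
        theta[0] = -1.0
        assert log_posterior(theta, noise_free_obs) == -np.inf


class TestRunMetropolis:
    def test_seeded_chain_is_bit_identical(self, noise_free_obs):
        kw = dict(n_iter=800, burn_in=200, thin=5, seed=123)
        s1, _ = run_metropolis(noise_free_obs, **kw)
        s2, _ = run_metropolis(noise_free_obs, **kw)
        assert np.array_equal(s1.draws, s2.draws)
        assert np.array_equal(s1.log_post, s2.log_post)

    def test_retained_count_bookkeeping(self, small_fit):
        sample, _ = small_fit
        assert sample.draws.shape[0] == (6000 - 2000) // 5

    def test_acceptance_rate_near_target(self, small_fit):
        _, diag = small_fit
        assert 0.15 <= diag.acceptance_rate <= 0.40
        assert 0.0 < diag.acceptance_rate_burnin < 1.0

    def test_collapsed_acceptance_warns(self, noise_free_obs):
        """A proposal frozen at an absurdly large scale accepts almost
        nothing and must trigger the diagnostic warning."""
        with pytest.warns(RuntimeWarning, match="acceptance rate"):
            run_metropolis(
                noise_free_obs, n_iter=400, burn_in=100, thin=5, seed=1,
                init_scale_frac=500.0, adapt_cov=False, adapt_power=10.0,
            )


class TestGeweke:
    def test_iid_chains_rarely_flagged(self):
        flags = 0
        for s in range(100):
            z = geweke_z(np.random.default_rng(s).standard_normal(10_000))
            flags += abs(z) > 3
        assert flags <= 1  # >= 99% of trials unflagged

    def test_linear_drift_detected(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(5000) + np.linspace(0.0, 5.0, 5000)
        assert abs(geweke_z(x)) > 3

    def test_palindromic_chain_symmetry(self):
        rng = np.random.default_rng(1)
        half = rng.standard_normal(2500)
        x = np.concatenate([half, half[::-1]])
        assert geweke_z(x) == geweke_z(x[::-1])

    def test_short_chain_rejected(self):
        with pytest.raises(ValueError):
            geweke_z(np.arange(50.0))

    def test_constant_chain_rejected(self):
        with pytest.raises(ValueError):
            geweke_z(np.full(1000, 3.14))


class TestPredictEEInterval:
    def _posterior_with_ee(self, ee):
        n = ee.shape[0]
        return PosteriorSample(
            param_names=THETA_NAMES,
            draws=np.tile(DEFAULT_THETA, (n, 1)),
            ei_draws=np.zeros((n, 0)),
            log_post=np.zeros(n),
            ee_pred={"g": ee},
            ee_times={"g": np.arange(ee.shape[1], dtype=float)},
            n_iter=n, burn_in=0, thin=1,
        )

    def test_identical_draws_zero_width(self):
        post = self._posterior_with_ee(np.full((150, 4), 12.5))
        _, lo, hi = predict_EE_interval(post)
        assert np.all(lo == hi)

    def test_matches_sort_based_percentiles(self):
        rng = np.random.default_rng(9)
        ee = rng.normal(12.0, 1.0, size=(501, 3))
        _, lo, hi = predict_EE_interval(self._posterior_with_ee(ee))
        srt = np.sort(ee, axis=0)
        # linear-interpolation percentile computed by hand on the sorted draws
        def pct(q):
            pos = q / 100.0 * (ee.shape[0] - 1)
            i = int(np.floor(pos))
            w = pos - i
            return srt[i] * (1 - w) + srt[i + 1] * w
        assert np.allclose(lo, pct(2.5))
        assert np.allclose(hi, pct(97.5))

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValueError):
            predict_EE_interval(self._posterior_with_ee(np.full((50, 4), 12.5)))

    def test_band_widens_with_intake_uncertainty(self):
        """Inflating the intake standard error by 10x propagates into a
        wider posterior EE band."""
        bands = []
        for infl in (1.0, 10.0):
            proto = dataclasses.replace(
                recovery_protocols()[0], ei_se=0.42 * infl
            )
            study = generate_study((proto,), seed=3)
            sample, _ = run_metropolis(
                study.observation_sets(), n_iter=3000, burn_in=1000, thin=5,
                seed=11,
            )
            t, lo, hi = predict_EE_interval(sample, group="ctrl")
            bands.append(np.mean(hi - lo))
        assert bands[1] > 1.5 * bands[0]
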