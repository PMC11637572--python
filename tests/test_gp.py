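import numpy as np
import pytest
from scipy import linalg

from abrgp.gp import (
    Hyperparameters,
    ObservationSet,
    PredictionGrid,
    S_SCALE_UV2,
    fit_hyperparameters,
    log_marginal_likelihood,
    marginal_at,
    posterior,
    prior_cov,
    theta_search_grid,
)


def mvn_conditional_oracle(xp, xt, o, noise_vars, hyper):
    """Condition the joint MVN of [prediction; observation] points directly."""
    joint = np.vstack([xp, xt])
    k = prior_cov(joint, joint, hyper)
    p, t = len(xp), len(xt)
    kpp, kpt = k[:p, :p], k[:p, p:]
    ktt = k[p:, p:] + np.diag(noise_vars) + 1e-9 * hyper.s * np.eye(t)
    sol = np.linalg.solve(ktt, np.eye(t))
    return kpt @ sol @ o, kpp - kpt @ sol @ kpt.T


def obs_from_arrays(xt, o, noise_vars):
    obs = ObservationSet()
    for (lvl, f), val, var in zip(xt, o, noise_vars):
        obs.upsert(lvl, f, val, var)
    return obs


class TestPriorCovariance:
    def test_scale_at_zero_distance(self):
        h = Hyperparameters(theta_db=1000.0, theta_hz=1.0)
        k = prior_cov([[0.0, 1000.0]], [[0.0, 1000.0]], h)[0, 0]
        assert k == pytest.approx((1.25 / 3.09) ** 2)
        assert round(k, 4) == 0.1636

    def test_level_distance_decay(self):
        h = Hyperparameters(theta_db=1000.0, theta_hz=1.0)
        k = prior_cov([[10.0, 1000.0]], [[0.0, 1000.0]], h)[0, 0]
        assert k == pytest.approx(S_SCALE_UV2 * np.exp(-0.01), rel=1e-12)

    def test_log_frequency_distance_decay(self):
        h = Hyperparameters(theta_db=1000.0, theta_hz=1.0)
        k = prior_cov([[0.0, 1000.0]], [[0.0, 2000.0]], h)[0, 0]
        assert k == pytest.approx(S_SCALE_UV2 * np.exp(-np.log(2)), rel=1e-12)

    def test_symmetry(self):
        h = Hyperparameters(theta_db=1500.0, theta_hz=0.3)
        a = prior_cov([[10.0, 500.0]], [[40.0, 4000.0]], h)
        b = prior_cov([[40.0, 4000.0]], [[10.0, 500.0]], h)
        assert a[0, 0] == b[0, 0]

    def test_invalid_theta_rejected(self):
        with pytest.raises(ValueError):
            Hyperparameters(theta_db=-1.0)


class TestPredictionGrid:
    def test_size_and_ordering(self):
        grid = PredictionGrid()
        locs = grid.locations
        assert grid.size == 324 and locs.shape == (324, 2)
        # frequency-major: first 81 rows all 500 Hz, levels ascending
        assert np.all(locs[:81, 1] == 500.0)
        assert np.all(np.diff(locs[:81, 0]) == 1)
        assert locs[0, 0] == -10 and locs[80, 0] == 70
        assert grid.index_of(-10, 500.0) == 0
        assert grid.index_of(70, 4000.0) == 323

    def test_off_grid_lookup_rejected(self):
        with pytest.raises(KeyError):
            PredictionGrid().index_of(5.5, 500.0)


class TestPosterior:
    def test_empty_observations_recover_prior(self):
        grid = PredictionGrid()
        h = Hyperparameters(theta_db=1500.0, theta_hz=0.5)
        post = posterior(ObservationSet(), grid, h)
        assert np.all(post.mean == 0.0)
        np.testing.assert_allclose(post.cov, prior_cov(grid.locations, grid.locations, h))

    def test_noiseless_observation_is_interpolated(self):
        grid = PredictionGrid()
        h = Hyperparameters(theta_db=1500.0, theta_hz=0.5)
        obs = ObservationSet()
        obs.upsert(30.0, 1000.0, 0.5, 1e-12)  # jitter dominates
        post = posterior(obs, grid, h)
        mu, var = post.marginal(30.0, 1000.0)
        assert mu == pytest.approx(0.5, abs=1e-6)
        assert var < 1e-6

    def test_matches_mvn_oracle_on_mini_grid(self):
        rng = np.random.default_rng(0)
        h = Hyperparameters(theta_db=1200.0, theta_hz=0.4)
        grid = PredictionGrid(levels=np.arange(0, 50, 10), frequencies=np.array([500.0, 2000.0]))
        xt = np.array([[10.0, 500.0], [30.0, 2000.0], [40.0, 500.0]])
        o = rng.normal(0.3, 0.1, 3)
        nv = rng.uniform(1e-4, 1e-2, 3)
        post = posterior(obs_from_arrays(xt, o, nv), grid, h)
        mean_o, cov_o = mvn_conditional_oracle(grid.locations, xt, o, nv, h)
        np.testing.assert_allclose(post.mean, mean_o, atol=1e-10)
        np.testing.assert_allclose(post.cov, cov_o, atol=1e-10)

    def test_variance_never_exceeds_prior(self):
        grid = PredictionGrid()
        h = Hyperparameters()
        obs = obs_from_arrays(
            np.array([[70.0, 500.0], [50.0, 4000.0]]), [0.4, 0.2], [1e-3, 1e-3]
        )
        post = posterior(obs, grid, h)
        assert np.all(np.diag(post.cov) <= h.s + 1e-8)

    def test_infinite_noise_recovers_prior(self):
        grid = PredictionGrid()
        h = Hyperparameters()
        obs = obs_from_arrays(np.array([[70.0, 500.0]]), [0.4], [1e6 * h.s])
        post = posterior(obs, grid, h)
        prior = prior_cov(grid.locations, grid.locations, h)
        assert np.max(np.abs(post.mean)) < 1e-3
        assert np.max(np.abs(post.cov - prior)) / h.s < 1e-3

    def test_observation_order_is_exchangeable(self):
        grid = PredictionGrid()
        h = Hyperparameters(theta_db=1300.0, theta_hz=0.2)
        xt = [(70.0, 500.0), (40.0, 1000.0), (20.0, 2000.0)]
        vals = [0.5, 0.3, 0.1]
        nv = [1e-3, 2e-3, 3e-3]
        a = posterior(obs_from_arrays(np.array(xt), vals, nv), grid, h)
        order = [2, 0, 1]
        b = posterior(
            obs_from_arrays(np.array(xt)[order], np.array(vals)[order], np.array(nv)[order]),
            grid,
            h,
        )
        np.testing.assert_allclose(a.mean, b.mean, atol=1e-12)
        np.testing.assert_allclose(a.cov, b.cov, atol=1e-12)

    def test_upsert_replaces_existing_location(self):
        obs = ObservationSet()
        obs.upsert(70.0, 500.0, 0.5, 1e-3)
        obs.upsert(70.0, 500.0, 0.6, 2e-3)
        assert len(obs) == 1
        assert obs.values[0] == 0.6 and obs.noise_vars[0] == 2e-3


class TestMarginal:
    def test_empty_obs_gives_prior_marginal(self):
        h = Hyperparameters()
        assert marginal_at(ObservationSet(), h, 30.0, 1000.0) == (0.0, h.s)

    def test_consistent_with_full_grid_posterior(self):
        grid = PredictionGrid()
        h = Hyperparameters(theta_db=1100.0, theta_hz=0.7)
        obs = obs_from_arrays(np.array([[70.0, 1000.0], [30.0, 500.0]]), [0.4, 0.1], [1e-3, 1e-3])
        post = posterior(obs, grid, h)
        for lvl, f in [(70.0, 1000.0), (-10.0, 4000.0), (25.0, 2000.0)]:
            mu_g, var_g = post.marginal(lvl, f)
            mu_s, var_s = marginal_at(obs, h, lvl, f)
            assert abs(mu_g - mu_s) < 1e-9 and abs(var_g - var_s) < 1e-9

    def test_off_grid_frequency_matches_oracle(self):
        h = Hyperparameters(theta_db=1100.0, theta_hz=0.7)
        xt = np.array([[70.0, 1000.0], [30.0, 500.0]])
        o, nv = np.array([0.4, 0.1]), np.array([1e-3, 1e-3])
        mu, var = marginal_at(obs_from_arrays(xt, o, nv), h, 40.0, 1500.0)
        mean_o, cov_o = mvn_conditional_oracle(np.array([[40.0, 1500.0]]), xt, o, nv, h)
        assert mu == pytest.approx(mean_o[0], abs=1e-10)
        assert var == pytest.approx(cov_o[0, 0], abs=1e-10)


class TestHyperparameterFit:
    def test_bounds_respected_on_random_data(self):
        rng = np.random.default_rng(5)
        xt = np.column_stack([rng.integers(-10, 71, 8), rng.choice([500.0, 1000.0, 2000.0, 4000.0], 8)])
        # de-duplicate locations
        xt = np.unique(xt, axis=0)
        obs = obs_from_arrays(xt, rng.normal(0, 0.3, len(xt)), np.full(len(xt), 1e-3))
        fit = fit_hyperparameters(obs)
        assert 1000.0 <= fit.theta_db <= 2000.0
        assert 0.05 <= fit.theta_hz <= 1.0

    def test_single_observation_tie_breaks_to_upper_bounds(self):
        obs = ObservationSet()
        obs.upsert(70.0, 500.0, 0.5, 1e-3)
        fit = fit_hyperparameters(obs)
        assert (fit.theta_db, fit.theta_hz) == (2000.0, 1.0)

    def test_empty_observation_default(self):
        fit = fit_hyperparameters(ObservationSet())
        assert (fit.theta_db, fit.theta_hz) == (2000.0, 1.0)

    def test_returned_point_maximises_gridded_likelihood(self):
        rng = np.random.default_rng(6)
        xt = np.array([[70.0, 500.0], [40.0, 500.0], [70.0, 2000.0], [10.0, 4000.0]])
        obs = obs_from_arrays(xt, rng.normal(0, 0.3, 4), np.full(4, 1e-3))
        fit = fit_hyperparameters(obs)
        best = log_marginal_likelihood(obs, fit)
        gdb, ghz = theta_search_grid()
        for tdb in gdb:
            for thz in ghz:
                ll = log_marginal_likelihood(obs, Hyperparameters(theta_db=tdb, theta_hz=thz))
                assert ll <= best + 1e-9
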