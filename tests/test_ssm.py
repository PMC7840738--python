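"""Kalman / point-process / multiscale filters and smoothers."""

import numpy as np
import pytest

import msmodes as mm
from msmodes.ssm import _run_filter

from oracles import batch_filtered_mean, batch_gaussian_posterior, \
    pp_single_step_map


def _lgssm_params(T=50, n_x=2, n_y=3, k=5, seed=0):
    rng = np.random.default_rng(seed)
    th = 0.15
    A = 0.95 * np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    W = 0.05 * np.eye(n_x)
    C = np.column_stack([rng.standard_normal(n_y),
                         rng.standard_normal((n_y, n_x))])
    R = np.diag(rng.uniform(0.2, 0.5, n_y))
    tb = mm.TimeBase(dt=0.01, k=k, T=T)
    return mm.ModelParams(A=A, W=W, x0=rng.standard_normal(n_x),
                          Lambda0=0.5 * np.eye(n_x), C=C, R=R,
                          alpha=np.zeros((0, n_x + 1)), timebase=tb,
                          scale_tag="lfp")


class TestKalman:
    def test_filter_matches_batch_posterior(self):
        """Filtered means agree with a causal batch joint-Gaussian solve and
        smoothed means/covariances with the full batch posterior (1e-8)."""
        params = _lgssm_params(T=50)
        rng = np.random.default_rng(42)
        Y = rng.standard_normal((10, 3))
        fr = mm.kalman_filter(Y, params)
        sm = mm.kalman_smoother(fr, params)
        obs_steps = params.timebase.lfp_steps
        mean, margs, lags = batch_gaussian_posterior(
            params.A, params.W, params.x0, params.Lambda0, params.C,
            params.R, Y, obs_steps, 50)
        np.testing.assert_allclose(sm.xs, mean, atol=1e-8)
        np.testing.assert_allclose(sm.Ps, margs, atol=1e-8)
        np.testing.assert_allclose(sm.Plag, lags, atol=1e-8)
        for t in (0, 4, 23, 49):
            xf_t = batch_filtered_mean(params.A, params.W, params.x0,
                                       params.Lambda0, params.C, params.R,
                                       Y, obs_steps, t)
            np.testing.assert_allclose(fr.xf[t], xf_t, atol=1e-8)

    def test_no_observations_is_pure_prediction(self):
        params = _lgssm_params(T=4, k=5)  # T < k: no LFP steps at all
        fr = mm.kalman_filter(np.zeros((0, 3)), params)
        expect = params.x0.copy()
        for t in range(4):
            if t > 0:
                expect = params.A @ expect
            np.testing.assert_allclose(fr.xf[t], expect, atol=1e-12)

    def test_measurement_dominated_limit(self):
        # C = [0 I], tiny R, huge W: the filter trusts the data completely
        n_x = 2
        tb = mm.TimeBase(dt=0.01, k=1, T=20)
        C = np.column_stack([np.zeros(n_x), np.eye(n_x)])
        params = mm.ModelParams(A=0.9 * np.eye(n_x), W=50 * np.eye(n_x),
                                x0=np.zeros(n_x), Lambda0=np.eye(n_x),
                                C=C, R=1e-10 * np.eye(n_x),
                                alpha=np.zeros((0, n_x + 1)), timebase=tb,
                                scale_tag="lfp")
        rng = np.random.default_rng(0)
        Y = rng.standard_normal((20, n_x))
        fr = mm.kalman_filter(Y, params)
        np.testing.assert_allclose(fr.xf, Y, atol=1e-4)

    def test_smoother_boundary_identity(self):
        params = _lgssm_params(T=50)
        Y = np.random.default_rng(3).standard_normal((10, 3))
        fr = mm.kalman_filter(Y, params)
        sm = mm.kalman_smoother(fr, params)
        np.testing.assert_array_equal(sm.xs[-1], fr.xf[-1])
        np.testing.assert_array_equal(sm.Ps[-1], fr.Pf[-1])

    def test_deterministic_dynamics_limit(self):
        """W -> 0: the smoothed trajectory obeys x_{t+1} = A x_t exactly."""
        params = _lgssm_params(T=50)
        params.W = 1e-14 * np.eye(2)
        Y = np.random.default_rng(5).standard_normal((10, 3))
        fr = mm.kalman_filter(Y, params)
        sm = mm.kalman_smoother(fr, params)
        for t in range(49):
            np.testing.assert_allclose(sm.xs[t + 1], params.A @ sm.xs[t],
                                       atol=1e-5)


def _spike_params(n_x=1, n_c=1, T=1, seed=0, alpha=None):
    tb = mm.TimeBase(dt=0.01, k=5, T=T)
    A = 0.98 * np.eye(n_x)
    W = 0.02 * np.eye(n_x)
    if alpha is None:
        alpha = np.column_stack([np.full(n_c, np.log(20.0)),
                                 np.ones((n_c, n_x))])
    return mm.ModelParams(A=A, W=W, x0=np.zeros(n_x),
                          Lambda0=0.3 * np.eye(n_x),
                          C=np.zeros((0, n_x + 1)), R=np.zeros((0, 0)),
                          alpha=alpha, timebase=tb, scale_tag="spike")


class TestPointProcessFilter:
    @pytest.mark.parametrize("n_obs", [0, 1])
    def test_single_step_posterior_matches_map_oracle(self, n_obs):
        """Iterated PPF update equals the 1-D numerical MAP of
        Gaussian-prior x point-process likelihood (1e-6)."""
        params = _spike_params()
        N = np.array([[n_obs]], dtype=float)
        fr = mm.point_process_filter(N, params, pp_iters=8)
        x_map = pp_single_step_map(0.0, 0.3 + 1e-9, (np.log(20.0), 1.0),
                                   n_obs, 0.01)
        assert fr.xf[0, 0] == pytest.approx(x_map, abs=1e-6)

    def test_uninformative_observations_leave_state_untouched(self):
        # alpha state columns all zero: spikes carry no state information
        alpha = np.column_stack([np.full(3, np.log(10.0)), np.zeros((3, 2))])
        params = _spike_params(n_x=2, n_c=3, T=100, alpha=alpha)
        rng = np.random.default_rng(0)
        N = (rng.uniform(size=(100, 3)) < 0.1).astype(float)
        fr = mm.point_process_filter(N, params)
        np.testing.assert_allclose(fr.xf, fr.xp, atol=1e-12)

    def test_filtering_beats_pure_prediction(self, planted_gt):
        """On simulated data the PPF state error is below the no-update
        (prior dynamics) error."""
        ds, x = mm.simulate(planted_gt, T=10_000, seed=21, return_latents=True)
        p = planted_gt.params
        sp = mm.ModelParams(A=p.A, W=p.W, x0=p.x0, Lambda0=p.Lambda0,
                            C=None, R=None, alpha=p.alpha,
                            timebase=ds.timebase, scale_tag="spike")
        fr = mm.point_process_filter(ds.spikes, sp)
        mse_filt = ((fr.xf - x) ** 2).mean()
        # pure prediction: x_{t} = A^t x0 = 0
        mse_prior = (x ** 2).mean()
        assert mse_filt < mse_prior

    def test_divergent_rate_raises_with_context(self):
        alpha = np.column_stack([[15.0], [0.0]])  # e^15 * 0.01 >> 10
        params = _spike_params(alpha=alpha.reshape(1, 2), T=5)
        with pytest.raises(mm.ssm.FilterError, match="step 0"):
            mm.point_process_filter(np.zeros((5, 1)), params)


class TestMultiscaleFilter:
    def test_reduces_to_ppf_without_lfp(self, planted_gt):
        ds = mm.simulate(planted_gt, T=2000, seed=5)
        p = planted_gt.params
        ms = mm.multiscale_filter(ds.spikes, np.zeros((400, 0)),
                                  mm.ModelParams(A=p.A, W=p.W, x0=p.x0,
                                                 Lambda0=p.Lambda0, C=None,
                                                 R=None, alpha=p.alpha,
                                                 timebase=ds.timebase,
                                                 scale_tag="multiscale"))
        sp = mm.ModelParams(A=p.A, W=p.W, x0=p.x0, Lambda0=p.Lambda0,
                            C=None, R=None, alpha=p.alpha,
                            timebase=ds.timebase, scale_tag="spike")
        pf = mm.point_process_filter(ds.spikes, sp)
        np.testing.assert_array_equal(ms.xf, pf.xf)   # bitwise
        np.testing.assert_array_equal(ms.Pf, pf.Pf)

    def test_reduces_to_kf_without_spikes(self, planted_gt):
        ds = mm.simulate(planted_gt, T=2000, seed=6)
        p = planted_gt.params
        ms_params = mm.ModelParams(A=p.A, W=p.W, x0=p.x0, Lambda0=p.Lambda0,
                                   C=p.C, R=p.R, alpha=None,
                                   timebase=ds.timebase,
                                   scale_tag="multiscale")
        ms = mm.multiscale_filter(np.zeros((2000, 0)), ds.lfp, ms_params)
        kf_params = mm.ModelParams(A=p.A, W=p.W, x0=p.x0, Lambda0=p.Lambda0,
                                   C=p.C, R=p.R, alpha=None,
                                   timebase=ds.timebase, scale_tag="lfp")
        kf = mm.kalman_filter(ds.lfp, kf_params)
        np.testing.assert_array_equal(ms.xf, kf.xf)
        np.testing.assert_array_equal(ms.Pf, kf.Pf)

    def test_combining_scales_reduces_state_error(self, planted_gt):
        """RMSE(multiscale) <= RMSE(spike-only) and <= RMSE(LFP-only)."""
        ds, x = mm.simulate(planted_gt, T=20_000, seed=9, return_latents=True)
        p = planted_gt.params
        tb = ds.timebase
        ms = mm.multiscale_filter(ds.spikes, ds.lfp, mm.ModelParams(
            A=p.A, W=p.W, x0=p.x0, Lambda0=p.Lambda0, C=p.C, R=p.R,
            alpha=p.alpha, timebase=tb, scale_tag="multiscale"))
        sp = mm.point_process_filter(ds.spikes, mm.ModelParams(
            A=p.A, W=p.W, x0=p.x0, Lambda0=p.Lambda0, C=None, R=None,
            alpha=p.alpha, timebase=tb, scale_tag="spike"))
        kf = mm.kalman_filter(ds.lfp, mm.ModelParams(
            A=p.A, W=p.W, x0=p.x0, Lambda0=p.Lambda0, C=p.C, R=p.R,
            alpha=None, timebase=tb, scale_tag="lfp"))
        def rmse(fr):
            return np.sqrt(((fr.xf - x) ** 2).mean())
        assert rmse(ms) <= rmse(sp) and rmse(ms) <= rmse(kf)

    def test_smoothing_reduces_error_further(self, planted_gt):
        ds, x = mm.simulate(planted_gt, T=20_000, seed=10, return_latents=True)
        p = planted_gt.params
        params = mm.ModelParams(A=p.A, W=p.W, x0=p.x0, Lambda0=p.Lambda0,
                                C=p.C, R=p.R, alpha=p.alpha,
                                timebase=ds.timebase, scale_tag="multiscale")
        fr = mm.multiscale_filter(ds.spikes, ds.lfp, params)
        sm = mm.multiscale_smoother(fr, params)
        assert np.sqrt(((sm.xs - x) ** 2).mean()) \
            <= np.sqrt(((fr.xf - x) ** 2).mean())


class TestStructuralProperties:
    def test_covariances_symmetric_psd(self, planted_gt):
        ds = mm.simulate(planted_gt, T=1000, seed=12)
        fr = mm.multiscale_filter(ds.spikes, ds.lfp, planted_gt.params)
        for P in (fr.Pf[::100], fr.Pp[::100]):
            np.testing.assert_allclose(P, np.swapaxes(P, 1, 2), atol=1e-12)
            for Pi in P:
                assert np.linalg.eigvalsh(Pi).min() > -1e-10

    def test_causality(self, planted_gt):
        """Perturbing the data at step t never changes estimates before t."""
        ds = mm.simulate(planted_gt, T=500, seed=13)
        fr1 = mm.multiscale_filter(ds.spikes, ds.lfp, planted_gt.params)
        spikes2 = ds.spikes.copy()
        spikes2[300:, :] = 1 - spikes2[300:, :]
        lfp2 = ds.lfp.copy()
        lfp2[60:, :] += 5.0
        fr2 = mm.multiscale_filter(spikes2, lfp2, planted_gt.params)
        np.testing.assert_array_equal(fr1.xf[:299], fr2.xf[:299])

    def test_params_round_trip(self, planted_gt, tmp_path):
        path = tmp_path / "model.h5"
        mm.save_params(planted_gt.params, path)
        back = mm.load_params(path)
        np.testing.assert_array_equal(back.A, planted_gt.params.A)
        np.testing.assert_array_equal(back.alpha, planted_gt.params.alpha)
        assert back.scale_tag == "multiscale"
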