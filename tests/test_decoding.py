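"""Behavior readout, CC/PP metrics, permutation and time-shift controls."""

import numpy as np
import pytest

import msmodes as mm
from oracles import auc_pair_counting


class TestProjection:
    def test_noiseless_linear_readout_recovered(self, rng):
        X = rng.standard_normal((500, 4))
        L0 = rng.standard_normal((2, 5))
        Z = L0[:, 0] + X @ L0[:, 1:].T
        proj = mm.fit_projection(X, Z)
        np.testing.assert_allclose(proj.L, L0, atol=1e-10)
        _, cc = mm.behavior_cc(Z, mm.predict_behavior(X, proj))
        assert cc == pytest.approx(1.0, abs=1e-12)

    def test_constant_states_use_ridge_fallback(self, rng):
        X = np.ones((100, 3))
        Z = rng.standard_normal((100, 1))
        proj = mm.fit_projection(X, Z)  # must not raise
        assert np.isfinite(proj.L).all()

    def test_ols_consistency_rate(self, rng):
        """||L_hat - L0|| shrinks roughly as 1/sqrt(T)."""
        L0 = rng.standard_normal((1, 4))
        errs = []
        for T in (1000, 4000, 16_000):
            X = rng.standard_normal((T, 3))
            Z = L0[:, 0] + X @ L0[:, 1:].T + rng.standard_normal((T, 1))
            proj = mm.fit_projection(X, Z)
            errs.append(np.linalg.norm(proj.L - L0))
        assert errs[2] < errs[1] < errs[0]
        assert errs[2] < errs[0] / 2  # ~1/4 expected; 1/2 with slack

    def test_zero_states_predict_bias(self):
        proj = mm.BehaviorProjection(L=np.array([[1.5, 2.0, 3.0]]))
        out = mm.predict_behavior(np.zeros((5, 2)), proj)
        np.testing.assert_allclose(out, 1.5)


class TestBehaviorCC:
    def test_identity_and_sign(self, rng):
        Z = rng.standard_normal((200, 2))
        cc, mean = mm.behavior_cc(Z, Z)
        np.testing.assert_allclose(cc, 1.0, atol=1e-12)
        cc, _ = mm.behavior_cc(Z, -Z)
        np.testing.assert_allclose(cc, -1.0, atol=1e-12)
        cc, _ = mm.behavior_cc(Z, Z + 7.0)  # offset invariance
        np.testing.assert_allclose(cc, 1.0, atol=1e-12)

    def test_zero_variance_dimension_excluded(self, rng):
        Z = np.column_stack([np.ones(100), rng.standard_normal(100)])
        Zh = rng.standard_normal((100, 2))
        cc, mean = mm.behavior_cc(Z, Zh)
        assert np.isnan(cc[0]) and np.isfinite(cc[1])
        assert mean == pytest.approx(cc[1])


class TestSpikePP:
    def test_worked_example_matches_pair_counting(self):
        """Six bins: AUC = 8/9 by brute-force pair counting, PP = 7/9."""
        probs = np.array([0.9, 0.8, 0.7, 0.3, 0.2, 0.1])
        spikes = np.array([1, 1, 0, 1, 0, 0])
        auc = mm.auc_rank(probs, spikes)
        assert auc == pytest.approx(auc_pair_counting(probs, spikes), abs=1e-12)
        assert auc == pytest.approx(8 / 9, abs=1e-12)
        assert 2 * auc - 1 == pytest.approx(7 / 9, abs=1e-12)

    def test_perfect_ordering_gives_pp_one(self, rng):
        probs = np.concatenate([rng.uniform(0.6, 1.0, 50),
                                rng.uniform(0.0, 0.4, 50)])
        labels = np.concatenate([np.ones(50), np.zeros(50)])
        assert 2 * mm.auc_rank(probs, labels) - 1 == pytest.approx(1.0)

    def test_rank_formulation_equals_threshold_sweep(self, rng):
        """Midrank AUC equals trapezoidal ROC integration on small cases."""
        from sklearn.metrics import roc_auc_score
        for _ in range(10):
            n = rng.integers(20, 200)
            scores = rng.standard_normal(n)
            labels = rng.uniform(size=n) < 0.3
            if labels.all() or not labels.any():
                continue
            assert mm.auc_rank(scores, labels) == pytest.approx(
                roc_auc_score(labels, scores), abs=1e-12)

    def test_degenerate_channels_reported_missing(self, planted_gt):
        ds = mm.simulate(planted_gt, T=1000, seed=3)
        fr = mm.multiscale_filter(ds.spikes, ds.lfp, planted_gt.params)
        N = ds.spikes.copy()
        N[:, 0] = 0
        pp = mm.one_step_spike_pp(N, planted_gt.params, fr)
        assert np.isnan(pp[0]) and np.isfinite(pp[1:]).all()

    def test_permuted_probabilities_near_zero(self, rng):
        n = 10_000
        probs = rng.uniform(size=n)
        labels = rng.uniform(size=n) < 0.1
        pp = 2 * mm.auc_rank(probs, labels) - 1
        assert abs(pp) < 0.05


class TestLfpCC:
    def test_exact_params_noiseless_limit(self, timebase):
        gt = mm.build_model([mm.ModeSpec(0.8, 0.2)], n_c=2, n_y=4, n_b=1,
                            timebase=timebase, seed=8, lfp_snr=1e6)
        ds = mm.simulate(gt, T=5000, seed=9)
        p = gt.params
        kf_params = mm.ModelParams(A=p.A, W=p.W, x0=p.x0, Lambda0=p.Lambda0,
                                   C=p.C, R=p.R, alpha=None,
                                   timebase=ds.timebase, scale_tag="lfp")
        fr = mm.kalman_filter(ds.lfp, kf_params)
        cc = mm.one_step_lfp_cc(ds.lfp, kf_params, fr)
        assert np.all(cc > 0.9)

    def test_bias_only_model_has_no_defined_cc(self, timebase, rng):
        n_x, n_y = 2, 3
        tb = mm.TimeBase(dt=0.01, k=5, T=500)
        C = np.zeros((n_y, n_x + 1))
        C[:, 0] = rng.standard_normal(n_y)
        params = mm.ModelParams(A=0.9 * np.eye(n_x), W=0.1 * np.eye(n_x),
                                x0=np.zeros(n_x), Lambda0=np.eye(n_x),
                                C=C, R=np.eye(n_y), alpha=None,
                                timebase=tb, scale_tag="lfp")
        Y = rng.standard_normal((100, n_y))
        fr = mm.kalman_filter(Y, params)
        cc = mm.one_step_lfp_cc(Y, params, fr)
        assert np.isnan(cc).all()


class TestPermutationChance:
    def test_mean_near_zero_and_identity_sanity(self, rng):
        T = 2000
        X = rng.standard_normal((T, 3))
        L0 = rng.standard_normal((2, 4))
        Z = L0[:, 0] + X @ L0[:, 1:].T + 0.5 * rng.standard_normal((T, 2))
        tr, te = slice(0, 1500), slice(1500, None)
        out = mm.permutation_chance(X[tr], Z[tr], X[te], Z[te],
                                    n_perm=200, seed=0)
        assert abs(out["mean"]) < 3 * out["sem"] + 0.01
        # unpermuted readout has a clearly higher CC
        proj = mm.fit_projection(X[tr], Z[tr])
        _, cc = mm.behavior_cc(Z[te], mm.predict_behavior(X[te], proj))
        assert cc > out["mean"] + 5 * out["sd"]

    def test_null_sd_shrinks_with_test_length(self, rng):
        X = rng.standard_normal((10_000, 2))
        L0 = rng.standard_normal((1, 3))
        Z = L0[:, 0] + X @ L0[:, 1:].T + rng.standard_normal((10_000, 1))
        sds = []
        for T_test in (2000, 8000):
            out = mm.permutation_chance(X[:1000], Z[:1000],
                                        X[1000:1000 + T_test],
                                        Z[1000:1000 + T_test],
                                        n_perm=150, seed=1)
            sds.append(out["sd"])
        assert sds[1] < sds[0]


class TestTimeShift:
    def test_zero_shift_identity(self, rng):
        z = rng.standard_normal((1000, 1))
        pred = z + 0.1 * rng.standard_normal((1000, 1))
        out = mm.time_shift_control(pred, z, [0, 5, -5])
        _, cc0 = mm.behavior_cc(z, pred)
        assert out[0] == pytest.approx(cc0)

    def test_cc_decays_with_shift_for_slow_signal(self, planted_gt):
        ds, x = mm.simulate(planted_gt, T=8000, seed=30, return_latents=True)
        pred = x @ planted_gt.readout[:, 1:].T
        shifts = [0, 55, 110, 220, 440, 880]  # up to ~4x the 1.1 s decay
        out = mm.time_shift_control(pred, ds.behavior, shifts)
        ccs = [out[s] for s in shifts]
        assert ccs[0] == max(ccs)
        assert ccs[-1] < 0.5 * ccs[0]

    def test_excessive_shift_rejected(self):
        with pytest.raises(ValueError):
            mm.time_shift_control(np.zeros((100, 1)), np.zeros((100, 1)),
                                  [40])
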