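"""Mode extraction, distances, chance level, clustering, contributions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import msmodes as mm
from msmodes.modes import EigDimDiagram, ModeCluster, vertical_test


def _rot(r, th):
    return r * np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])


class TestExtractModes:
    def test_rotation_block_gives_planted_decay_frequency(self):
        # r = exp(-dt/1.1) ~= 0.990953, theta = 2*pi*0.17*dt ~= 0.0106814
        A = _rot(np.exp(-0.01 / 1.1), 2 * np.pi * 0.17 * 0.01)
        modes, _ = mm.extract_modes(A, 0.01)
        assert len(modes) == 1
        m = modes[0]
        assert m.kind == "complex"
        assert m.decay == pytest.approx(1.1, abs=1e-9)
        assert m.frequency == pytest.approx(0.17, abs=1e-9)

    def test_identity_modes_non_decaying_non_periodic(self):
        modes, _ = mm.extract_modes(np.eye(3), 0.01)
        assert len(modes) == 3
        for m in modes:
            assert m.non_decaying and m.non_periodic and m.kind == "real"

    def test_real_diagonal_decays(self):
        modes, _ = mm.extract_modes(np.diag([0.9, 0.5]), 0.01)
        decays = sorted(m.decay for m in modes)
        assert decays[0] == pytest.approx(0.01 / np.log(2), rel=1e-9)
        assert decays[1] == pytest.approx(0.01 / np.log(1 / 0.9), rel=1e-9)

    def test_negative_real_eigenvalue_flagged_alternating(self):
        modes, _ = mm.extract_modes(np.diag([-0.8, 0.7]), 0.01)
        neg = [m for m in modes if m.alternating]
        assert len(neg) == 1 and neg[0].kind == "real"
        assert neg[0].decay == pytest.approx(0.01 / np.log(1 / 0.8), rel=1e-9)

    def test_defective_matrix_rejected(self):
        A = np.array([[0.9, 1.0], [0.0, 0.9]])  # Jordan block
        with pytest.raises(np.linalg.LinAlgError, match="condition"):
            mm.extract_modes(A, 0.01)

    def test_reconstruction_identity(self, planted_gt):
        _, dec = mm.extract_modes(planted_gt.params.A, 0.01)
        recon = (dec.U @ np.diag(dec.E) @ dec.U_inv).real
        np.testing.assert_allclose(recon, planted_gt.params.A, atol=1e-10)


class TestModeDistance:
    def test_small_arithmetic_case(self):
        a = complex(0.99, 0.010)
        b = complex(0.99, 0.013)
        assert mm.mode_distance(a, b) == pytest.approx(0.003, abs=1e-12)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.tuples(*[st.floats(-1, 1, allow_nan=False) for _ in range(6)]))
    def test_metric_properties(self, vals):
        a = complex(vals[0], vals[1])
        b = complex(vals[2], vals[3])
        c = complex(vals[4], vals[5])
        dab = mm.mode_distance(a, b)
        assert dab == pytest.approx(mm.mode_distance(b, a), abs=1e-15)
        assert mm.mode_distance(a, a) == 0
        assert dab <= mm.mode_distance(a, c) + mm.mode_distance(c, b) + 1e-12


class TestChanceLevel:
    def test_unit_square_matches_closed_form(self):
        """Mean distance of two uniform points in the unit square is
        (2 + sqrt(2) + 5 asinh(1)) / 15 ~= 0.5214."""
        closed_form = (2 + np.sqrt(2) + 5 * np.arcsinh(1.0)) / 15
        est = mm.chance_level_distance((0, 1, 0, 1), n_samples=1_000_000,
                                       seed=0)
        assert est == pytest.approx(closed_form, abs=0.002)

    def test_zero_area_region(self):
        assert mm.chance_level_distance((0.5, 0.5, 0, 1), 1000, 0) == 0.0


def _cluster_from(eigs, centroid, dt=0.01):
    modes = [mm.extract_modes(_rot(abs(e), np.angle(e)), dt)[0][0]
             for e in eigs]
    return ModeCluster(centroid=centroid, kind="complex",
                       members=[(i + 2, 0, m) for i, m in enumerate(modes)])


class TestVerticalTest:
    def test_tight_cluster_significant(self):
        c = complex(0.98, 0.01)
        eigs = [c + 1e-4 * np.exp(1j * k) for k in range(8)]
        cl = _cluster_from(eigs, c)
        p, flag = vertical_test(cl, chance=0.02)
        assert flag and p < 0.05

    def test_members_spread_at_chance_radius_not_significant(self):
        rng = np.random.default_rng(0)
        chance = 0.02
        c = complex(0.95, 0.03)
        eigs = [c + chance * np.sqrt(rng.uniform()) * np.exp(2j * np.pi * rng.uniform())
                for _ in range(12)]
        cl = _cluster_from(eigs, c)
        p, flag = vertical_test(cl, chance=chance)
        assert not flag

    def test_too_few_members_undefined(self):
        cl = _cluster_from([complex(0.98, 0.01)] * 3, complex(0.98, 0.01))
        p, flag = vertical_test(cl, chance=0.02)
        assert p is None and not flag


class TestClusterModes:
    def _diagram_with_planted_clusters(self, seed=0):
        rng = np.random.default_rng(seed)
        centers = [complex(0.9910, 0.0107), complex(0.9672, 0.0031),
                   complex(0.9034, 0.0568)]
        modes_by_dim = {}
        for d in range(6, 14):
            ms = []
            for c in centers:
                e = c + 5e-4 * (rng.standard_normal() + 1j * rng.standard_normal())
                ms.append(mm.extract_modes(_rot(abs(e), np.angle(e)), 0.01,
                                           source_dimension=d)[0][0])
            # one real mode per dimension
            ms.append(mm.extract_modes(np.array([[rng.uniform(0.3, 0.5)]]),
                                       0.01, source_dimension=d)[0][0])
            modes_by_dim[d] = ms
        return EigDimDiagram(dims=list(range(6, 14)),
                             modes_by_dim=modes_by_dim, dt=0.01), centers

    def test_planted_clusters_recovered(self):
        diag, centers = self._diagram_with_planted_clusters()
        clusters = mm.cluster_modes(diag, seed=0)
        cplx = [c for c in clusters if c.kind == "complex"]
        assert len(cplx) == 3
        for ctr in centers:
            assert min(abs(c.centroid - ctr) for c in cplx) < 0.005

    def test_deviant_member_discarded(self):
        diag, centers = self._diagram_with_planted_clusters()
        # inject a stray mode: same decay band, frequency 60% off everything
        stray = mm.extract_modes(_rot(0.991, 0.0107 * 2.5), 0.01,
                                 source_dimension=13)[0][0]
        diag.modes_by_dim[13].append(stray)
        clusters = mm.cluster_modes(diag, seed=0)
        for c in clusters:
            assert all(m is not stray for _, _, m in c.members)

    def test_deterministic_under_restarts(self):
        diag, _ = self._diagram_with_planted_clusters()
        a = mm.cluster_modes(diag, seed=3)
        b = mm.cluster_modes(diag, seed=3)
        assert [c.centroid for c in a] == [c.centroid for c in b]


class TestModeContribution:
    def test_contributions_sum_to_full_projection(self, planted_gt, rng):
        modes, dec = mm.extract_modes(planted_gt.params.A, 0.01)
        n_x = planted_gt.params.n_x
        F = rng.standard_normal((3, n_x))
        X = rng.standard_normal((50, n_x))
        total = sum(mm.mode_contribution(dec, F, X, m) for m in modes)
        np.testing.assert_allclose(total, X @ F.T, atol=1e-10)

    def test_conjugate_pair_contribution_is_real(self, planted_gt, rng):
        modes, dec = mm.extract_modes(planted_gt.params.A, 0.01)
        cplx = [m for m in modes if m.kind == "complex"][0]
        F = rng.standard_normal((2, planted_gt.params.n_x))
        X = rng.standard_normal((20, planted_gt.params.n_x))
        contrib = mm.mode_contribution(dec, F, X, cplx)
        assert contrib.dtype.kind == "f"

    def test_single_mode_model_owns_everything(self, rng):
        A = np.array([[0.95]])
        modes, dec = mm.extract_modes(A, 0.01)
        F = np.array([[2.0]])
        X = rng.standard_normal((10, 1))
        np.testing.assert_allclose(mm.mode_contribution(dec, F, X, modes[0]),
                                   2 * X, atol=1e-12)


class TestIdentifyPredictiveMode:
    def _clusters(self, ccs_list):
        out = []
        for ccs in ccs_list:
            cl = ModeCluster(centroid=0.9 + 0.01j, kind="complex",
                             members=[(d, 0, None) for d in range(len(ccs))])
            cl.member_cc = list(ccs)
            out.append(cl)
        return out

    def test_dominant_cluster_flagged(self):
        cls = self._clusters([[0.6, 0.62, 0.58, 0.61, 0.59, 0.6],
                              [0.05, 0.02, 0.04, 0.03, 0.06, 0.01],
                              [0.1, 0.12, 0.9, 0.11, 0.08, 0.13]])
        idx, pv = mm.identify_predictive_mode(cls)
        assert idx == 0 and cls[0].predictive
        assert all(p < 0.05 for p in pv.values())

    def test_identical_distributions_not_flagged(self):
        cls = self._clusters([[0.3, 0.31, 0.29, 0.3, 0.3],
                              [0.3, 0.31, 0.29, 0.3, 0.3]])
        idx, pv = mm.identify_predictive_mode(cls)
        assert not cls[idx].predictive

    def test_single_cluster_vacuous(self):
        cls = self._clusters([[0.4, 0.5, 0.45]])
        idx, pv = mm.identify_predictive_mode(cls)
        assert idx == 0 and cls[0].predictive and pv == {}
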