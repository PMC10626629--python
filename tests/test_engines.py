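"""QTR / G-Ext / fully-TR / XLBO guess engines and the (q, eps) heuristic."""

import numpy as np
import pytest

from qtrgext.engines import (
    DEFAULT_EPS_GRID,
    DEFAULT_Q_GRID,
    ExtrapolationConfig,
    HistoryBuffer,
    XLBO_ALPHA,
    XLBO_C,
    XLBO_KAPPA,
    XLBOState,
    build_ls_system,
    cold_start_guess,
    default_config_for_threshold,
    fully_tr_tangent,
    gext_guess,
    mcweeny_purify,
    qtr_guess,
    qtr_tangent,
    select_parameters,
    solve_tikhonov,
    tangent_weights,
    xlbo_step,
)
from qtrgext.manifold import density_from_frame, grassmann_exp

from conftest import random_frame, random_tangent


# ---------------------------------------------------------------- helpers

def linear_history(rng, n_d=12, n=8, N=3, omegas=(0.3,), n_steps=30, offset=True):
    """Tangent/descriptor trajectory with an exactly linear map Gamma = M d.

    The descriptor is a superposition of sinusoids (plus an optional
    constant offset); the tangent is a fixed linear image of it.
    """
    M = rng.normal(size=(n * N, n_d))
    u = rng.normal(size=n_d) if offset else np.zeros(n_d)
    ws = [rng.normal(size=n_d) for _ in omegas]
    phases = rng.uniform(0, 2 * np.pi, size=len(omegas))

    def d_of(k):
        return u + sum(w * np.sin(om * k + ph) for w, om, ph in zip(ws, omegas, phases))

    def g_of(k):
        return (M @ d_of(k)).reshape(n, N)

    h = HistoryBuffer(capacity=64)
    for k in range(n_steps):
        h.append(k, g_of(k), d_of(k))
    return h, d_of, g_of


# ---------------------------------------------------------------- config

class TestConfig:
    @pytest.mark.parametrize("q,qt", [(3, 1), (4, 2), (5, 2), (6, 3), (20, 10)])
    def test_q_tilde_rule(self, q, qt):
        assert ExtrapolationConfig(q=q, epsilon=0.01).q_tilde == qt

    def test_threshold_defaults(self):
        loose = default_config_for_threshold(1e-5)
        tight = default_config_for_threshold(1e-7)
        assert (loose.q, loose.epsilon) == (5, 0.005)
        assert (tight.q, tight.epsilon) == (4, 0.001)
        assert default_config_for_threshold(1e-5, "gext").epsilon == 0.01

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            ExtrapolationConfig(q=2, epsilon=0.01)
        with pytest.raises(ValueError):
            ExtrapolationConfig(q=5, epsilon=0.0)
        with pytest.raises(ValueError):
            ExtrapolationConfig(q=5, epsilon=0.01, variant="nope")


class TestHistoryBuffer:
    def test_rejects_non_increasing_steps(self, rng):
        h = HistoryBuffer()
        h.append(3, np.zeros((2, 1)), np.zeros(3))
        with pytest.raises(ValueError, match="increasing"):
            h.append(3, np.zeros((2, 1)), np.zeros(3))

    def test_consecutive_check(self):
        h = HistoryBuffer()
        for k in (0, 1, 3):
            h.append(k, np.zeros((2, 1)), np.zeros(3))
        assert not h.has_consecutive(3, 4)  # gap at step 2
        assert h.has_consecutive(1, 4)


# ---------------------------------------------------------------- LS system

class TestBuildSystem:
    def test_against_brute_force_assembly(self, rng):
        # hand-built q = 4 history of 3-vectors vs independent assembly
        descs = {k: rng.normal(size=3) for k in range(5)}  # steps 0..3 + target
        h = HistoryBuffer()
        for k in range(4):
            h.append(k, np.zeros((2, 1)), descs[k])
        cfg = ExtrapolationConfig(q=4, epsilon=0.07)
        A, b = build_ls_system(h, descs[4], cfg)
        n = 4
        # brute force, straight from the definitions
        b_expect = np.concatenate([descs[n] + descs[n - 4], np.zeros(2)])
        cols = [descs[n - i] + descs[n - 4 + i] for i in (1, 2)]
        A_expect = np.vstack([np.column_stack(cols), 0.07 * np.eye(2)])
        assert np.allclose(A, A_expect)
        assert np.allclose(b, b_expect)

    def test_constant_history(self, rng):
        d_c = rng.normal(size=5)
        h = HistoryBuffer()
        for k in range(5):
            h.append(k, np.zeros((2, 1)), d_c)
        cfg = ExtrapolationConfig(q=5, epsilon=0.005)
        A, b = build_ls_system(h, d_c, cfg)
        assert np.allclose(A[:5].T, np.tile(2 * d_c, (2, 1)))
        assert np.allclose(b[:5], 2 * d_c)
        assert np.allclose(b[5:], 0.0)

    def test_insufficient_history_signals_cold_start(self, rng):
        h = HistoryBuffer()
        h.append(0, np.zeros((2, 1)), rng.normal(size=3))
        cfg = ExtrapolationConfig(q=4, epsilon=0.01)
        assert build_ls_system(h, rng.normal(size=3), cfg) is None


class TestTikhonov:
    def test_exact_representability_limit(self, rng):
        a = rng.normal(size=10)
        alpha = solve_tikhonov(a[:, None], a, 1e-12)
        assert alpha[0] == pytest.approx(1.0, abs=1e-8)

    def test_shrinkage_with_large_epsilon(self, rng):
        A = rng.normal(size=(15, 3))
        b = rng.normal(size=15)
        norms = [np.linalg.norm(solve_tikhonov(A, b, e)) for e in (0.1, 1.0, 10.0, 100.0)]
        assert all(n1 > n2 for n1, n2 in zip(norms, norms[1:]))
        assert norms[-1] < 1e-2

    @pytest.mark.parametrize("qt", range(1, 9))
    def test_matches_normal_equations(self, qt, rng):
        A = rng.normal(size=(20, qt))
        b = rng.normal(size=20)
        eps = 0.01
        alpha = solve_tikhonov(A, b, eps)
        oracle = np.linalg.solve(A.T @ A + eps**2 * np.eye(qt), A.T @ b)
        assert np.abs(alpha - oracle).max() < 1e-10


# ---------------------------------------------------------------- tangents

class TestQTRTangent:
    @pytest.mark.parametrize("q", [3, 4, 5, 6, 9, 10])
    def test_weight_symmetry(self, q, rng):
        # structural time-reversal: after stripping the fixed -1 on the
        # trailing snapshot, Gamma_{n-i} and Gamma_{n-(q-i)} share weights
        alpha = rng.normal(size=q // 2)
        w_sym = tangent_weights(alpha, q)
        w_sym[q - 1] += 1.0
        for i in range(1, q):
            assert w_sym[i - 1] == pytest.approx(w_sym[q - i - 1], abs=1e-14)

    def test_zero_alpha_returns_minus_oldest(self, rng):
        h, d_of, g_of = linear_history(rng)
        cfg = ExtrapolationConfig(q=5, epsilon=0.01)
        G = qtr_tangent(h, np.zeros(2), cfg)
        n = 30
        assert np.allclose(G, -g_of(n - 5))

    def test_constant_history_stationary(self, rng):
        g_c = rng.normal(size=(4, 2))
        h = HistoryBuffer()
        for k in range(5):
            h.append(k, g_c, np.ones(3))
        cfg = ExtrapolationConfig(q=5, epsilon=0.01)
        alpha = np.array([0.7, 0.3])  # sum 1 => weights sum to 2*1 - 1 = 1
        assert np.allclose(qtr_tangent(h, alpha, cfg), g_c)

    @pytest.mark.parametrize("q", [4, 5, 6])
    def test_linear_exactness(self, q, rng):
        # Eq-6-style property: exact linear map + tiny ridge => exact tangent
        h, d_of, g_of = linear_history(rng, omegas=(0.3,), n_steps=30)
        cfg = ExtrapolationConfig(q=q, epsilon=1e-10)
        A, b = build_ls_system(h, d_of(30), cfg)
        alpha = solve_tikhonov(A, b)
        G = qtr_tangent(h, alpha, cfg)
        assert np.abs(G - g_of(30)).max() < 1e-8


class TestGuesses:
    def test_constant_history_reproduces_density(self, rng):
        C0 = random_frame(rng, 8, 3)
        G_c = random_tangent(rng, C0, 0.2)
        D_c = grassmann_exp(G_c, C0)
        h = HistoryBuffer()
        for k in range(5):
            h.append(k, G_c, np.full(4, 10.0))
        cfg = ExtrapolationConfig(q=5, epsilon=0.005)
        D, _ = qtr_guess(h, np.full(4, 10.0), cfg, C0)
        assert np.abs(D - D_c).max() < 1e-8
        D2, _ = gext_guess(h, np.full(4, 10.0), C0, q=5)
        assert np.abs(D2 - D_c).max() < 1e-8

    def test_qtr_accepts_reported_good_values(self, rng):
        cfg = ExtrapolationConfig(q=5, epsilon=0.005)
        assert cfg.q_tilde == 2

    def test_guess_is_projector(self, rng):
        C0 = random_frame(rng, 10, 4)
        h = HistoryBuffer()
        for k in range(6):
            h.append(k, random_tangent(rng, C0, 0.05), rng.normal(size=6))
        cfg = ExtrapolationConfig(q=5, epsilon=0.005)
        D, G = qtr_guess(h, rng.normal(size=6), cfg, C0)
        assert np.abs(D @ D - D).max() < 1e-10
        assert abs(np.trace(D) - 4) < 1e-10
        assert np.abs(C0.T @ G).max() < 1e-10  # tangency

    def test_gext_single_entry_reuses_previous(self, rng):
        C0 = random_frame(rng, 6, 2)
        G1 = random_tangent(rng, C0, 0.1)
        d1 = rng.normal(size=4)
        h = HistoryBuffer()
        h.append(0, G1, d1)
        out = gext_guess(h, d1, C0, q=1, epsilon=1e-8)
        D, _ = out
        assert np.abs(D - grassmann_exp(G1, C0)).max() < 1e-7

    def test_fully_tr_reduces_to_qtr_with_converged_guess(self, rng):
        h, d_of, g_of = linear_history(rng)
        cfg = ExtrapolationConfig(q=5, epsilon=0.01, variant="fully_tr")
        alpha = rng.normal(size=2)
        n = 30
        stored = {n - 5: g_of(n - 5)}  # guess == converged tangent
        G_tr = fully_tr_tangent(h, alpha, cfg, stored)
        G_qtr = qtr_tangent(h, alpha, cfg)
        assert np.allclose(G_tr, G_qtr)

    def test_fully_tr_missing_guess_is_cold_start(self, rng):
        h, d_of, g_of = linear_history(rng)
        cfg = ExtrapolationConfig(q=5, epsilon=0.01, variant="fully_tr")
        assert fully_tr_tangent(h, rng.normal(size=2), cfg, {}) is None


# ---------------------------------------------------------------- XLBO

class TestXLBO:
    def test_printed_constants(self):
        state = XLBOState()
        assert state.kappa == 1.86
        assert state.c == 0.0016
        assert state.alpha == (-36, 99, -88, 11, 32, -25, 8, -1)
        assert sum(state.alpha) == 0

    def test_stationary_fixed_point(self, rng):
        D = density_from_frame(random_frame(rng, 6, 2))
        state = XLBOState(P_history=[D.copy() for _ in range(9)])
        P_next, _ = xlbo_step(state, D)
        assert np.abs(P_next - D).max() < 1e-12

    def test_verlet_limit_without_dissipation(self, rng):
        # with c = 0 and P_n = D_n the update is plain 2 P_n - P_{n-1}
        P_hist = [rng.normal(size=(4, 4)) for _ in range(9)]
        P_hist = [0.5 * (P + P.T) for P in P_hist]
        state = XLBOState(c=0.0, P_history=P_hist)
        D_n = P_hist[-1]
        P_next, _ = xlbo_step(state, D_n)
        assert np.allclose(P_next, 2 * P_hist[-1] - P_hist[-2])

    def test_cold_start_fills_history(self, rng):
        D = density_from_frame(random_frame(rng, 5, 2))
        P_next, state = xlbo_step(XLBOState(), D)
        assert np.abs(P_next - D).max() < 1e-12
        assert len(state.P_history) == 9


class TestMcWeeny:
    def test_idempotent_fixed_point(self, rng):
        D = density_from_frame(random_frame(rng, 7, 3))
        assert np.abs(mcweeny_purify(D) - D).max() < 1e-12

    def test_diagonal_basin(self):
        P = mcweeny_purify(np.diag([0.9, 0.1]))
        assert np.abs(P - np.diag([1.0, 0.0])).max() < 1e-12

    def test_matches_eigenvalue_rounding_oracle(self, rng):
        C = random_frame(rng, 8, 3)
        D = density_from_frame(C)
        noise = rng.normal(size=(8, 8)) * 0.02
        P0 = D + 0.5 * (noise + noise.T)
        P = mcweeny_purify(P0)
        # oracle: round the eigenvalues of P0 to {0, 1}
        w, V = np.linalg.eigh(P0)
        D_oracle = (V[:, w > 0.5] @ V[:, w > 0.5].T)
        assert np.abs(P @ P - P).max() < 1e-12
        assert abs(np.trace(P) - 3) < 1e-9
        assert np.abs(P - D_oracle).max() < 1e-6

    def test_out_of_basin_rejected(self):
        with pytest.raises(ValueError, match="basin"):
            mcweeny_purify(np.diag([1.5, 0.0]))


# ---------------------------------------------------------------- selection

class TestSelectParameters:
    def test_default_grids(self):
        assert DEFAULT_Q_GRID == tuple(range(3, 21))
        assert DEFAULT_EPS_GRID == (0.001, 0.002, 0.005, 0.01, 0.02, 0.05)

    def test_recovers_known_optimum_on_truncated_grid(self, rng):
        # two incommensurate modes + offset: exactly representable only for
        # q_tilde >= 3, i.e. q >= 6 -> q = 6 is the unique optimum in 3..6
        h, d_of, g_of = linear_history(
            rng, omegas=(0.37, 0.81), n_steps=40, offset=True)
        traj = [(g_of(k), d_of(k)) for k in range(40)]
        q, eps = select_parameters(traj, q_grid=range(3, 7), eps_grid=[1e-3, 5e-3])
        assert q == 6
        assert eps == 1e-3

    def test_tie_break_prefers_smaller_q_then_eps(self, rng):
        # zero tangents: every (q, eps) has exactly zero error -> smallest wins
        g_c = np.zeros((3, 1))
        traj = [(g_c, np.full(4, 1.5)) for _ in range(25)]
        q, eps = select_parameters(traj, q_grid=[4, 5, 6], eps_grid=[0.01, 0.001])
        assert (q, eps) == (4, 0.001)

    def test_short_history_rejected(self, rng):
        traj = [(np.zeros((2, 1)), np.zeros(3))] * 10
        with pytest.raises(ValueError, match="too short"):
            select_parameters(traj, q_grid=[3, 20], eps_grid=[0.01])


def test_cold_start_policy(rng):
    assert cold_start_guess(None) is None
    D = np.eye(3)
    assert cold_start_guess(D) is D
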