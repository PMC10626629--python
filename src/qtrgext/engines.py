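"""SCF initial-guess engines for Born-Oppenheimer MD.

The central scheme is the quasi time-reversible Grassmann extrapolation
(QTR G-Ext).  Given the last ``q`` converged tangent vectors
``Gamma_{n-1}, ..., Gamma_{n-q}`` (Grassmann logarithms of converged
densities at a fixed reference) and their Coulomb-matrix descriptors, the
guess tangent is the symmetric, time-reversal-structured combination

    Gamma~_n = sum_{i=1..q~} alpha_i (Gamma_{n-i} + Gamma_{n-q+i}) - Gamma_{n-q}

with ``q~ = q/2`` (q even) or ``(q-1)/2`` (q odd).  The coefficients solve
the Tikhonov-regularized least squares problem

    min_alpha || sum_i alpha_i (d_{n-i} + d_{n-q+i}) - (d_n + d_{n-q}) ||^2
               + eps^2 ||alpha||^2,

assembled in stacked form: the data matrix gets an ``eps I`` block appended
below and the right-hand side ``b = d_n + d_{n-q}`` is padded with ``q~``
zeros.  The guess density is then ``Exp(Gamma~_n)``.

Also provided, as baselines:

* the one-sided Grassmann extrapolation (G-Ext), fitting
  ``sum_i alpha_i d_{n-i} ~= d_n`` with eps = 0.01;
* a *fully* time-reversible variant where the trailing ``Gamma_{n-q}`` is
  the engine's own guess tangent from step ``n-q`` instead of the converged
  one (accurate energy conservation, but errors accumulate);
* the dissipative extended-Lagrangian scheme (XLBO) propagating an
  auxiliary density ``P`` with fixed constants kappa = 1.86, c = 0.0016 and
  an 8-term dissipation stencil, optionally McWeeny-purified before use;
* a previous-converged-density guess and the cold-start policy.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field, replace

import numpy as np

from .manifold import (
    density_from_frame,
    exp_frame,
    frame_from_density,
    grassmann_exp,
    grassmann_log,
    make_reference,
)

__all__ = [
    "ExtrapolationConfig",
    "HistoryBuffer",
    "default_config_for_threshold",
    "build_ls_system",
    "solve_tikhonov",
    "tangent_weights",
    "qtr_tangent",
    "qtr_guess",
    "fully_tr_tangent",
    "gext_coefficients",
    "gext_guess",
    "XLBO_KAPPA",
    "XLBO_C",
    "XLBO_ALPHA",
    "XLBOState",
    "xlbo_step",
    "mcweeny_purify",
    "PurificationFailureError",
    "select_parameters",
    "parameter_scan",
    "cold_start_guess",
    "DEFAULT_Q_GRID",
    "DEFAULT_EPS_GRID",
    "GuessEngine",
    "GrassmannEngine",
    "XLBOEngine",
    "PreviousDensityEngine",
    "make_engine",
]

#: Parameter grids used by the (q, eps) selection heuristic.
DEFAULT_Q_GRID: tuple[int, ...] = tuple(range(3, 21))
DEFAULT_EPS_GRID: tuple[float, ...] = (0.001, 0.002, 0.005, 0.01, 0.02, 0.05)

#: XLBO dissipative-propagation constants.
XLBO_KAPPA: float = 1.86
XLBO_C: float = 0.0016
XLBO_ALPHA: tuple[int, ...] = (-36, 99, -88, 11, 32, -25, 8, -1)


class PurificationFailureError(RuntimeError):
    """McWeeny purification did not converge."""


# --------------------------------------------------------------------------
# configuration and history
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ExtrapolationConfig:
    """Depth ``q``, regularization ``epsilon`` and variant of the extrapolation."""

    q: int = 5
    epsilon: float = 0.005
    variant: str = "qtr"  # qtr | fully_tr | gext

    def __post_init__(self):
        if self.q < 1:
            raise ValueError("history depth q must be >= 1")
        if self.variant in ("qtr", "fully_tr") and self.q < 3:
            raise ValueError("time-reversible variants require q >= 3")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.variant not in ("qtr", "fully_tr", "gext"):
            raise ValueError(f"unknown variant {self.variant!r}")

    @property
    def q_tilde(self) -> int:
        """Number of free coefficients: q/2 for even q, (q-1)/2 for odd q."""
        return self.q // 2


def default_config_for_threshold(threshold: float, variant: str = "qtr") -> ExtrapolationConfig:
    """Recommended (q, epsilon) per SCF convergence threshold.

    Loose thresholds (>= 1e-6) use (5, 0.005); tight ones use (4, 0.001).
    The G-Ext baseline always uses its standard epsilon = 0.01.
    """
    q = 5 if threshold >= 1e-6 else 4
    if variant == "gext":
        return ExtrapolationConfig(q=q, epsilon=0.01, variant="gext")
    eps = 0.005 if threshold >= 1e-6 else 0.001
    return ExtrapolationConfig(q=q, epsilon=eps, variant=variant)


class HistoryBuffer:
    """Bounded, ordered record of converged (step, tangent, descriptor) triples."""

    def __init__(self, capacity: int = 32):
        if capacity < 1:
            raise ValueError("capacity must be >= 1")
        self._entries: deque = deque(maxlen=capacity)

    def append(self, step: int, gamma: np.ndarray, descriptor: np.ndarray) -> None:
        if self._entries and step <= self._entries[-1][0]:
            raise ValueError(
                f"step indices must be strictly increasing (got {step} after "
                f"{self._entries[-1][0]})"
            )
        self._entries.append((int(step), np.asarray(gamma, float), np.asarray(descriptor, float)))

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self):
        return iter(self._entries)

    def last(self, k: int) -> list:
        """The most recent ``k`` entries, oldest first."""
        if k > len(self._entries):
            raise ValueError(f"requested {k} entries but history holds {len(self._entries)}")
        return list(self._entries)[-k:]

    def has_consecutive(self, q: int, n: int) -> bool:
        """True if entries for steps n-q, ..., n-1 are all present."""
        if len(self._entries) < q:
            return False
        tail = self.last(q)
        return [e[0] for e in tail] == list(range(n - q, n))


# --------------------------------------------------------------------------
# QTR least-squares system
# --------------------------------------------------------------------------

def build_ls_system(h: HistoryBuffer, d_n: np.ndarray, cfg: ExtrapolationConfig):
    """Assemble the stacked QTR least-squares system (A, b).

    Top block of column ``i`` (i = 1..q~) is ``d_{n-i} + d_{n-q+i}``; the
    right-hand side's top block is ``d_n + d_{n-q}``.  The bottom ``q~``
    rows carry the regularization block ``eps I`` (zeros in ``b``).

    Returns ``None`` (cold-start signal) when fewer than ``q`` consecutive
    history entries are available.
    """
    q, qt = cfg.q, cfg.q_tilde
    n = (h.last(1)[0][0] + 1) if len(h) else 0
    if not h.has_consecutive(q, n):
        return None
    d_n = np.asarray(d_n, float)
    tail = h.last(q)  # steps n-q .. n-1, oldest first
    desc = {e[0]: e[2] for e in tail}
    b_top = d_n + desc[n - q]
    A_top = np.column_stack([desc[n - i] + desc[n - q + i] for i in range(1, qt + 1)])
    A = np.vstack([A_top, cfg.epsilon * np.eye(qt)])
    b = np.concatenate([b_top, np.zeros(qt)])
    return A, b


def solve_tikhonov(A: np.ndarray, b: np.ndarray, epsilon: float = 0.0) -> np.ndarray:
    """Least-squares solution of ``min ||A x - b||^2 + epsilon^2 ||x||^2``.

    Solved through the stacked formulation (an ``epsilon I`` block appended
    to ``A`` and zeros to ``b``); with ``epsilon = 0`` the input is solved
    as given, which is the right call for systems that already carry their
    regularization block.
    """
    A = np.asarray(A, float)
    b = np.asarray(b, float)
    if epsilon < 0:
        raise ValueError("epsilon must be non-negative")
    if epsilon > 0:
        k = A.shape[1]
        A = np.vstack([A, epsilon * np.eye(k)])
        b = np.concatenate([b, np.zeros(k)])
    coeff, *_ = np.linalg.lstsq(A, b, rcond=None)
    return coeff


def tangent_weights(alpha: np.ndarray, q: int) -> np.ndarray:
    """Weights ``w`` of the combination ``Gamma~_n = sum_j w[j-1] Gamma_{n-j}``.

    Index ``j`` runs 1..q.  Each coefficient ``alpha_i`` is applied
    symmetrically to the pair (Gamma_{n-i}, Gamma_{n-q+i}); the trailing
    snapshot Gamma_{n-q} carries a fixed weight of -1.  The symmetry
    ``w[j] == w[q-j]`` for j = 1..q-1 is the structural time-reversal
    property of the scheme.
    """
    alpha = np.asarray(alpha, float)
    qt = q // 2
    if len(alpha) != qt:
        raise ValueError(f"expected {qt} coefficients for q = {q}, got {len(alpha)}")
    w = np.zeros(q)
    for i in range(1, qt + 1):
        w[i - 1] += alpha[i - 1]
        w[q - i - 1] += alpha[i - 1]  # index n-q+i  <->  j = q-i
    w[q - 1] -= 1.0
    return w


def qtr_tangent(h: HistoryBuffer, alpha: np.ndarray, cfg: ExtrapolationConfig) -> np.ndarray:
    """Combine history tangents with the QTR weights."""
    w = tangent_weights(alpha, cfg.q)
    tail = h.last(cfg.q)  # oldest (n-q) first
    n = tail[-1][0] + 1
    G = np.zeros_like(tail[0][1])
    for step, gamma, _ in tail:
        G += w[n - step - 1] * gamma
    return G


def qtr_guess(h: HistoryBuffer, d_n: np.ndarray, cfg: ExtrapolationConfig, ref: np.ndarray):
    """QTR G-Ext guess density for the step with descriptor ``d_n``.

    Returns ``(D_guess, Gamma~)`` or ``None`` on cold start.
    """
    system = build_ls_system(h, d_n, cfg)
    if system is None:
        return None
    alpha = solve_tikhonov(*system)
    G = qtr_tangent(h, alpha, cfg)
    return grassmann_exp(G, ref), G


def fully_tr_tangent(
    h: HistoryBuffer,
    alpha: np.ndarray,
    cfg: ExtrapolationConfig,
    previous_guesses: dict,
) -> np.ndarray | None:
    """Fully time-reversible combination.

    Identical to :func:`qtr_tangent` except that the trailing converged
    tangent ``Gamma_{n-q}`` is replaced by the engine's own *guess* tangent
    emitted at step ``n-q`` (looked up in ``previous_guesses``, a mapping
    step -> tangent).  Returns ``None`` (cold-start signal) if that guess
    was never stored.
    """
    tail = h.last(cfg.q)
    n = tail[-1][0] + 1
    if (n - cfg.q) not in previous_guesses:
        return None
    G = qtr_tangent(h, alpha, cfg)
    gamma_conv = tail[0][1]  # converged Gamma_{n-q}
    return G - (-gamma_conv) + (-previous_guesses[n - cfg.q])


# --------------------------------------------------------------------------
# G-Ext baseline
# --------------------------------------------------------------------------

def gext_coefficients(h: HistoryBuffer, d_n: np.ndarray, q: int, epsilon: float) -> np.ndarray:
    """One-sided fit: ``min || sum_i alpha_i d_{n-i} - d_n ||^2 + eps^2 ||alpha||^2``."""
    tail = h.last(q)
    n = tail[-1][0] + 1
    desc = {e[0]: e[2] for e in tail}
    A = np.column_stack([desc[n - i] for i in range(1, q + 1)])
    return solve_tikhonov(A, np.asarray(d_n, float), epsilon)


def gext_guess(h: HistoryBuffer, d_n: np.ndarray, ref: np.ndarray,
               q: int = 5, epsilon: float = 0.01):
    """One-sided Grassmann extrapolation guess (baseline scheme).

    Tangent ``sum_{i=1..q} alpha_i Gamma_{n-i}`` with descriptor-fitted
    coefficients; returns ``(D_guess, Gamma~)`` or ``None`` on cold start.
    """
    n = (h.last(1)[0][0] + 1) if len(h) else 0
    if not h.has_consecutive(q, n):
        return None
    alpha = gext_coefficients(h, d_n, q, epsilon)
    tail = h.last(q)
    G = np.zeros_like(tail[0][1])
    for step, gamma, _ in tail:
        G += alpha[n - step - 1] * gamma
    return grassmann_exp(G, ref), G


# --------------------------------------------------------------------------
# XLBO baseline
# --------------------------------------------------------------------------

@dataclass
class XLBOState:
    """Auxiliary-density propagation state of the XLBO scheme."""

    kappa: float = XLBO_KAPPA
    c: float = XLBO_C
    alpha: tuple = XLBO_ALPHA
    P_history: list = field(default_factory=list)  # newest last, capacity 9

    def __post_init__(self):
        if sum(self.alpha) != 0:
            raise ValueError("XLBO dissipation coefficients must sum to zero")


def xlbo_step(state: XLBOState, D_converged: np.ndarray):
    """One dissipative auxiliary-density update.

    ``P_{n+1} = 2 P_n - P_{n-1} + kappa (D_n - P_n) + c sum_{k=0..7} alpha_k P_{n-k}``.

    On cold start (fewer than 9 stored densities) the history is filled
    with the incoming converged density, which makes the first updates a
    stationary warm-up.  Returns ``(guess, new_state)``; the guess is not
    idempotent in general.
    """
    D = np.asarray(D_converged, float)
    hist = [np.asarray(P, float) for P in state.P_history]
    while len(hist) < 9:
        hist.insert(0, D.copy())
    P_n, P_nm1 = hist[-1], hist[-2]
    diss = np.zeros_like(D)
    for k, a_k in enumerate(state.alpha):
        diss += a_k * hist[-1 - k]
    P_next = 2.0 * P_n - P_nm1 + state.kappa * (D - P_n) + state.c * diss
    new_hist = (hist + [P_next])[-9:]
    return P_next, replace(state, P_history=new_hist)


def mcweeny_purify(P: np.ndarray, max_iter: int = 50, tol: float = 1e-12) -> np.ndarray:
    """Drive a near-idempotent symmetric matrix to an exact projector.

    Iterates ``P <- 3P^2 - 2P^3`` until ``max |P^2 - P| < tol``.  Requires
    all eigenvalues in (-0.3, 1.3) (the attraction basin of {0, 1}).
    """
    P = 0.5 * (np.asarray(P, float) + np.asarray(P, float).T)
    w = np.linalg.eigvalsh(P)
    if w[0] <= -0.3 or w[-1] >= 1.3:
        raise ValueError(
            f"eigenvalues in [{w[0]:.3f}, {w[-1]:.3f}] outside the purification basin (-0.3, 1.3)"
        )
    target_trace = np.round(np.trace(P))
    for _ in range(max_iter):
        P2 = P @ P
        if np.abs(P2 - P).max() < tol:
            if abs(np.trace(P) - target_trace) > 0.5:
                raise PurificationFailureError("purification changed the rank")
            return P
        P = 3.0 * P2 - 2.0 * P2 @ P
        P = 0.5 * (P + P.T)
    raise PurificationFailureError(f"no convergence in {max_iter} iterations")


# --------------------------------------------------------------------------
# (q, eps) selection heuristic
# --------------------------------------------------------------------------

def parameter_scan(trajectory_history, q_grid=None, eps_grid=None):
    """Replay the QTR extrapolation on a stored trajectory for each (q, eps).

    ``trajectory_history`` is a list of (tangent, descriptor) pairs from
    consecutive converged steps.  For each grid pair the mean Frobenius
    error ``||Gamma~_n - Gamma_n||_F`` over all replayable steps
    (n >= max(q_grid), so every pair is scored on the same steps) is
    computed.  Returns a list of (q, eps, mean_error) rows.
    """
    q_grid = sorted(q_grid if q_grid is not None else DEFAULT_Q_GRID)
    eps_grid = sorted(eps_grid if eps_grid is not None else DEFAULT_EPS_GRID)
    n_hist = len(trajectory_history)
    q_max = max(q_grid)
    if n_hist < q_max + 1:
        raise ValueError(
            f"trajectory history of length {n_hist} too short for q_max = {q_max}"
        )
    gammas = [np.asarray(g, float) for g, _ in trajectory_history]
    descs = [np.asarray(d, float) for _, d in trajectory_history]
    rows = []
    for q in q_grid:
        for eps in eps_grid:
            cfg = ExtrapolationConfig(q=q, epsilon=eps)
            h = HistoryBuffer(capacity=q)
            for k in range(q_max):
                h.append(k, gammas[k], descs[k])
            errs = []
            for n in range(q_max, n_hist):
                system = build_ls_system(h, descs[n], cfg)
                alpha = solve_tikhonov(*system)
                G = qtr_tangent(h, alpha, cfg)
                errs.append(np.linalg.norm(G - gammas[n]))
                h.append(n, gammas[n], descs[n])
            rows.append((q, eps, float(np.mean(errs))))
    return rows


def select_parameters(trajectory_history, q_grid=None, eps_grid=None):
    """Grid-search (q, eps) minimizing the mean tangent extrapolation error.

    Ties are broken toward smaller q, then smaller epsilon (the cheaper,
    less-regularized model).
    """
    rows = parameter_scan(trajectory_history, q_grid, eps_grid)
    best = None
    for q, eps, err in rows:  # rows are sorted q-major, eps-minor
        if best is None or err < best[2]:
            best = (q, eps, err)
    return best[0], best[1]


def cold_start_guess(previous: np.ndarray | None):
    """Cold-start policy: previous converged density if any, else ``None``.

    ``None`` tells the caller to fall back on the backend's default initial
    guess.  Steps served this way are flagged so iteration statistics can
    discard the warm-up.
    """
    return previous


# --------------------------------------------------------------------------
# engine objects (drive the per-step guess/observe cycle for the MD loop)
# --------------------------------------------------------------------------

class GuessEngine:
    """Interface: ``propose`` a guess density, ``observe`` a converged one.

    ``propose`` returns an idempotent guess density or ``None`` (cold
    start).  ``observe`` feeds the converged density of the completed step
    back into the engine's internal state.
    """

    name = "base"

    def propose(self, step: int, d_n: np.ndarray | None) -> np.ndarray | None:
        raise NotImplementedError

    def observe(self, step: int, D_converged: np.ndarray, d_n: np.ndarray | None) -> None:
        raise NotImplementedError


class GrassmannEngine(GuessEngine):
    """QTR, fully-TR or one-sided (gext) Grassmann extrapolation engine.

    The reference frame is fixed to the frame of the first observed
    converged density; the logarithm of each converged density is stored
    once and reused up to q times.
    """

    def __init__(self, cfg: ExtrapolationConfig):
        self.cfg = cfg
        self.name = cfg.variant
        self.ref: np.ndarray | None = None
        self.history = HistoryBuffer(capacity=max(cfg.q + 2, 8))
        self._guess_tangents: dict[int, np.ndarray] = {}  # fully_tr bookkeeping

    def propose(self, step, d_n):
        if self.ref is None or d_n is None:
            return None
        cfg = self.cfg
        if cfg.variant == "gext":
            out = gext_guess(self.history, d_n, self.ref, q=cfg.q, epsilon=cfg.epsilon)
            if out is None:
                return None
            D, _ = out
            return D
        system = build_ls_system(self.history, d_n, cfg)
        if system is None:
            return None
        alpha = solve_tikhonov(*system)
        if cfg.variant == "fully_tr":
            G = fully_tr_tangent(self.history, alpha, cfg, self._guess_tangents)
            if G is None:  # no stored guess for step n-q yet: fall back to QTR
                G = qtr_tangent(self.history, alpha, cfg)
        else:
            G = qtr_tangent(self.history, alpha, cfg)
        if cfg.variant == "fully_tr":
            self._guess_tangents[step] = G
            for old in [k for k in self._guess_tangents if k < step - cfg.q - 2]:
                del self._guess_tangents[old]
        return grassmann_exp(G, self.ref)

    def observe(self, step, D_converged, d_n):
        if self.ref is None:
            self.ref = make_reference(frame_from_density(D_converged))
        gamma = grassmann_log(D_converged, self.ref)
        self.history.append(step, gamma, d_n)


class XLBOEngine(GuessEngine):
    """Extended-Lagrangian auxiliary-density guess engine."""

    name = "xlbo"

    def __init__(self, purify: bool = True):
        self.purify = purify
        self.state = XLBOState()
        self._next_guess: np.ndarray | None = None

    def propose(self, step, d_n):
        if self._next_guess is None:
            return None
        if self.purify:
            return mcweeny_purify(self._next_guess)
        return self._next_guess

    def observe(self, step, D_converged, d_n):
        self._next_guess, self.state = xlbo_step(self.state, D_converged)


class PreviousDensityEngine(GuessEngine):
    """Baseline: reuse the previous converged density as the guess."""

    name = "previous"

    def __init__(self):
        self._previous: np.ndarray | None = None

    def propose(self, step, d_n):
        return cold_start_guess(self._previous)

    def observe(self, step, D_converged, d_n):
        self._previous = np.asarray(D_converged, float)


def make_engine(strategy: str, threshold: float = 1e-5,
                q: int | None = None, epsilon: float | None = None,
                purify_xlbo: bool = True) -> GuessEngine:
    """Engine factory used by the MD driver and the CLI.

    ``strategy`` is one of qtr | fully_tr | gext | xlbo | previous.  For the
    Grassmann engines, unspecified (q, epsilon) fall back on the
    threshold-dependent defaults of :func:`default_config_for_threshold`.
    """
    if strategy == "xlbo":
        return XLBOEngine(purify=purify_xlbo)
    if strategy == "previous":
        return PreviousDensityEngine()
    if strategy in ("qtr", "fully_tr", "gext"):
        cfg = default_config_for_threshold(threshold, variant=strategy)
        if q is not None:
            cfg = replace(cfg, q=q)
        if epsilon is not None:
            cfg = replace(cfg, epsilon=epsilon)
        return GrassmannEngine(cfg)
    raise ValueError(f"unknown guess strategy {strategy!r}")
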