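"""Self-consistent tight-binding toy model with a desk-scale SCF.

A stand-in for a real Kohn-Sham backend: one basis function per atom,
distance-decaying hopping, a Hubbard-style on-site coupling that makes the
Fock operator depend on its own density, and an exponentially decaying
overlap that exercises the Löwdin orthogonalization path.  Because the
fixed point, the energy and (finite-difference) forces are cheap, the
quality of an SCF initial guess is directly measurable as the number of
fixed-point iterations - the same observable the extrapolation schemes are
designed to reduce in production Born-Oppenheimer MD.

Model, in the Löwdin-orthonormalized basis:

    F(D) = h0~ + U diag(D_11, ..., D_nn)
    E_el = tr(D h0~) + (U/2) sum_i D_ii^2

with ``h0~ = S^-1/2 h0 S^-1/2``, hopping ``h0_ij = -t0 exp(-r_ij/r0)`` and
overlap ``S_ij = delta_ij + s0 exp(-r_ij/r0)``.  The MD potential adds a
pairwise core repulsion ``a_rep exp(-r/rho_rep)`` so that nuclear motion is
bound (the purely attractive band energy alone has no equilibrium
geometry).  The SCF iteration is plain aufbau diagonalization with linear
mixing; no convergence accelerator is used, so iteration counts respond
monotonically to guess quality instead of being masked by DIIS-style
extrapolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .descriptors import MolecularGeometry
from .manifold import OverlapFactor, grassmann_exp, lowdin_factor

__all__ = [
    "ToyModelSpec",
    "SCFResult",
    "SCFConvergenceError",
    "DegeneracyError",
    "build_h0",
    "build_overlap",
    "fock",
    "electronic_energy",
    "nuclear_repulsion",
    "assemble",
    "core_guess",
    "scf_solve",
    "total_energy",
    "forces",
    "subspace_trajectory",
    "chain_geometry",
]


class SCFConvergenceError(RuntimeError):
    """SCF fixed-point iteration did not converge."""


class DegeneracyError(RuntimeError):
    """HOMO-LUMO gap numerically zero; aufbau occupation ill defined."""


@dataclass(frozen=True)
class ToyModelSpec:
    """Toy-model parameters (energies in Hartree, lengths in Bohr).

    t0, r0   : hopping prefactor and decay length
    U        : on-site (Hubbard-like) density coupling
    s0       : overlap decay amplitude; must stay < 0.3 to keep S positive
               definite for non-pathological geometries
    a_rep,
    rho_rep  : pairwise core repulsion a_rep * exp(-r/rho_rep) entering the
               MD potential only (binds the nuclei; steeper than the hopping)
    """

    n_sites: int = 10
    N: int = 5
    t0: float = 1.0
    r0: float = 2.0
    U: float = 0.5
    s0: float = 0.1
    a_rep: float = 0.9
    rho_rep: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.N <= self.n_sites):
            raise ValueError("need 0 < N <= n_sites")
        if not (0 <= self.s0 < 0.3):
            raise ValueError("s0 must lie in [0, 0.3)")
        if self.U < 0:
            raise ValueError("U must be non-negative")


@dataclass
class SCFResult:
    """Converged density, electronic energy and iteration record."""

    density: np.ndarray
    energy: float
    iterations: int
    converged: bool
    rms_history: list = field(default_factory=list)


def build_h0(g: MolecularGeometry, spec: ToyModelSpec) -> np.ndarray:
    """Core Hamiltonian: off-diagonal hopping -t0 exp(-r/r0), zero diagonal."""
    r = g.pairwise_distances()
    h0 = -spec.t0 * np.exp(-r / spec.r0)
    np.fill_diagonal(h0, 0.0)
    return h0


def build_overlap(g: MolecularGeometry, spec: ToyModelSpec) -> np.ndarray:
    """Overlap: unit diagonal, s0 exp(-r/r0) off-diagonal; verified SPD."""
    r = g.pairwise_distances()
    S = spec.s0 * np.exp(-r / spec.r0)
    np.fill_diagonal(S, 1.0)
    if np.linalg.eigvalsh(S)[0] <= 0:
        raise ValueError("overlap matrix not positive definite: geometry too compressed")
    return S


def fock(D: np.ndarray, h0: np.ndarray, spec: ToyModelSpec) -> np.ndarray:
    """Mean-field operator ``F = h0 + U diag(D)``; depends on D's diagonal only."""
    F = h0.copy()
    F[np.diag_indices_from(F)] += spec.U * np.diag(D)
    return F


def electronic_energy(D: np.ndarray, h0: np.ndarray, spec: ToyModelSpec) -> float:
    """``E = tr(D h0) + (U/2) sum_i D_ii^2`` (orthonormal-basis quantities)."""
    d = np.diag(D)
    return float(np.einsum("ij,ji->", D, h0) + 0.5 * spec.U * (d @ d))


def nuclear_repulsion(g: MolecularGeometry, spec: ToyModelSpec) -> float:
    """Pairwise core repulsion; keeps the toy nuclei bound in MD."""
    r = g.pairwise_distances()
    iu = np.triu_indices(g.n_atoms, k=1)
    return float(spec.a_rep * np.exp(-r[iu] / spec.rho_rep).sum())


def assemble(g: MolecularGeometry, spec: ToyModelSpec) -> tuple[np.ndarray, OverlapFactor]:
    """Orthonormal-basis core Hamiltonian and Löwdin factors for a geometry."""
    S = build_overlap(g, spec)
    f = lowdin_factor(S)
    h0 = build_h0(g, spec)
    h0o = f.s_inv_half @ h0 @ f.s_inv_half
    return 0.5 * (h0o + h0o.T), f


def _aufbau(F: np.ndarray, N: int, gap_tol: float = 1e-10) -> np.ndarray:
    w, V = np.linalg.eigh(F)
    if N < len(w) and (w[N] - w[N - 1]) < gap_tol:
        raise DegeneracyError(
            f"HOMO-LUMO gap {w[N] - w[N - 1]:.3e} below {gap_tol:.1e}"
        )
    C = V[:, :N]
    return C @ C.T


def core_guess(g: MolecularGeometry, spec: ToyModelSpec,
               assembled: tuple | None = None) -> np.ndarray:
    """Default initial guess: aufbau density of the core Hamiltonian (U off)."""
    h0o, _ = assembled if assembled is not None else assemble(g, spec)
    return _aufbau(h0o, spec.N)


def scf_solve(
    guess: np.ndarray | None,
    g: MolecularGeometry,
    spec: ToyModelSpec,
    threshold: float = 1e-7,
    mixing: float = 0.6,
    max_iter: int = 200,
    assembled: tuple | None = None,
) -> SCFResult:
    """Fixed-point SCF iteration in the orthonormalized basis.

    Convergence is monitored as the RMS density change between successive
    aufbau densities, ``||D_k - D_{k-1}||_F / n < threshold``; ``iterations``
    counts Fock builds.  The returned density is the final aufbau projector
    (exactly idempotent).  A ``None`` guess falls back on the core guess.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if not (0 < mixing <= 1):
        raise ValueError("mixing must be in (0, 1]")
    h0o, _ = assembled if assembled is not None else assemble(g, spec)
    n = h0o.shape[0]
    if guess is None:
        guess = _aufbau(h0o, spec.N)
    D_mix = np.asarray(guess, float)
    D_prev_out = D_mix
    rms_history: list[float] = []
    converged = False
    iterations = 0
    for k in range(1, max_iter + 1):
        iterations = k
        F = fock(D_mix, h0o, spec)
        D_out = _aufbau(F, spec.N)
        rms = float(np.linalg.norm(D_out - D_prev_out) / n)
        rms_history.append(rms)
        if rms < threshold:
            converged = True
            D_mix = D_out
            break
        D_mix = (1.0 - mixing) * D_mix + mixing * D_out
        D_prev_out = D_out
    else:
        raise SCFConvergenceError(
            f"SCF did not reach RMS {threshold:.1e} in {max_iter} iterations "
            f"(last RMS {rms_history[-1]:.3e})"
        )
    energy = electronic_energy(D_out, h0o, spec)
    return SCFResult(D_out, energy, iterations, converged, rms_history)


def total_energy(result: SCFResult, g: MolecularGeometry, spec: ToyModelSpec) -> float:
    """Electronic energy plus core repulsion: the MD potential energy."""
    return result.energy + nuclear_repulsion(g, spec)


def forces(
    g: MolecularGeometry,
    spec: ToyModelSpec,
    D_converged: np.ndarray,
    threshold: float = 1e-7,
    mixing: float = 0.6,
    h: float = 1e-4,
    remove_net_force: bool = True,
    reconverge: bool = False,
) -> np.ndarray:
    """Central finite-difference forces of the total energy at ``D_converged``.

    By default the density is *frozen* at the converged value while the
    geometry is displaced (a Hellmann-Feynman-style gradient): because the
    SCF solution is variational, this converges to the exact
    Born-Oppenheimer force as the density converges, while its error is
    *linear* in the density's convergence error - exactly how analytic
    gradients behave in production codes, where a threshold-limited SCF
    leaks a guess-dependent bias into the forces.  With
    ``reconverge=True`` each displaced geometry is re-converged from
    ``D_converged`` at the given threshold instead (variational, hence
    quadratically insensitive to the convergence error, but ~60x the
    cost).

    The spurious net translational force (pure finite-difference noise;
    the energy is exactly translation invariant) is projected out by
    default so linear momentum is conserved in MD.
    """
    F = np.zeros_like(g.positions)
    for a in range(g.n_atoms):
        for c in range(3):
            e_pm = []
            for sgn in (+1.0, -1.0):
                pos = g.positions.copy()
                pos[a, c] += sgn * h
                g_d = g.with_positions(pos)
                if reconverge:
                    res = scf_solve(D_converged, g_d, spec,
                                    threshold=threshold, mixing=mixing)
                    e_pm.append(total_energy(res, g_d, spec))
                else:
                    h0o, _ = assemble(g_d, spec)
                    e_pm.append(electronic_energy(D_converged, h0o, spec)
                                + nuclear_repulsion(g_d, spec))
            F[a, c] = -(e_pm[0] - e_pm[1]) / (2.0 * h)
    if remove_net_force:
        F -= F.mean(axis=0)
    return F


def subspace_trajectory(
    ref: np.ndarray,
    tangent_dirs,
    amplitudes,
    frequencies,
    times,
    phases=None,
) -> list[np.ndarray]:
    """SCF-free smooth density trajectory on the Grassmann manifold.

    ``D(t) = Exp(sum_j a_j sin(w_j t + phi_j) Gamma_j)`` for tangent
    directions ``Gamma_j`` at the reference frame.  Every output is an
    exact projector; the generating tangent at each time is known exactly,
    which makes this the ground-truth fixture for extrapolation-accuracy
    tests.
    """
    tangent_dirs = [np.asarray(t, float) for t in tangent_dirs]
    if len(tangent_dirs) < 2:
        raise ValueError("need at least 2 tangent directions")
    amplitudes = np.asarray(amplitudes, float)
    frequencies = np.asarray(frequencies, float)
    if phases is None:
        phases = np.zeros_like(amplitudes)
    out = []
    for t in times:
        G = np.zeros_like(tangent_dirs[0])
        for a, w, p, T in zip(amplitudes, frequencies, phases, tangent_dirs):
            G += a * np.sin(w * t + p) * T
        out.append(grassmann_exp(G, ref))
    return out


def chain_geometry(
    n: int = 10,
    spacing: float = 2.6,
    disorder: float = 0.08,
    seed: int = 0,
) -> MolecularGeometry:
    """Standard fixture: an n-atom carbon-like chain with mild 3-D disorder.

    Spacing is in Bohr; the default spacing sits near the toy model's
    equilibrium bond length so NVE runs oscillate mildly instead of
    launching from a strained configuration.  Carbon-like nuclei (z = 6,
    m = 12 amu) give vibration periods of tens of fs, so a 0.5 fs time
    step resolves the motion the way production BOMD time steps do.
    """
    rng = np.random.default_rng(seed)
    pos = np.zeros((n, 3))
    pos[:, 0] = spacing * np.arange(n)
    pos += disorder * rng.uniform(-1.0, 1.0, size=(n, 3))
    return MolecularGeometry(pos, 6.0 * np.ones(n), ["C"] * n)
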