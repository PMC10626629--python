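"""Grassmann-manifold geometry for one-particle density matrices.

An idempotent, symmetric, rank-``N`` density matrix ``D`` in an orthonormal
basis is an orthogonal projector onto the occupied subspace, i.e. a point on
the Grassmann manifold Gr(N, n).  This module provides

* the Löwdin factorization ``S -> (S^1/2, S^-1/2)`` used to move between the
  atomic-orbital and orthonormal representations,
* conversions between orbital frames ``C`` (n x N, orthonormal columns) and
  densities ``D = C C^T``,
* the Grassmann exponential and logarithm at a fixed reference frame ``C0``,
  computed via thin SVD, which map between densities near the reference and
  the (flat) tangent space at the reference.

Tangent vectors are stored in the economical n x N representative form
``G`` with ``C0^T G = 0``.  Linear combinations of tangent vectors stay in
the tangent space, which is what makes linear extrapolation of densities
well defined once they are pulled back through the logarithm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LinearDependenceError",
    "NonOrthonormalInputError",
    "NonIdempotentDensityError",
    "OutOfInjectivityDomainError",
    "InvalidTangentError",
    "OverlapFactor",
    "lowdin_factor",
    "orthonormalize",
    "deorthonormalize",
    "density_from_frame",
    "frame_from_density",
    "grassmann_log",
    "grassmann_exp",
    "exp_frame",
    "make_reference",
    "save_checkpoint",
    "load_checkpoint",
]


class LinearDependenceError(ValueError):
    """Overlap matrix is numerically singular (linearly dependent basis)."""


class NonOrthonormalInputError(ValueError):
    """Input coefficients do not satisfy the expected orthonormality."""


class NonIdempotentDensityError(ValueError):
    """Matrix is not (numerically) an idempotent rank-N projector."""


class OutOfInjectivityDomainError(ValueError):
    """Density is outside the injectivity domain of the logarithm at C0."""


class InvalidTangentError(ValueError):
    """Matrix is not tangent at the reference frame."""


@dataclass(frozen=True)
class OverlapFactor:
    """Löwdin factors ``S^1/2`` and ``S^-1/2`` of an overlap matrix."""

    s_half: np.ndarray
    s_inv_half: np.ndarray


def lowdin_factor(S: np.ndarray, min_eig: float = 1e-10) -> OverlapFactor:
    """Symmetric (Löwdin) square root and inverse square root of ``S``.

    Both factors are obtained from a single symmetric eigendecomposition.
    Raises :class:`LinearDependenceError` if the smallest eigenvalue of
    ``S`` is at or below ``min_eig``.
    """
    S = np.asarray(S, dtype=float)
    if not np.allclose(S, S.T, atol=1e-10):
        raise ValueError("overlap matrix must be symmetric")
    w, V = np.linalg.eigh(S)
    if w[0] <= min_eig:
        raise LinearDependenceError(
            f"overlap matrix is near singular: smallest eigenvalue {w[0]:.3e} "
            f"<= {min_eig:.1e}"
        )
    sq = np.sqrt(w)
    s_half = (V * sq) @ V.T
    s_inv_half = (V / sq) @ V.T
    # Symmetrize away eigh roundoff so the OverlapFactor invariants are exact.
    return OverlapFactor(0.5 * (s_half + s_half.T), 0.5 * (s_inv_half + s_inv_half.T))


def orthonormalize(C_ao: np.ndarray, f: OverlapFactor, atol: float = 1e-8) -> np.ndarray:
    """Map S-orthonormal AO coefficients to an orthonormal frame ``C = S^1/2 C_ao``."""
    C_ao = np.asarray(C_ao, dtype=float)
    S = f.s_half @ f.s_half
    gram = C_ao.T @ S @ C_ao
    if not np.allclose(gram, np.eye(C_ao.shape[1]), atol=atol):
        raise NonOrthonormalInputError(
            "input coefficients are not S-orthonormal "
            f"(max deviation {np.abs(gram - np.eye(C_ao.shape[1])).max():.3e})"
        )
    return f.s_half @ C_ao


def deorthonormalize(C: np.ndarray, f: OverlapFactor) -> np.ndarray:
    """Inverse of :func:`orthonormalize`: ``C_ao = S^-1/2 C``."""
    return f.s_inv_half @ np.asarray(C, dtype=float)


def density_from_frame(C: np.ndarray, atol: float = 1e-8) -> np.ndarray:
    """Projector ``D = C C^T`` onto the span of the (orthonormal) columns of ``C``."""
    C = np.asarray(C, dtype=float)
    gram = C.T @ C
    if not np.allclose(gram, np.eye(C.shape[1]), atol=atol):
        raise NonOrthonormalInputError(
            "frame columns are not orthonormal "
            f"(max deviation {np.abs(gram - np.eye(C.shape[1])).max():.3e})"
        )
    return C @ C.T


def frame_from_density(D: np.ndarray) -> np.ndarray:
    """Orthonormal frame spanning the range of an idempotent projector ``D``.

    Columns are the eigenvectors with eigenvalue above 0.5.  Any eigenvalue
    inside the guard band [0.1, 0.9] signals a corrupted (non-idempotent)
    density and raises :class:`NonIdempotentDensityError`; converged SCF
    densities have eigenvalues at 0/1 to machine precision.
    """
    D = np.asarray(D, dtype=float)
    w, V = np.linalg.eigh(D)
    in_band = (w > 0.1) & (w < 0.9)
    if in_band.any():
        raise NonIdempotentDensityError(
            f"density has {int(in_band.sum())} eigenvalue(s) in [0.1, 0.9]; "
            "not an idempotent projector"
        )
    occ = w > 0.5
    n_occ = int(occ.sum())
    trace = float(np.trace(D))
    if abs(trace - n_occ) > 1e-6:
        raise NonIdempotentDensityError(
            f"occupied eigenvalue count {n_occ} inconsistent with trace {trace:.6f}"
        )
    return V[:, occ]


def make_reference(C0: np.ndarray) -> np.ndarray:
    """Freeze a frame as the run's immutable reference (read-only copy)."""
    ref = np.array(C0, dtype=float, copy=True)
    ref.setflags(write=False)
    return ref


def _project_tangent(G: np.ndarray, C0: np.ndarray) -> np.ndarray:
    return G - C0 @ (C0.T @ G)


def grassmann_log(D: np.ndarray, C0: np.ndarray, max_cond: float = 1e8) -> np.ndarray:
    """Grassmann logarithm of ``D`` at the reference frame ``C0``.

    With ``C`` any frame of ``D`` and ``M = C0^T C``, forms the thin SVD
    ``U S V^T`` of ``(I - C0 C0^T) C M^{-1}`` and returns
    ``G = U arctan(S) V^T``.  The result is gauge invariant (independent of
    the frame chosen for ``D``) and satisfies ``C0^T G = 0``.
    """
    C0 = np.asarray(C0, dtype=float)
    C = frame_from_density(D)
    M = C0.T @ C
    cond = np.linalg.cond(M)
    if not np.isfinite(cond) or cond > max_cond:
        raise OutOfInjectivityDomainError(
            f"subspace too far from the reference (cond(C0^T C) = {cond:.3e}); "
            "the logarithm is outside its injectivity domain - choose a new reference"
        )
    X = np.linalg.solve(M.T, C.T).T  # C M^{-1}
    P = X - C0 @ (C0.T @ X)
    U, s, Vt = np.linalg.svd(P, full_matrices=False)
    G = (U * np.arctan(s)) @ Vt
    # Re-project: guards against roundoff leaking a component along C0.
    return _project_tangent(G, C0)


def exp_frame(G: np.ndarray, C0: np.ndarray, atol: float = 1e-8) -> np.ndarray:
    """Orthonormal frame of ``Exp_C0(G)`` (see :func:`grassmann_exp`)."""
    C0 = np.asarray(C0, dtype=float)
    G = np.asarray(G, dtype=float)
    resid = np.abs(C0.T @ G).max() if G.size else 0.0
    if resid > atol:
        raise InvalidTangentError(
            f"matrix is not tangent at the reference (max |C0^T G| = {resid:.3e})"
        )
    # Exact projection makes the returned frame orthonormal to roundoff,
    # so Exp outputs are projectors by construction for any ||G||.
    G = _project_tangent(G, C0)
    U, s, Vt = np.linalg.svd(G, full_matrices=False)
    F = (C0 @ Vt.T) * np.cos(s) + U * np.sin(s)
    return F @ Vt


def grassmann_exp(G: np.ndarray, C0: np.ndarray, atol: float = 1e-8) -> np.ndarray:
    """Grassmann exponential: maps a tangent vector at ``C0`` to a density.

    With the thin SVD ``G = U S V^T``, the frame of the result is
    ``(C0 V cos S + U sin S) V^T`` and the density is its projector.
    """
    F = exp_frame(G, C0, atol=atol)
    return F @ F.T


def save_checkpoint(path, C0: np.ndarray, history) -> None:
    """Write reference frame and extrapolation history to an HDF5 container.

    Layout: ``/reference/C0`` plus ``/history/step_<k>/gamma`` and
    ``/history/step_<k>/descriptor`` per entry.
    """
    import h5py

    with h5py.File(path, "w") as fh:
        fh.create_dataset("reference/C0", data=np.asarray(C0, dtype=float))
        for step, gamma, descriptor in history:
            grp = fh.create_group(f"history/step_{step}")
            grp.create_dataset("gamma", data=np.asarray(gamma, dtype=float))
            grp.create_dataset("descriptor", data=np.asarray(descriptor, dtype=float))


def load_checkpoint(path):
    """Inverse of :func:`save_checkpoint`; history is sorted by step index."""
    import h5py

    with h5py.File(path, "r") as fh:
        C0 = make_reference(fh["reference/C0"][()])
        entries = []
        if "history" in fh:
            for name in fh["history"]:
                step = int(name.split("_", 1)[1])
                grp = fh["history"][name]
                entries.append((step, grp["gamma"][()], grp["descriptor"][()]))
        entries.sort(key=lambda e: e[0])
    return C0, entries
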