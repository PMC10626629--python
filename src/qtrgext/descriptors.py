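"""Coulomb-matrix molecular descriptors.

The map from nuclear configuration to descriptor vector is the first leg of
the composed extrapolation map  R -> d -> Gamma -> D.  The Coulomb matrix

    M_kl = z_k z_l / |R_k - R_l|   (k != l),      M_kk = 0.5 z_k^2.4,

is invariant under rigid rotations and translations of the geometry; its
vectorized lower triangle (row-major, diagonal included) is the descriptor.
Within a single MD run the atom ordering is fixed, so no permutation
canonicalization is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .units import ATOMIC_MASSES, BOHR_PER_ANGSTROM, ELEMENT_NUMBERS

__all__ = [
    "DegenerateGeometryError",
    "MolecularGeometry",
    "coulomb_matrix",
    "vectorize_lower",
    "descriptor",
    "read_xyz",
    "write_xyz",
]

MIN_DISTANCE = 1e-6  # Bohr; below this two nuclei are considered coincident


class DegenerateGeometryError(ValueError):
    """Two nuclei (numerically) coincide."""


@dataclass
class MolecularGeometry:
    """Nuclear configuration in atomic units.

    positions : (N, 3) array, Bohr
    charges   : (N,) positive nuclear charges
    symbols   : element labels (informational; charges drive the physics)
    """

    positions: np.ndarray
    charges: np.ndarray
    symbols: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        self.charges = np.asarray(self.charges, dtype=float).ravel()
        if len(self.charges) != len(self.positions):
            raise ValueError("positions and charges length mismatch")
        if np.any(self.charges <= 0):
            raise ValueError("nuclear charges must be positive")
        if not self.symbols:
            self.symbols = ["X"] * len(self.charges)
        d = self.pairwise_distances()
        n = len(self.charges)
        if n > 1 and d[np.triu_indices(n, k=1)].min() <= MIN_DISTANCE:
            raise DegenerateGeometryError("coincident nuclei in geometry")

    @property
    def n_atoms(self) -> int:
        return len(self.charges)

    def pairwise_distances(self) -> np.ndarray:
        diff = self.positions[:, None, :] - self.positions[None, :, :]
        return np.sqrt((diff**2).sum(axis=-1))

    def masses(self) -> np.ndarray:
        """Atomic masses (amu) looked up from the element labels."""
        return np.array([ATOMIC_MASSES.get(s, 1.0) for s in self.symbols])

    def with_positions(self, positions: np.ndarray) -> "MolecularGeometry":
        return MolecularGeometry(positions, self.charges, list(self.symbols))


def coulomb_matrix(g: MolecularGeometry) -> np.ndarray:
    """Coulomb matrix of a geometry (atomic units)."""
    r = g.pairwise_distances()
    n = g.n_atoms
    z = g.charges
    with np.errstate(divide="ignore"):
        M = np.where(r > 0, np.outer(z, z) / np.where(r > 0, r, 1.0), 0.0)
    np.fill_diagonal(M, 0.5 * z**2.4)
    return M


def vectorize_lower(M: np.ndarray, atol: float = 1e-10) -> np.ndarray:
    """Row-major vectorization of the lower triangle (diagonal included).

    For an N x N symmetric matrix the result has length N(N+1)/2.
    """
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("expected a square matrix")
    if np.abs(M - M.T).max() > atol:
        raise ValueError("matrix is not symmetric")
    idx = np.tril_indices(M.shape[0])
    return M[idx]


def descriptor(g: MolecularGeometry) -> np.ndarray:
    """Descriptor vector d(R): vectorized lower triangle of the Coulomb matrix."""
    return vectorize_lower(coulomb_matrix(g))


def read_xyz(path) -> MolecularGeometry:
    """Read a standard XYZ file (element symbol + Angstrom coordinates)."""
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip() or True]
    n = int(lines[0].split()[0])
    atoms = lines[2 : 2 + n]
    symbols, pos = [], []
    for ln in atoms:
        parts = ln.split()
        symbols.append(parts[0])
        pos.append([float(x) for x in parts[1:4]])
    try:
        charges = [float(ELEMENT_NUMBERS[s]) for s in symbols]
    except KeyError as exc:
        raise ValueError(f"unsupported element symbol {exc} (Z <= 54 supported)")
    return MolecularGeometry(np.array(pos) * BOHR_PER_ANGSTROM, charges, symbols)


def write_xyz(path, g: MolecularGeometry, comment: str = "") -> None:
    """Write a geometry as standard XYZ (Angstrom)."""
    ang = g.positions / BOHR_PER_ANGSTROM
    with open(path, "w") as fh:
        fh.write(f"{g.n_atoms}\n{comment}\n")
        for s, (x, y, z) in zip(g.symbols, ang):
            fh.write(f"{s} {x:.12f} {y:.12f} {z:.12f}\n")
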