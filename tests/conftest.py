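"""Shared fixtures.

The expensive multi-engine NVE comparison runs are session-scoped so the
ordering/stability checks and the guess-validity sweep all reuse the same
trajectories.
"""

from __future__ import annotations

import numpy as np
import pytest

from qtrgext.descriptors import MolecularGeometry
from qtrgext.manifold import density_from_frame, make_reference
from qtrgext.md import MDConfig, run_bomd
from qtrgext.toy import ToyModelSpec, chain_geometry


def random_frame(rng, n, N):
    """Random orthonormal n x N frame (QR of a Gaussian matrix)."""
    Q, _ = np.linalg.qr(rng.normal(size=(n, N)))
    return Q


def random_tangent(rng, C0, scale=0.1):
    """Random tangent vector at C0 with singular values below ``scale``."""
    n, N = C0.shape
    G = rng.normal(size=(n, N))
    G -= C0 @ (C0.T @ G)
    s = np.linalg.svd(G, compute_uv=False).max()
    return G * (scale / s)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def chain():
    """Standard 10-atom chain fixture and toy-model parameters."""
    return chain_geometry(seed=7), ToyModelSpec()


@pytest.fixture(scope="session")
def comparison_runs():
    """2000-step NVE runs: engines x thresholds {1e-5, 1e-7} x seeds {1,2,3}."""
    geom = chain_geometry(seed=7)
    spec = ToyModelSpec()
    runs = {}
    for thr in (1e-5, 1e-7):
        for strat in ("qtr", "gext", "xlbo"):
            for seed in (1, 2, 3):
                cfg = MDConfig(n_steps=2000, threshold=thr, seed=seed, strategy=strat)
                result = run_bomd(geom, cfg, spec)
                assert not result.aborted, result.abort_reason
                runs[(strat, thr, seed)] = result
        # fully time-reversible variant: one seed (guess-validity coverage)
        cfg = MDConfig(n_steps=2000, threshold=thr, seed=1, strategy="fully_tr")
        result = run_bomd(geom, cfg, spec)
        assert not result.aborted, result.abort_reason
        runs[("fully_tr", thr, 1)] = result
    return runs


@pytest.fixture(scope="session")
def tight_runs():
    """2000-step NVE runs at a machine-tight SCF threshold (1e-13), seed 1."""
    geom = chain_geometry(seed=7)
    spec = ToyModelSpec()
    runs = {}
    for strat in ("qtr", "gext", "xlbo"):
        cfg = MDConfig(n_steps=2000, threshold=1e-13, seed=1, strategy=strat)
        result = run_bomd(geom, cfg, spec)
        assert not result.aborted, result.abort_reason
        runs[strat] = result
    return runs
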