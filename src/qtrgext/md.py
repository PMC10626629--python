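"""NVE Born-Oppenheimer dynamics with pluggable SCF guess engines.

Velocity Verlet integration of the toy electronic-structure model: at every
step the electronic problem is fully converged (that is what makes the
dynamics Born-Oppenheimer), the converged tangent/descriptor pair is handed
to the guess engine, and the number of SCF iterations is logged.  Total
energy (potential + kinetic) series from these logs feed the stability
diagnostics (short-time fluctuation, long-time drift).

Units: Bohr, fs, amu, Hartree (see :mod:`qtrgext.units`).  Velocity
initialization is Maxwell-Boltzmann with the center-of-mass momentum
removed (angular momentum is not removed; runs are short).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .descriptors import MolecularGeometry, descriptor
from .engines import GuessEngine, make_engine
from .toy import ToyModelSpec, core_guess, forces, scf_solve, total_energy
from .units import KB_HARTREE, KINETIC_TO_HARTREE

__all__ = [
    "MDConfig",
    "MDState",
    "StepLog",
    "RunResult",
    "init_velocities",
    "velocity_verlet_step",
    "kinetic_energy",
    "run_bomd",
    "reverse_run",
]


@dataclass(frozen=True)
class MDConfig:
    """Run configuration for an NVE trajectory."""

    dt: float = 0.5               # fs
    n_steps: int = 100
    threshold: float = 1e-5       # SCF RMS convergence threshold
    temperature_init: float = 300.0  # K
    seed: int = 0
    strategy: str = "qtr"         # qtr | fully_tr | gext | xlbo | previous
    mixing: float = 0.6
    q: int | None = None          # None -> threshold-dependent default
    epsilon: float | None = None
    purify_xlbo: bool = True

    def __post_init__(self):
        if self.dt <= 0 or self.n_steps < 1:
            raise ValueError("need dt > 0 and n_steps >= 1")


@dataclass
class MDState:
    """Nuclear phase-space point (Bohr, Bohr/fs, amu)."""

    positions: np.ndarray
    velocities: np.ndarray
    masses: np.ndarray
    step: int = 0


@dataclass
class StepLog:
    """Per-step record: energies (Hartree), SCF cost, guess diagnostics."""

    step: int
    time: float
    potential_energy: float
    kinetic_energy: float
    total_energy: float
    scf_iterations: int
    converged: bool
    cold_start: bool
    guess_idem_error: float = np.nan   # max |D_g^2 - D_g| of the engine guess
    guess_trace_error: float = np.nan  # |tr D_g - N|
    guess_density_error: float = np.nan  # Frobenius ||D_g - D_converged||


@dataclass
class RunResult:
    """Logs plus the trajectory and final phase-space point of a run."""

    logs: list
    positions: np.ndarray      # (n_logged, N, 3) positions at each logged step
    final_state: MDState
    config: MDConfig
    aborted: bool = False
    abort_reason: str = ""


def kinetic_energy(velocities: np.ndarray, masses: np.ndarray) -> float:
    """Kinetic energy in Hartree for velocities in Bohr/fs, masses in amu."""
    return float(0.5 * KINETIC_TO_HARTREE * np.sum(masses[:, None] * velocities**2))


def init_velocities(masses: np.ndarray, temperature: float, seed) -> np.ndarray:
    """Maxwell-Boltzmann velocities (Bohr/fs) with COM momentum removed.

    ``seed`` may be an int or a :class:`numpy.random.Generator`.  At T = 0
    all velocities are exactly zero.
    """
    if temperature < 0:
        raise ValueError("temperature must be non-negative")
    masses = np.asarray(masses, float)
    if temperature == 0:
        return np.zeros((len(masses), 3))
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sigma = np.sqrt(KB_HARTREE * temperature / (KINETIC_TO_HARTREE * masses))
    v = rng.normal(size=(len(masses), 3)) * sigma[:, None]
    p = (masses[:, None] * v).sum(axis=0)
    v -= p / masses.sum()
    return v


def velocity_verlet_step(state: MDState, F: np.ndarray, forces_fn, dt: float):
    """One kick-drift-kick velocity Verlet update.

    ``F`` are the forces (Hartree/Bohr) at the current positions and
    ``forces_fn(positions) -> forces`` evaluates them at the drifted ones.
    Returns ``(new_state, new_forces)``.  The update is exactly
    time-reversible for deterministic forces.
    """
    m = state.masses[:, None] * KINETIC_TO_HARTREE  # Hartree fs^2 / Bohr^2
    v_half = state.velocities + 0.5 * dt * F / m
    r_new = state.positions + dt * v_half
    F_new = forces_fn(r_new)
    v_new = v_half + 0.5 * dt * F_new / m
    return MDState(r_new, v_new, state.masses, state.step + 1), F_new


class _BOMDForces:
    """Converges the SCF at a geometry (via the guess engine) and differentiates."""

    def __init__(self, template: MolecularGeometry, cfg: MDConfig,
                 spec: ToyModelSpec, engine: GuessEngine):
        self.template = template
        self.cfg = cfg
        self.spec = spec
        self.engine = engine
        self.last: dict = {}

    def solve_at(self, positions: np.ndarray) -> MolecularGeometry:
        g = self.template.with_positions(positions)
        d_n = descriptor(g)
        step = self.last.get("step", -1) + 1
        guess = self.engine.propose(step, d_n)
        cold = guess is None
        if cold:
            guess = self.last.get("density")  # previous converged density, if any
        res = scf_solve(guess, g, self.spec, threshold=self.cfg.threshold,
                        mixing=self.cfg.mixing)
        if guess is not None and not cold:
            D_g = np.asarray(guess)
            idem = float(np.abs(D_g @ D_g - D_g).max())
            trace_err = float(abs(np.trace(D_g) - self.spec.N))
            dens_err = float(np.linalg.norm(D_g - res.density))
        else:
            idem = trace_err = dens_err = np.nan
        self.engine.observe(step, res.density, d_n)
        self.last = {
            "step": step, "geometry": g, "density": res.density,
            "result": res, "cold": cold, "idem": idem,
            "trace_err": trace_err, "dens_err": dens_err,
            "epot": total_energy(res, g, self.spec),
        }
        return g

    def __call__(self, positions: np.ndarray) -> np.ndarray:
        g = self.solve_at(positions)
        return forces(g, self.spec, self.last["density"],
                      threshold=self.cfg.threshold, mixing=self.cfg.mixing)


def run_bomd(
    g0: MolecularGeometry,
    cfg: MDConfig,
    spec: ToyModelSpec,
    engine: GuessEngine | None = None,
    velocities: np.ndarray | None = None,
) -> RunResult:
    """NVE Born-Oppenheimer trajectory from geometry ``g0``.

    Per step: the guess engine proposes a density (falling back on the
    previous converged density, then the core guess, on cold start), the
    SCF is converged, forces are evaluated by finite differences, and the
    state is Verlet-updated.  Only converged densities enter the history;
    an SCF failure aborts the run cleanly with the partial logs flushed.
    """
    if engine is None:
        engine = make_engine(cfg.strategy, threshold=cfg.threshold,
                             q=cfg.q, epsilon=cfg.epsilon,
                             purify_xlbo=cfg.purify_xlbo)
    masses = g0.masses()
    if velocities is None:
        velocities = init_velocities(masses, cfg.temperature_init, cfg.seed)
    state = MDState(g0.positions.copy(), np.asarray(velocities, float), masses, 0)
    driver = _BOMDForces(g0, cfg, spec, engine)
    logs: list[StepLog] = []
    positions = np.empty((cfg.n_steps, g0.n_atoms, 3))
    aborted = False
    reason = ""
    try:
        F = driver(state.positions)
        for k in range(cfg.n_steps):
            info = driver.last
            ekin = kinetic_energy(state.velocities, masses)
            epot = info["epot"]
            etot = epot + ekin
            if not np.isfinite(etot):
                raise FloatingPointError(f"non-finite total energy at step {k}")
            logs.append(StepLog(
                step=k, time=k * cfg.dt,
                potential_energy=epot, kinetic_energy=ekin, total_energy=etot,
                scf_iterations=info["result"].iterations,
                converged=info["result"].converged,
                cold_start=info["cold"],
                guess_idem_error=info["idem"],
                guess_trace_error=info["trace_err"],
                guess_density_error=info["dens_err"],
            ))
            positions[k] = state.positions
            state, F = velocity_verlet_step(state, F, driver, cfg.dt)
    except (RuntimeError, FloatingPointError, ValueError) as exc:
        aborted = True
        reason = f"{type(exc).__name__}: {exc}"
        positions = positions[: len(logs)]
    return RunResult(logs, positions[: len(logs)], state, cfg, aborted, reason)


def reverse_run(
    result: RunResult,
    g0: MolecularGeometry,
    spec: ToyModelSpec,
    engine: GuessEngine | None = None,
) -> float:
    """Retrace diagnostic: integrate backward from the final state.

    Negates the final velocities, integrates the same number of steps with
    a fresh engine of the same strategy, and returns the maximum position
    deviation from the forward trajectory read in reverse.  Near-zero for
    exactly time-reversible force evaluation.
    """
    cfg = result.config
    state = result.final_state
    back = run_bomd(
        g0.with_positions(state.positions.copy()),
        cfg,
        spec,
        engine=engine or make_engine(cfg.strategy, threshold=cfg.threshold,
                                     q=cfg.q, epsilon=cfg.epsilon,
                                     purify_xlbo=cfg.purify_xlbo),
        velocities=-state.velocities,
    )
    if back.aborted:
        raise RuntimeError(f"reverse run aborted: {back.abort_reason}")
    # Backward step k lands where the forward run stood n_steps-1-k steps in;
    # backward positions[0] is the final forward state's position (not logged
    # forward), so compare positions[1:] against forward logs reversed.
    n = cfg.n_steps
    fwd = result.positions
    bwd = back.positions
    devs = [np.abs(bwd[k] - fwd[n - k]).max() for k in range(1, n)]
    return float(max(devs))
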