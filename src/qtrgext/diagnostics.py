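"""Stability and performance diagnostics for NVE runs.

Two energy-stability metrics summarize a total-energy series E(t):

* STF (short-time fluctuation): the trajectory is cut into consecutive,
  non-overlapping windows (default 50 fs, anchored at the first logged
  time; a trailing partial window is dropped); within each window the RMS
  deviation from the window mean is taken, and the window values are
  averaged.
* LTD (long-time drift): the ordinary-least-squares slope of E against t
  over the whole series (energy per fs here).

SCF cost is summarized as the mean and population standard deviation of
the per-step iteration counts, discarding the first q steps (and any
cold-start steps), since every engine needs q converged densities before
it can extrapolate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .units import BOHR_PER_ANGSTROM

__all__ = [
    "EnergySeries",
    "StabilityReport",
    "stf",
    "ltd",
    "iteration_stats",
    "moving_average",
    "analyze",
    "compare_report",
    "render_table",
    "logs_to_dataframe",
    "write_logs_csv",
    "read_logs_csv",
    "write_extxyz",
]

LOG_COLUMNS = [
    "step", "time_fs", "epot", "ekin", "etot",
    "scf_iterations", "converged", "cold_start",
    "guess_idem_error", "guess_trace_error", "guess_density_error",
]


@dataclass(frozen=True)
class EnergySeries:
    """Total-energy time series (fs, consistent energy units)."""

    times: np.ndarray
    total_energies: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, float)
        e = np.asarray(self.total_energies, float)
        if len(t) != len(e):
            raise ValueError("times and energies must have equal length")
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "total_energies", e)


@dataclass(frozen=True)
class StabilityReport:
    """STF/LTD plus iteration statistics of one run."""

    stf: float
    ltd: float
    n_windows: int
    mean_iterations: float
    std_iterations: float


def stf(series: EnergySeries, window: float = 50.0) -> float:
    """Average windowed RMS energy fluctuation (see module docstring)."""
    t, e = series.times, series.total_energies
    if len(t) == 0 or t[-1] - t[0] < window:
        raise ValueError(f"series spans less than one {window} fs window")
    idx = np.floor((t - t[0]) / window).astype(int)
    values = []
    for w in range(idx.max() + 1):
        sel = e[idx == w]
        t_sel = t[idx == w]
        if t_sel.size == 0:
            continue
        # only full windows count
        if (w + 1) * window > (t[-1] - t[0]) + 1e-12:
            break
        values.append(np.sqrt(np.mean((sel - sel.mean()) ** 2)))
    return float(np.mean(values))


def _n_full_windows(series: EnergySeries, window: float = 50.0) -> int:
    return int((series.times[-1] - series.times[0] + 1e-12) // window)


def ltd(series: EnergySeries) -> float:
    """OLS slope of total energy vs time (energy / fs)."""
    t, e = series.times, series.total_energies
    if len(t) < 2:
        raise ValueError("need at least two points for a drift estimate")
    slope, _ = np.polyfit(t, e, 1)
    return float(slope)


def iteration_stats(logs, q: int) -> tuple[float, float]:
    """Mean and population std of SCF iterations, discarding warm-up.

    Steps with index < q or flagged as cold starts are excluded.
    """
    counts = [lg.scf_iterations for lg in logs if lg.step >= q and not lg.cold_start]
    if not counts:
        raise ValueError("no eligible steps after discarding the warm-up")
    counts = np.asarray(counts, float)
    return float(counts.mean()), float(counts.std())  # ddof=0: population std


def moving_average(values, window: int) -> np.ndarray:
    """Centered moving average with shrinking edge windows (same length out)."""
    if window < 1:
        raise ValueError("window must be >= 1")
    s = pd.Series(np.asarray(values, float))
    return s.rolling(window, center=True, min_periods=1).mean().to_numpy()


def _series_from_logs(logs) -> EnergySeries:
    return EnergySeries(
        np.array([lg.time for lg in logs]),
        np.array([lg.total_energy for lg in logs]),
    )


def analyze(logs, q: int = 5, window: float = 50.0) -> StabilityReport:
    """Full stability report of one run's logs."""
    series = _series_from_logs(logs)
    mean, std = iteration_stats(logs, q)
    return StabilityReport(
        stf=stf(series, window), ltd=ltd(series),
        n_windows=_n_full_windows(series, window),
        mean_iterations=mean, std_iterations=std,
    )


def compare_report(runs: dict, q: int = 5, window: float = 50.0) -> pd.DataFrame:
    """One row of stability/cost metrics per strategy.

    ``runs`` maps a strategy label to its list of step logs.  Runs with
    inconsistent lengths are compared on their common prefix (with a
    warning).
    """
    import warnings

    if not runs:
        raise ValueError("need at least one run")
    lengths = {k: len(v) for k, v in runs.items()}
    n = min(lengths.values())
    if len(set(lengths.values())) > 1:
        warnings.warn(
            f"runs have different lengths {lengths}; comparing first {n} steps",
            stacklevel=2,
        )
    rows = []
    for label, logs in runs.items():
        rep = analyze(logs[:n], q=q, window=window)
        rows.append({
            "strategy": label, "stf": rep.stf, "ltd": rep.ltd,
            "n_windows": rep.n_windows,
            "mean_iterations": rep.mean_iterations,
            "std_iterations": rep.std_iterations,
        })
    return pd.DataFrame(rows).set_index("strategy")


def render_table(df: pd.DataFrame) -> str:
    """Aligned text rendering of a comparison table."""
    return df.to_string(float_format=lambda x: f"{x:.6g}")


def logs_to_dataframe(logs) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "step": [lg.step for lg in logs],
            "time_fs": [lg.time for lg in logs],
            "epot": [lg.potential_energy for lg in logs],
            "ekin": [lg.kinetic_energy for lg in logs],
            "etot": [lg.total_energy for lg in logs],
            "scf_iterations": [lg.scf_iterations for lg in logs],
            "converged": [lg.converged for lg in logs],
            "cold_start": [lg.cold_start for lg in logs],
            "guess_idem_error": [lg.guess_idem_error for lg in logs],
            "guess_trace_error": [lg.guess_trace_error for lg in logs],
            "guess_density_error": [lg.guess_density_error for lg in logs],
        }
    )


def write_logs_csv(path, logs) -> None:
    logs_to_dataframe(logs).to_csv(path, index=False, float_format="%.17g")


def read_logs_csv(path):
    """Read a per-step log CSV back into StepLog records."""
    from .md import StepLog

    df = pd.read_csv(path, float_precision="round_trip")
    return [
        StepLog(
            step=int(r.step), time=float(r.time_fs),
            potential_energy=float(r.epot), kinetic_energy=float(r.ekin),
            total_energy=float(r.etot),
            scf_iterations=int(r.scf_iterations),
            converged=bool(r.converged), cold_start=bool(r.cold_start),
            guess_idem_error=float(r.guess_idem_error),
            guess_trace_error=float(r.guess_trace_error),
            guess_density_error=float(r.guess_density_error),
        )
        for r in df.itertuples()
    ]


def write_extxyz(path, symbols, positions_series, logs) -> None:
    """Extended-XYZ trajectory (Angstrom; comment carries step, time, energy)."""
    with open(path, "w") as fh:
        for pos, lg in zip(positions_series, logs):
            ang = np.asarray(pos) / BOHR_PER_ANGSTROM
            fh.write(f"{len(symbols)}\n")
            fh.write(f"step={lg.step} time_fs={lg.time:.6f} etot={lg.total_energy:.12f}\n")
            for s, (x, y, z) in zip(symbols, ang):
                fh.write(f"{s} {x:.10f} {y:.10f} {z:.10f}\n")
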