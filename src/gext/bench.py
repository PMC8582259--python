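"""Evaluation protocol: SCF-iteration statistics and NVE stability metrics.

Guess strategies are compared by the mean and standard deviation of per-step
SCF iteration counts after discarding a warm-up (8 steps by default, so every
strategy is past its own history build-up), and trajectories are judged by
two total-energy stability numbers:

* STF (short-time fluctuation): the trajectory is cut into consecutive,
  non-overlapping 50 fs windows (after discarding the first 500 fs); within
  each complete window the RMS deviation of the energy from the window mean
  is taken, and the window values are averaged.
* LTD (long-time drift): the slope of an ordinary least-squares linear fit
  of energy vs. time on the same post-discard data, reported per ps.

Standard deviations are population (divide by N) throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .engine import (
    HARTREE_TO_KCALMOL,
    ModelParameters,
    ProbeResult,
    generate_trajectory,
    make_strategy,
    probe_guess_strategy,
)

DEFAULT_DISCARD_STEPS = 8
DEFAULT_WINDOW_FS = 50.0
DEFAULT_DISCARD_FS = 500.0


@dataclass(frozen=True)
class EnergySeries:
    """A uniformly sampled total-energy series with a unit tag."""

    times: np.ndarray  # fs, strictly increasing, uniform
    energies: np.ndarray
    unit: str = "kcal/mol"

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        e = np.asarray(self.energies, dtype=float)
        if t.ndim != 1 or t.shape != e.shape or t.size < 2:
            raise ValueError("times and energies must be equal-length 1-D, >= 2 points")
        dt = np.diff(t)
        if np.any(dt <= 0) or np.max(np.abs(dt - dt[0])) > 1e-9:
            raise ValueError("times must be strictly increasing with uniform spacing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "energies", e)

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])


@dataclass(frozen=True)
class IterationRecord:
    """Per-step SCF iteration counts for one guess strategy and tolerance."""

    counts: np.ndarray
    label: str = ""
    r_scf: float = np.nan

    def __post_init__(self):
        c = np.asarray(self.counts, dtype=int)
        if c.ndim != 1 or np.any(c < 1):
            raise ValueError("iteration counts must be a 1-D array of positive integers")
        object.__setattr__(self, "counts", c)


def iteration_stats(
    rec: IterationRecord | np.ndarray, n_discard: int = DEFAULT_DISCARD_STEPS
) -> tuple[float, float]:
    """Mean and population standard deviation of the post-warm-up counts."""
    counts = rec.counts if isinstance(rec, IterationRecord) else np.asarray(rec)
    if len(counts) <= n_discard:
        raise ValueError(
            f"need more than n_discard={n_discard} counts, got {len(counts)}"
        )
    kept = np.asarray(counts[n_discard:], dtype=float)
    return float(np.mean(kept)), float(np.std(kept))


def short_time_fluctuation(
    s: EnergySeries,
    window_fs: float = DEFAULT_WINDOW_FS,
    discard_fs: float = DEFAULT_DISCARD_FS,
) -> float:
    """Average windowed RMS energy fluctuation (same unit as the series)."""
    keep = s.times >= s.times[0] + discard_fs
    e = s.energies[keep]
    per_window = max(1, int(round(window_fs / s.dt)))
    n_windows = len(e) // per_window
    if n_windows < 1:
        raise ValueError(
            f"series too short: no complete {window_fs} fs window after "
            f"discarding {discard_fs} fs"
        )
    w = e[: n_windows * per_window].reshape(n_windows, per_window)
    rms = np.sqrt(np.mean((w - w.mean(axis=1, keepdims=True)) ** 2, axis=1))
    return float(np.mean(rms))


def long_time_drift(
    s: EnergySeries, discard_fs: float = DEFAULT_DISCARD_FS
) -> float:
    """OLS slope of energy vs. time on post-discard data, per *ps*."""
    keep = s.times >= s.times[0] + discard_fs
    t = s.times[keep]
    e = s.energies[keep]
    if len(t) < 2:
        raise ValueError("need at least 2 post-discard points for the drift fit")
    if np.ptp(t) == 0:
        raise ValueError("degenerate time axis")
    slope_per_fs = np.polyfit(t, e, 1)[0]
    return float(slope_per_fs * 1000.0)


# ---------------------------------------------------------------------------
# multi-strategy benchmark driver
# ---------------------------------------------------------------------------


@dataclass
class BenchConfig:
    """Configuration of a guess-strategy comparison run."""

    template: str = "chain6"
    n_steps: int = 2000
    dt: float = 0.5  # fs
    seed: int = 0
    temperature: float = 300.0  # K
    strategies: list = field(
        default_factory=lambda: ["core", "previous", "gext3", "gext6"]
    )
    tolerances: list = field(default_factory=lambda: [1e-5, 1e-7])
    epsilon: float | None = None  # None -> 1e3 * r_scf
    n_discard: int = DEFAULT_DISCARD_STEPS
    window_fs: float = DEFAULT_WINDOW_FS
    discard_fs: float = DEFAULT_DISCARD_FS
    force_tol: float = 1e-9
    params: ModelParameters | None = None

    @classmethod
    def from_dict(cls, d: dict) -> "BenchConfig":
        d = dict(d)
        if "params" in d and isinstance(d["params"], dict):
            d["params"] = ModelParameters(**d["params"])
        return cls(**d)


@dataclass
class BenchmarkReport:
    """Per-(strategy, tolerance) summary table plus raw probe records."""

    table: pd.DataFrame
    probes: dict  # (strategy, r_scf) -> ProbeResult
    config: BenchConfig

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def __str__(self) -> str:
        return self.table.to_string(
            index=False,
            formatters={
                "mean_iterations": "{:.2f}".format,
                "sigma": "{:.2f}".format,
                "stf_kcalmol": "{:.4f}".format,
                "ltd_kcalmol_per_ps": "{:+.4f}".format,
            },
        )


def probe_to_energy_series(probe: ProbeResult, dt: float) -> EnergySeries:
    """Total-energy series (kcal/mol) of a probe run."""
    t = dt * np.arange(len(probe.total_energies))
    return EnergySeries(t, probe.total_energies * HARTREE_TO_KCALMOL, "kcal/mol")


def run_benchmark(config: BenchConfig) -> BenchmarkReport:
    """Compare guess strategies on trajectories from identical initial conditions.

    The propagation uses tightly converged finite-difference forces, so the
    per-strategy trajectories launched from one seed coincide exactly; the
    trajectory is therefore generated once and every (strategy, tolerance)
    pair is probed along it.  Deterministic for a fixed seed.
    """
    traj = generate_trajectory(
        template=config.template,
        n_steps=config.n_steps,
        dt=config.dt,
        seed=config.seed,
        temperature=config.temperature,
        params=config.params,
        force_tol=config.force_tol,
        store_densities=False,
    )
    rows = []
    probes = {}
    for r_scf in config.tolerances:
        for name in config.strategies:
            strategy = make_strategy(name, r_scf, epsilon=config.epsilon)
            probe = probe_guess_strategy(traj, strategy, r_scf)
            probes[(name, r_scf)] = probe
            mean, sigma = iteration_stats(probe.iterations, config.n_discard)
            series = probe_to_energy_series(probe, config.dt)
            duration = config.n_steps * config.dt
            if duration > config.discard_fs + config.window_fs:
                stf = short_time_fluctuation(series, config.window_fs, config.discard_fs)
                ltd = long_time_drift(series, config.discard_fs)
            else:  # short smoke runs: use the whole series
                stf = short_time_fluctuation(series, duration / 4, 0.0)
                ltd = long_time_drift(series, 0.0)
            rows.append(
                {
                    "strategy": name,
                    "r_scf": r_scf,
                    "mean_iterations": mean,
                    "sigma": sigma,
                    "stf_kcalmol": stf,
                    "ltd_kcalmol_per_ps": ltd,
                }
            )
    return BenchmarkReport(table=pd.DataFrame(rows), probes=probes, config=config)
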