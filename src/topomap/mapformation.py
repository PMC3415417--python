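"""Map-formation time detection, trials, and learning-region sweeps.

A trial asks whether the coactivity of one simulated place-cell ensemble,
observed along an exploratory trajectory, recovers the topology of the
arena.  The Betti numbers of the growing temporal complex are traced at
every coactivity-window boundary; the minimal map-formation time T_min is
the earliest moment after which both b0 and b1 equal the arena's
ground-truth values and stay correct through the end of the observation
period.  A trial with no such moment is a failure.

Sweeping the three ensemble parameters (rate mode f_mode, field-size mode
s_mode, cell count N) over a grid, with several seeded repetitions per
cell, maps out the learning region L: the set of ensemble states that form
correct maps quickly, reliably (high success fraction) and stably (low
relative spread xi = sd(T_min)/mean(T_min), threshold 0.3).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .behavior import Trajectory
from .ensemble import EnsembleParams, sample_ensemble, simulate_spikes
from .environments import Environment
from .homology import Barcode, CoactivityParams, temporal_betti_trace

__all__ = [
    "TrialOutcome",
    "SweepCell",
    "LearningRegion",
    "betti_trace",
    "detect_Tmin",
    "run_trial",
    "run_sweep",
    "learning_region",
    "derive_trial_seed",
]

#: default observation caps (s): single trials / parameter sweeps
DEFAULT_T_MAX = 15 * 60.0
DEFAULT_SWEEP_T_MAX = 25 * 60.0


@dataclass(frozen=True)
class TrialOutcome:
    """Result of one ensemble trial."""

    success: bool
    T_min: float | None  # s; None on failure
    betti_trace: pd.DataFrame  # columns: time_s, b0, b1
    params: EnsembleParams
    seed: int

    @property
    def T_min_minutes(self) -> float | None:
        return None if self.T_min is None else self.T_min / 60.0


@dataclass(frozen=True)
class SweepCell:
    """Statistics of one grid cell over its repetitions."""

    f_mode: float
    s_mode: float
    N: int
    n_reps: int
    success_fraction: float
    mean_Tmin: float | None  # s, over successful reps
    sd_Tmin: float | None
    xi: float | None  # relative spread sd/mean

    def to_row(self) -> dict:
        return {
            "f_mode_hz": self.f_mode,
            "s_mode_cm": self.s_mode * 100,
            "N": self.N,
            "n_reps": self.n_reps,
            "success_fraction": self.success_fraction,
            "mean_Tmin_min": None if self.mean_Tmin is None else self.mean_Tmin / 60,
            "sd_Tmin_min": None if self.sd_Tmin is None else self.sd_Tmin / 60,
            "xi": self.xi,
        }


@dataclass(frozen=True)
class LearningRegion:
    """Sweep cells passing all stability criteria."""

    cells: tuple[SweepCell, ...]
    T_cap: float
    xi_max: float
    min_success: float

    def __len__(self) -> int:
        return len(self.cells)


def betti_trace(barcode: Barcode, times: np.ndarray, max_dim: int = 1) -> pd.DataFrame:
    """Betti numbers at each time, from the barcode.

    Vectorised: b_k(t) = #(births <= t) - #(deaths <= t) over dimension-k
    intervals (zero-length bars cancel exactly).
    """
    times = np.asarray(times, dtype=float)
    data = {"time_s": times}
    for k in range(max_dim + 1):
        ivs = barcode.in_dim(k)
        births = np.sort([b for b, _ in ivs])
        deaths = np.sort([d for _, d in ivs if not math.isinf(d)])
        data[f"b{k}"] = np.searchsorted(births, times, side="right") - np.searchsorted(
            deaths, times, side="right"
        )
    return pd.DataFrame(data)


def detect_Tmin(
    trace: pd.DataFrame, truth: Sequence[int], T_max: float | None = None
) -> tuple[bool, float | None]:
    """Earliest time from which the Betti trace equals truth through T_max.

    ``trace`` has columns ``time_s, b0, b1, …`` covering (0, T_max].  The
    trial succeeds iff some bin time t* exists with the trace correct at
    every bin in [t*, T_max]; T_min is that earliest t*.
    """
    if len(trace) == 0:
        raise ValueError("empty Betti trace")
    if T_max is not None:
        trace = trace[trace["time_s"] <= T_max]
        if len(trace) == 0:
            raise ValueError("trace does not cover (0, T_max]")
    cols = [f"b{k}" for k in range(len(truth))]
    correct = (trace[cols].to_numpy() == np.asarray(truth)).all(axis=1)
    if not correct[-1]:
        return False, None
    wrong = np.nonzero(~correct)[0]
    first_ok = 0 if wrong.size == 0 else int(wrong[-1]) + 1
    return True, float(trace["time_s"].to_numpy()[first_ok])


def _truncate(traj: Trajectory, T_max: float) -> Trajectory:
    if traj.duration <= T_max:
        return traj
    n = int(round(T_max / traj.dt))
    return Trajectory(times=traj.times[: n + 1], positions=traj.positions[: n + 1], env=traj.env)


def run_trial(
    env: Environment,
    traj: Trajectory,
    params: EnsembleParams,
    coact: CoactivityParams = CoactivityParams(),
    T_max: float = DEFAULT_T_MAX,
    seed: int | None = None,
) -> TrialOutcome:
    """One full map-formation trial.

    Samples a fresh ensemble (new field centres every trial), simulates
    spikes along the trajectory up to T_max, builds the temporal complex,
    computes its barcode, and detects T_min against the arena's ground
    truth.  Fully reproducible from ``seed`` (ensemble and spiking use
    independent streams derived from it).
    """
    if traj.duration + 1e-9 < T_max:
        raise ValueError("trajectory shorter than the observation period T_max")
    if seed is not None:
        ss = np.random.SeedSequence(seed)
        ens_seed, spike_seed = (int(s) % 2**31 for s in ss.generate_state(2))
        params = replace(params, seed=ens_seed)
    else:
        seed = params.seed
        spike_seed = int(np.random.SeedSequence(params.seed).generate_state(1)[0]) % 2**31

    traj = _truncate(traj, T_max)
    cells = sample_ensemble(params, env)
    trains = simulate_spikes(cells, traj, seed=spike_seed)
    trace = temporal_betti_trace(trains, coact)
    success, t_min = detect_Tmin(trace, env.betti_truth, T_max)
    return TrialOutcome(success=success, T_min=t_min, betti_trace=trace, params=params, seed=seed)


def derive_trial_seed(master_seed: int, i_f: int, i_s: int, i_n: int, rep: int) -> int:
    """Stable per-trial seed from the master seed and grid indices.

    Trials are independent and may run in any order or in parallel.
    """
    ss = np.random.SeedSequence([int(master_seed), i_f, i_s, i_n, rep])
    return int(ss.generate_state(1)[0]) % 2**31


def _summarize_cell(
    f_mode: float, s_mode: float, N: int, outcomes: Sequence[TrialOutcome]
) -> SweepCell:
    tmins = [o.T_min for o in outcomes if o.success]
    n = len(outcomes)
    if tmins:
        mean = float(np.mean(tmins))
        sd = float(np.std(tmins))  # population sd; 0 for a single success
        xi = sd / mean if mean > 0 else 0.0
    else:
        mean = sd = xi = None
    return SweepCell(
        f_mode=f_mode,
        s_mode=s_mode,
        N=N,
        n_reps=n,
        success_fraction=sum(o.success for o in outcomes) / n,
        mean_Tmin=mean,
        sd_Tmin=sd,
        xi=xi,
    )


def run_sweep(
    env: Environment,
    traj: Trajectory,
    f_modes: Sequence[float],
    s_modes: Sequence[float],
    Ns: Sequence[int],
    n_reps: int = 10,
    coact: CoactivityParams = CoactivityParams(),
    T_max: float = DEFAULT_SWEEP_T_MAX,
    master_seed: int = 0,
    a: float = 1.2,
    b: float = 1.7,
    progress: Callable[[SweepCell], None] | None = None,
    cache: Callable[[int, int, int], SweepCell | None] | None = None,
) -> list[SweepCell]:
    """Grid sweep over (f_mode, s_mode, N) with n_reps trials per cell.

    The reference protocol probes 10 rate modes from 2 to 40 Hz, 10 size
    modes from ~10 to ~90 cm and 10 ensemble sizes from 50 to 400 cells
    with 10 repetitions each (10,000 trials); reduced grids sweep the same
    ranges more coarsely.  The trajectory is fixed across the whole sweep;
    field centres are redrawn for every trial.  ``cache(i_f, i_s, i_n)``
    may return a precomputed cell to skip (resume support).
    """
    if not (len(f_modes) and len(s_modes) and len(Ns)):
        raise ValueError("empty sweep grid")
    cells: list[SweepCell] = []
    for i_f, f_mode in enumerate(f_modes):
        for i_s, s_mode in enumerate(s_modes):
            for i_n, N in enumerate(Ns):
                if cache is not None:
                    hit = cache(i_f, i_s, i_n)
                    if hit is not None:
                        cells.append(hit)
                        continue
                outcomes = []
                for rep in range(n_reps):
                    seed = derive_trial_seed(master_seed, i_f, i_s, i_n, rep)
                    params = EnsembleParams(N=int(N), f_mode=f_mode, s_mode=s_mode, a=a, b=b)
                    outcomes.append(run_trial(env, traj, params, coact, T_max, seed=seed))
                cell = _summarize_cell(f_mode, s_mode, int(N), outcomes)
                cells.append(cell)
                if progress is not None:
                    progress(cell)
    return cells


def sweep_frame(cells: Sequence[SweepCell]) -> pd.DataFrame:
    """Sweep results as a table (rates in Hz, sizes in cm, times in min)."""
    return pd.DataFrame([c.to_row() for c in cells])


def learning_region(
    cells: Sequence[SweepCell],
    T_cap: float = 5 * 60.0,
    xi_max: float = 0.3,
    min_success: float = 0.8,
) -> LearningRegion:
    """Cells forming fast, stable, reliable maps.

    Membership requires mean T_min <= T_cap, relative spread xi < xi_max
    (default 0.3) and success fraction >= min_success.
    """
    members = tuple(
        c
        for c in cells
        if c.mean_Tmin is not None
        and c.mean_Tmin <= T_cap
        and c.xi is not None
        and c.xi < xi_max
        and c.success_fraction >= min_success
    )
    return LearningRegion(cells=members, T_cap=T_cap, xi_max=xi_max, min_success=min_success)
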