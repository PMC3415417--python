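"""Exploratory trajectory simulation and spatial-coverage statistics.

The simulated animal performs a smooth correlated random walk: speed follows
a mean-reverting (Ornstein–Uhlenbeck) process clipped to a physiological
range, and the heading changes each step by a draw from an even two-component
Gaussian mixture with modes at ±phi0 — a bimodal turning distribution of the
kind measured in open-field rodent tracking.  Steps that would enter a hole
or leave the arena are rejected and the turn re-drawn; if the wall cannot be
avoided the heading is reversed.  This produces ergodic, non-preferential
exploration with elevated occupancy along walls, hole borders and corners,
as seen in real open-field data.

Coverage (ergodicity) curves count the fraction of accessible 3 cm spatial
bins visited up to each time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .environments import Environment, SpatialBinning, is_accessible

__all__ = [
    "TrajectoryParams",
    "Trajectory",
    "generate_trajectory",
    "coverage_curve",
    "time_to_coverage",
]

_TURN_REF_DT = 0.1  # s; reference step at which the turning mixture is stated


@dataclass(frozen=True)
class TrajectoryParams:
    """Parameters of the speed and turning model.

    Speeds in m/s: mean 0.25 with range 0–0.5 (slightly brisk for a rat, so
    learning-time estimates are lower bounds).  The turning mixture has
    modes ±``turn_mode_deg`` and s.d. ``turn_sd_deg`` per 0.1 s reference
    step; both are rescaled linearly to the integration step ``dt`` so the
    per-step distribution keeps its bimodal shape at any dt.
    """

    mean_speed: float = 0.25
    max_speed: float = 0.50
    min_speed: float = 0.0
    dt: float = 0.01
    turn_mode_deg: float = 30.0
    turn_sd_deg: float = 20.0
    speed_reversion: float = 1.0  # OU reversion rate, 1/s
    speed_noise: float = 0.15  # OU noise, m/s per sqrt(s)
    max_heading_tries: int = 50
    wall_brake: float = 0.7  # speed multiplier on wall/hole contact (thigmotaxis)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.min_speed < self.mean_speed < self.max_speed):
            raise ValueError("require 0 <= min_speed < mean_speed < max_speed")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    @property
    def turn_mode_rad(self) -> float:
        """Per-step mixture mode, rescaled to dt."""
        return math.radians(self.turn_mode_deg) * (self.dt / _TURN_REF_DT)

    @property
    def turn_sd_rad(self) -> float:
        """Per-step mixture s.d., rescaled to dt."""
        return math.radians(self.turn_sd_deg) * (self.dt / _TURN_REF_DT)


@dataclass(frozen=True)
class Trajectory:
    """Sampled path: times (s), positions (m, shape (n, 2)), environment."""

    times: np.ndarray
    positions: np.ndarray
    env: Environment

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def duration(self) -> float:
        return float(self.times[-1])

    def speeds(self) -> np.ndarray:
        """Per-step displacement speed (m/s), length n-1."""
        d = np.diff(self.positions, axis=0)
        return np.hypot(d[:, 0], d[:, 1]) / np.diff(self.times)

    def heading_changes(self) -> np.ndarray:
        """Per-step change in movement direction (rad), wrapped to (-pi, pi].

        Length n-2, aligned with the sample index of the middle position;
        NaN where either adjacent step has zero displacement.
        """
        d = np.diff(self.positions, axis=0)
        moving = np.hypot(d[:, 0], d[:, 1]) > 1e-12
        ang = np.arctan2(d[:, 1], d[:, 0])
        dphi = np.mod(np.diff(ang) + np.pi, 2 * np.pi) - np.pi
        dphi[~(moving[:-1] & moving[1:])] = np.nan
        return dphi

    def validate(self) -> None:
        if not np.all(is_accessible(self.env, self.positions[:, 0], self.positions[:, 1])):
            raise ValueError("trajectory leaves the accessible region")
        steps = np.diff(self.times)
        if not np.allclose(steps, steps[0]):
            raise ValueError("non-uniform time step")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_s": self.times, "x_m": self.positions[:, 0], "y_m": self.positions[:, 1]}
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, env: Environment) -> "Trajectory":
        return cls(
            times=df["time_s"].to_numpy(float),
            positions=df[["x_m", "y_m"]].to_numpy(float),
            env=env,
        )


def _random_accessible_point(env: Environment, rng: np.random.Generator) -> np.ndarray:
    for _ in range(10_000):
        p = rng.uniform([0, 0], [env.width, env.height])
        if is_accessible(env, p[0], p[1]):
            return p
    raise RuntimeError("could not find an accessible start point")


def generate_trajectory(
    env: Environment,
    duration: float,
    params: TrajectoryParams = TrajectoryParams(),
    *,
    start: tuple[float, float] | None = None,
) -> Trajectory:
    """Simulate an exploratory path of ``duration`` seconds.

    Deterministic given ``params.seed``.  The path has
    ``round(duration/dt) + 1`` samples, all accessible; candidate steps that
    would cross a wall or hole trigger re-draws of the heading change (up to
    ``max_heading_tries``), then a heading reversal.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(params.seed)
    dt = params.dt
    n = int(round(duration / dt))

    if start is None:
        pos = _random_accessible_point(env, rng)
    else:
        pos = np.asarray(start, dtype=float)
        if not is_accessible(env, pos[0], pos[1]):
            raise ValueError(f"start point {start} is not accessible")

    # pre-drawn innovations for the common (no-rejection) path
    signs = rng.choice([-1.0, 1.0], size=n)
    turns = signs * (params.turn_mode_rad + params.turn_sd_rad * rng.standard_normal(n))
    dv = rng.standard_normal(n)

    positions = np.empty((n + 1, 2))
    positions[0] = pos
    phi = rng.uniform(0, 2 * np.pi)
    v = params.mean_speed
    sqrt_dt = math.sqrt(dt)

    for i in range(n):
        v = v + params.speed_reversion * (params.mean_speed - v) * dt + params.speed_noise * sqrt_dt * dv[i]
        v = min(max(v, params.min_speed), params.max_speed)
        cand_phi = phi + turns[i]
        step = v * dt
        x = pos[0] + step * math.cos(cand_phi)
        y = pos[1] + step * math.sin(cand_phi)
        if not is_accessible(env, x, y):
            # contact with a wall or hole border: brake (rats slow down and
            # investigate boundaries, raising occupancy there) and
            v *= params.wall_brake
            step = v * dt
            x = pos[0] + step * math.cos(cand_phi)
            y = pos[1] + step * math.sin(cand_phi)
        if not is_accessible(env, x, y):
            # rejection-resample the turn from the same mixture; if the wall
            # still blocks, reflect specularly (preserves motion along the
            # wall, so corners of narrow corridors can be rounded)
            placed = False
            for _ in range(params.max_heading_tries):
                s = -1.0 if rng.random() < 0.5 else 1.0
                cand_phi = phi + s * (params.turn_mode_rad + params.turn_sd_rad * rng.standard_normal())
                x = pos[0] + step * math.cos(cand_phi)
                y = pos[1] + step * math.sin(cand_phi)
                if is_accessible(env, x, y):
                    placed = True
                    break
            if not placed:
                dx, dy = math.cos(cand_phi), math.sin(cand_phi)
                for rx, ry in ((-1, 1), (1, -1), (-1, -1)):
                    x = pos[0] + step * dx * rx
                    y = pos[1] + step * dy * ry
                    if is_accessible(env, x, y):
                        cand_phi = math.atan2(dy * ry, dx * rx)
                        placed = True
                        break
                if not placed:
                    x, y = pos  # stay put for this step
        phi = cand_phi
        pos = np.array([x, y])
        positions[i + 1] = pos

    times = np.arange(n + 1) * dt
    return Trajectory(times=times, positions=positions, env=env)


def coverage_curve(traj: Trajectory, binning: SpatialBinning | None = None) -> pd.DataFrame:
    """Fraction of accessible spatial bins visited up to each sample time.

    Monotone non-decreasing, starting at 1/#accessible (the initial bin) and
    approaching 1 as exploration saturates.  Returns columns
    ``time_s, fraction``.
    """
    if binning is None:
        binning = SpatialBinning(traj.env)
    idx = binning.bin_index(traj.positions[:, 0], traj.positions[:, 1])
    accessible = binning.accessible_mask
    n_acc = int(accessible.sum())
    # first visit time index of each distinct accessible bin
    _, first = np.unique(idx, return_index=True)
    first = first[accessible[idx[first]]]
    first.sort()
    # cumulative count of distinct bins at each sample
    counts = np.searchsorted(first, np.arange(len(idx)), side="right")
    return pd.DataFrame({"time_s": traj.times, "fraction": counts / n_acc})


def time_to_coverage(curve: pd.DataFrame, fraction: float) -> float:
    """Earliest time at which the coverage fraction reaches ``fraction``.

    Returns ``inf`` if the trajectory never reaches it.
    """
    hit = curve.loc[curve["fraction"] >= fraction, "time_s"]
    return float(hit.iloc[0]) if len(hit) else math.inf
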