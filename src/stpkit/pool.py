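"""Finite-pool vesicle refilling model.

A synaptic connection is modeled as ``n_sites`` independent release
sites.  Each site is either empty or holds a docked (release-ready)
vesicle; vesicles dock at rate ``k1`` (per empty site) and undock at
rate ``b1``.  When an action potential (AP) arrives, every docked
vesicle fuses independently with probability ``p_v``.  The expected
site occupancy rho obeys

    d(rho)/dt = k1 * (1 - rho) - b1 * rho

between APs, with an instantaneous multiplicative drop
``rho -> (1 - p_v) * rho`` at each AP time.

Two simulation surfaces are provided: a deterministic forward-Euler
integrator of the expected occupancy (optionally with a time-dependent
k1 supplied by the calcium-sensor module) and a per-site Monte-Carlo
simulator in two dialects (exact two-state Markov propagation, or a
one-transition-per-interval binomial scheme that matches the
combinatorial failure analysis).

Units are SI: seconds for time, per-second for rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PoolParams",
    "StimTrain",
    "PoolTrajectory",
    "steady_state_occupancy",
    "integrate_deterministic",
    "simulate_stochastic",
]


@dataclass(frozen=True)
class PoolParams:
    """Parameters of the refilling model.

    Parameters
    ----------
    n_sites : int
        Number of release sites (N_max).
    k1_base : float
        Baseline forward docking rate, per second.
    b1 : float
        Undocking rate, per second.
    p_v : float
        Vesicular fusion probability per AP, in [0, 1].
    """

    n_sites: int
    k1_base: float
    b1: float
    p_v: float

    def __post_init__(self) -> None:
        if self.n_sites < 1 or int(self.n_sites) != self.n_sites:
            raise ValueError(f"n_sites must be a positive integer, got {self.n_sites}")
        if self.k1_base < 0 or self.b1 < 0:
            raise ValueError("rates must be nonnegative")
        if not 0.0 <= self.p_v <= 1.0:
            raise ValueError(f"p_v must be in [0, 1], got {self.p_v}")

    @property
    def p_occ(self) -> float:
        """Steady-state site occupancy k1/(k1+b1)."""
        return steady_state_occupancy(self.k1_base, self.b1)


@dataclass(frozen=True)
class StimTrain:
    """An ordered train of AP times, in seconds."""

    ap_times: tuple[float, ...]
    label: str = ""

    def __post_init__(self) -> None:
        times = tuple(float(t) for t in self.ap_times)
        object.__setattr__(self, "ap_times", times)
        arr = np.asarray(times)
        if arr.size and arr[0] < 0:
            raise ValueError("AP times must be nonnegative")
        if arr.size > 1 and not np.all(np.diff(arr) > 0):
            raise ValueError("AP times must be strictly increasing")

    @classmethod
    def regular(cls, frequency_hz: float, n_pulses: int, start: float = 0.0,
                label: str = "") -> "StimTrain":
        """Build an n-pulse train at a fixed frequency (first AP at `start`)."""
        if frequency_hz <= 0:
            raise ValueError("frequency must be positive")
        times = start + np.arange(n_pulses) / frequency_hz
        return cls(tuple(times), label=label or f"{frequency_hz:g}Hz x{n_pulses}")

    def min_isi(self) -> float:
        if len(self.ap_times) < 2:
            return np.inf
        return float(np.min(np.diff(self.ap_times)))


@dataclass
class PoolTrajectory:
    """Result of a deterministic pool integration.

    Attributes
    ----------
    times : ndarray
        Integration grid, seconds.
    occupancy : ndarray
        Expected docked fraction per site at each grid time (post-AP
        value at AP samples).
    released_per_ap : ndarray
        Expected quanta released at each AP (occupancy drop times N).
    normalized_amplitudes : ndarray
        released_per_ap divided by its first element.
    """

    times: np.ndarray
    occupancy: np.ndarray
    released_per_ap: np.ndarray
    normalized_amplitudes: np.ndarray
    ap_times: np.ndarray = field(default_factory=lambda: np.empty(0))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.times, "occupancy": self.occupancy})

    def per_ap_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "ap_index": np.arange(1, len(self.released_per_ap) + 1),
            "ap_time_s": self.ap_times,
            "released": self.released_per_ap,
            "normalized_amplitude": self.normalized_amplitudes,
        })


def steady_state_occupancy(k1: float, b1: float) -> float:
    """Steady-state probability that a site holds a docked vesicle.

    Computed as k1 / (k1 + b1).  Raises if both rates are zero (the
    occupancy is then undefined).
    """
    if k1 < 0 or b1 < 0:
        raise ValueError("rates must be nonnegative")
    if k1 + b1 == 0:
        raise ValueError("occupancy undefined when both rates are zero")
    return k1 / (k1 + b1)


def integrate_deterministic(
    params: PoolParams,
    stim: StimTrain,
    k1_series: Sequence[float] | None = None,
    dt: float = 1e-3,
    times: Sequence[float] | None = None,
    occupancy0: float | None = None,
    t_end: float | None = None,
) -> PoolTrajectory:
    """Forward-Euler integration of the expected site occupancy.

    Between APs the occupancy relaxes toward k1/(k1+b1); at each AP it
    is multiplied by (1 - p_v) instantaneously and the drop (times
    n_sites) is recorded as the expected number of released quanta.
    Modeling release as a delta event keeps the per-AP release
    independent of dt.

    Parameters
    ----------
    k1_series : sequence of float, optional
        Time-dependent forward rate evaluated on the integration grid
        (one value per grid point).  Defaults to constant ``k1_base``.
    times : sequence of float, optional
        Explicit (possibly non-uniform) integration grid.  When given,
        ``dt`` is ignored and every AP time must lie on the grid.
    occupancy0 : float, optional
        Initial occupancy; defaults to the steady state at ``k1_base``.
    t_end : float, optional
        End of integration (default: last AP + 5 refill time constants,
        or 10 time constants with no APs).
    """
    ap_times = np.asarray(stim.ap_times, dtype=float)

    if times is not None:
        grid = np.asarray(times, dtype=float)
        if grid.ndim != 1 or grid.size < 2 or not np.all(np.diff(grid) > 0):
            raise ValueError("times must be a strictly increasing 1-D grid")
    else:
        if dt <= 0:
            raise ValueError("dt must be positive")
        if ap_times.size and dt > stim.min_isi():
            raise ValueError(
                f"dt={dt} exceeds the smallest inter-AP interval {stim.min_isi()}"
            )
        tau = 1.0 / max(params.k1_base + params.b1, 1e-12)
        pad = min(5 * tau, 1.0)  # cap the tail for near-frozen pools
        if t_end is None:
            t_end = (ap_times[-1] + pad) if ap_times.size else 2 * pad
        n_steps = int(np.ceil(t_end / dt))
        grid = np.arange(n_steps + 1) * dt

    if k1_series is None:
        k1_arr = np.full(grid.size, params.k1_base, dtype=float)
    else:
        k1_arr = np.asarray(k1_series, dtype=float)
        if k1_arr.shape != grid.shape:
            raise ValueError("k1_series must match the integration grid")

    # Map each AP onto its grid index (nearest sample; must be close).
    ap_idx = np.searchsorted(grid, ap_times - 1e-12)
    ap_idx = np.clip(ap_idx, 0, grid.size - 1)
    local_dt = np.diff(grid).min() if grid.size > 1 else dt
    if ap_times.size and np.any(np.abs(grid[ap_idx] - ap_times) > local_dt + 1e-12):
        raise ValueError("every AP time must lie on the integration grid")

    rho = params.p_occ if occupancy0 is None else float(occupancy0)
    if not 0.0 <= rho <= 1.0:
        raise ValueError("initial occupancy must be in [0, 1]")

    occ = np.empty(grid.size)
    released: list[float] = []
    ap_set = {int(i) for i in ap_idx}
    for i in range(grid.size):
        if i in ap_set:
            drop = params.p_v * rho
            released.append(drop * params.n_sites)
            rho -= drop
        occ[i] = rho
        if i < grid.size - 1:
            h = grid[i + 1] - grid[i]
            rho = rho + h * (k1_arr[i] * (1.0 - rho) - params.b1 * rho)
            rho = min(max(rho, 0.0), 1.0)

    released_arr = np.asarray(released)
    if released_arr.size and released_arr[0] > 0:
        norm = released_arr / released_arr[0]
    else:
        norm = np.full(released_arr.size, np.nan)
    return PoolTrajectory(
        times=grid, occupancy=occ,
        released_per_ap=released_arr, normalized_amplitudes=norm,
        ap_times=ap_times,
    )


def simulate_stochastic(
    params: PoolParams,
    stim: StimTrain,
    n_trials: int,
    seed: int,
    dialect: Literal["continuous-time", "per-interval-BF"] = "continuous-time",
) -> pd.DataFrame:
    """Monte-Carlo simulation of per-site occupancy and release.

    Each trial tracks ``n_sites`` independent sites, initialized from
    the steady-state occupancy.  Between consecutive APs (interval dt):

    - ``"continuous-time"``: the exact two-state Markov propagator is
      applied, P(occupied | occupied) = p_inf + (1 - p_inf) * E and
      P(occupied | empty) = p_inf * (1 - E) with
      E = exp(-(k1 + b1) * dt) and p_inf = k1/(k1+b1).
    - ``"per-interval-BF"``: at most one transition per interval; a
      docked site undocks with probability B = 1 - exp(-b1 dt), an
      empty site docks with probability F = 1 - exp(-k1 dt), and a
      site vacated by release or undocking is not refilled within the
      same interval.  This is the scheme assumed by the closed-form
      two-pulse failure analysis (:mod:`stpkit.failures`).

    At each AP every docked vesicle releases independently with
    probability ``p_v``.

    Returns a long-format DataFrame with columns
    ``trial, ap_index, quanta_released`` (ap_index is 1-based).
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if dialect not in ("continuous-time", "per-interval-BF"):
        raise ValueError(f"unknown dialect {dialect!r}")
    ap_times = np.asarray(stim.ap_times, dtype=float)
    if ap_times.size == 0:
        raise ValueError("stimulation train has no APs")

    rng = np.random.default_rng(seed)
    k1, b1, p_v = params.k1_base, params.b1, params.p_v
    p_inf = params.p_occ

    docked = rng.random((n_trials, params.n_sites)) < p_inf
    released = np.empty((n_trials, ap_times.size), dtype=np.int64)

    prev_t = None
    for a, t_ap in enumerate(ap_times):
        if prev_t is not None:
            dt = t_ap - prev_t
            if dialect == "continuous-time":
                e = np.exp(-(k1 + b1) * dt)
                p_stay = p_inf + (1.0 - p_inf) * e
                p_gain = p_inf * (1.0 - e)
                u = rng.random(docked.shape)
                docked = np.where(docked, u < p_stay, u < p_gain)
            else:
                big_b = 1.0 - np.exp(-b1 * dt)
                big_f = 1.0 - np.exp(-k1 * dt)
                u = rng.random(docked.shape)
                docked = np.where(docked, u >= big_b, u < big_f)
        fuse = docked & (rng.random(docked.shape) < p_v)
        released[:, a] = fuse.sum(axis=1)
        docked = docked & ~fuse
        prev_t = t_ap

    trials = np.repeat(np.arange(n_trials), ap_times.size)
    ap_index = np.tile(np.arange(1, ap_times.size + 1), n_trials)
    return pd.DataFrame({
        "trial": trials,
        "ap_index": ap_index,
        "quanta_released": released.reshape(-1),
    })
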