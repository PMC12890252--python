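"""Slow calcium sensor driving activity-dependent pool refilling.

Synaptotagmin-7 (Syt7) is modeled as a chain of ``n_ca_sites``
sequential Ca2+ binding steps S_0 <-> S_1 <-> ... <-> S_n.  Binding is
cooperative: the forward rate of step j is (n - j) * k_on * [Ca], and
the backward rate of step j+1 -> j is (j + 1) * k_off * b**j, so a
cooperativity factor b < 1 progressively slows unbinding as more Ca2+
ions are bound.  Only the fully bound form catalyzes vesicle docking:

    k1(t) = k1_base + K1_max * s_n(t)

where s_n is the fraction of Syt7 with all sites occupied.

The presynaptic Ca2+ waveform seen by the sensor is the sum, over APs,
of a brief local transient (Gaussian, ~40 uM peak, sub-millisecond
width) and a residual component (~1 uM, tens-of-ms exponential decay),
superposed linearly across APs.

Because the local transient is three orders of magnitude briefer than
the inter-AP intervals, integration uses a two-timescale grid: a fine
step inside a window around each AP and a coarse step elsewhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from stpkit.pool import PoolParams, PoolTrajectory, StimTrain, integrate_deterministic

__all__ = [
    "CaWaveformParams",
    "Syt7Params",
    "BindingState",
    "make_two_timescale_grid",
    "build_ca_waveform",
    "integrate_binding_chain",
    "k1_of_t",
    "simulate_stp",
]


@dataclass(frozen=True)
class CaWaveformParams:
    """AP-locked presynaptic Ca2+ waveform.

    Defaults describe the transient at a small cortical bouton: a local
    Gaussian spike of 40 uM peak centered 0.25 ms after the AP with
    sigma = 0.085 ms (FWHM 0.2 ms), plus a 1 uM residual decaying with
    a 50 ms time constant.  Concentrations in uM, times in seconds.
    """

    local_peak: float = 40.0          # uM
    local_tp: float = 0.25e-3         # s, Gaussian center after AP
    local_sigma: float = 0.085e-3     # s
    residual_amp: float = 1.0         # uM
    residual_tau: float = 50e-3       # s
    ca_rest: float = 0.0              # uM; measured resting value is 0.05

    def __post_init__(self) -> None:
        if self.local_sigma <= 0:
            raise ValueError("local_sigma must be positive")
        for name in ("local_peak", "local_tp", "residual_amp", "residual_tau",
                     "ca_rest"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


@dataclass(frozen=True)
class Syt7Params:
    """Sequential-binding sensor parameters.

    k_on in /uM/s, k_off in /s, K1_max and k1_base in /s; coop_b is the
    dimensionless cooperativity factor applied geometrically to
    successive unbinding steps.
    """

    n_ca_sites: int = 5
    k_on: float = 7.0
    k_off: float = 10.0
    coop_b: float = 0.35
    K1_max: float = 300.0
    k1_base: float = 6.9

    def __post_init__(self) -> None:
        if self.n_ca_sites < 1 or int(self.n_ca_sites) != self.n_ca_sites:
            raise ValueError("n_ca_sites must be a positive integer")
        if min(self.k_on, self.k_off, self.K1_max, self.k1_base) < 0:
            raise ValueError("rates must be nonnegative")
        if self.coop_b <= 0:
            raise ValueError("coop_b must be positive")


@dataclass
class BindingState:
    """Occupancy distribution over S_0..S_n (fractions summing to 1)."""

    s_fractions: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.s_fractions, dtype=float)
        if np.any(arr < -1e-12):
            raise ValueError("fractions must be nonnegative")
        if abs(arr.sum() - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")
        self.s_fractions = arr

    @classmethod
    def ground(cls, n_ca_sites: int) -> "BindingState":
        s = np.zeros(n_ca_sites + 1)
        s[0] = 1.0
        return cls(s)


def make_two_timescale_grid(
    stim: StimTrain,
    t_end: float,
    fine_dt: float = 5e-6,
    coarse_dt: float = 1e-3,
    fine_window: float = 2e-3,
) -> np.ndarray:
    """Integration grid: `fine_dt` within +-`fine_window` of each AP,
    `coarse_dt` elsewhere.  AP times fall exactly on the grid."""
    if fine_dt <= 0 or coarse_dt <= 0 or fine_dt > coarse_dt:
        raise ValueError("need 0 < fine_dt <= coarse_dt")
    edges = [0.0]
    pieces = []
    windows = [(max(t - fine_window, 0.0), min(t + fine_window, t_end))
               for t in stim.ap_times if t <= t_end]
    # merge overlapping fine windows
    merged: list[list[float]] = []
    for lo, hi in windows:
        if merged and lo <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])
    cursor = 0.0
    for lo, hi in merged:
        if lo > cursor:
            n = max(int(np.ceil((lo - cursor) / coarse_dt)), 1)
            pieces.append(np.linspace(cursor, lo, n + 1)[:-1])
        n = max(int(np.ceil((hi - lo) / fine_dt)), 1)
        pieces.append(np.linspace(lo, hi, n + 1)[:-1])
        cursor = hi
    if cursor < t_end:
        n = max(int(np.ceil((t_end - cursor) / coarse_dt)), 1)
        pieces.append(np.linspace(cursor, t_end, n + 1)[:-1])
    grid = np.concatenate(pieces + [[t_end]])
    # snap AP times onto the grid exactly
    ap = np.asarray([t for t in stim.ap_times if t <= t_end])
    idx = np.searchsorted(grid, ap)
    grid[np.clip(idx, 0, grid.size - 1)] = ap
    return np.unique(grid)


def build_ca_waveform(
    params: CaWaveformParams, stim: StimTrain, grid: np.ndarray
) -> np.ndarray:
    """Ca2+ concentration (uM) on `grid` as a linear superposition of
    per-AP local Gaussians and residual exponentials, plus baseline.

    The Gaussian is peak-scaled: its maximum equals ``local_peak``.
    The grid must resolve the local transient (>= 5 samples per sigma
    inside the AP windows)."""
    grid = np.asarray(grid, dtype=float)
    ca = np.full(grid.size, params.ca_rest, dtype=float)
    for t_ap in stim.ap_times:
        # the grid must resolve the local transient around this AP
        window_hi = t_ap + 2 * params.local_tp + 3 * params.local_sigma
        lo = int(np.searchsorted(grid, t_ap))
        hi = int(np.searchsorted(grid, window_hi))
        steps = np.diff(grid[max(lo - 1, 0): min(hi + 1, grid.size)])
        max_step = np.max(steps) if steps.size else np.inf
        if max_step > params.local_sigma / 5:
            raise ValueError(
                "grid too coarse near AP at "
                f"t={t_ap}: step {max_step:.2e} s > sigma/5"
            )
        dt_loc = grid - (t_ap + params.local_tp)
        ca += params.local_peak * np.exp(-0.5 * (dt_loc / params.local_sigma) ** 2)
        after = grid >= t_ap
        ca[after] += params.residual_amp * np.exp(-(grid[after] - t_ap) / params.residual_tau)
    return ca


def _chain_rates(params: Syt7Params) -> tuple[np.ndarray, np.ndarray]:
    """Per-step on-rate multipliers (n-j)*k_on and off rates
    (j+1)*k_off*b**j for j = 0..n-1."""
    n = params.n_ca_sites
    j = np.arange(n)
    kf = (n - j) * params.k_on                       # times [Ca]
    kb = (j + 1) * params.k_off * params.coop_b ** j
    return kf, kb


def integrate_binding_chain(
    params: Syt7Params,
    ca_series: np.ndarray,
    state0: BindingState,
    grid: np.ndarray,
) -> np.ndarray:
    """Master-equation (forward-Euler) integration of the binding chain.

    Returns an array of shape (len(grid), n_ca_sites + 1) whose rows are
    the S_0..S_n occupancy fractions.  Probability is conserved exactly
    (fluxes are antisymmetric) and states are renormalized against
    floating-point drift.
    """
    grid = np.asarray(grid, dtype=float)
    ca = np.asarray(ca_series, dtype=float)
    if ca.shape != grid.shape:
        raise ValueError("ca_series must match the grid")
    if np.any(ca < 0):
        raise ValueError("negative Ca2+ concentration")
    kf, kb = _chain_rates(params)
    n = params.n_ca_sites
    s = state0.s_fractions.astype(float).copy()
    if s.size != n + 1:
        raise ValueError("state0 has wrong chain length")
    out = np.empty((grid.size, n + 1))
    out[0] = s
    for i in range(grid.size - 1):
        h = grid[i + 1] - grid[i]
        fwd = kf * ca[i] * s[:-1]      # flux j -> j+1
        bwd = kb * s[1:]               # flux j+1 -> j
        net = fwd - bwd
        s = s.copy()
        s[:-1] += h * (-net)
        s[1:] += h * net
        np.clip(s, 0.0, None, out=s)
        s /= s.sum()
        out[i + 1] = s
    return out


def equilibrium_state(params: Syt7Params, ca: float) -> np.ndarray:
    """Detailed-balance equilibrium of the chain at constant [Ca] (uM)."""
    if ca == 0:
        s = np.zeros(params.n_ca_sites + 1)
        s[0] = 1.0
        return s
    kf, kb = _chain_rates(params)
    log_w = np.concatenate([[0.0], np.cumsum(np.log(kf * ca) - np.log(kb))])
    w = np.exp(log_w - log_w.max())
    return w / w.sum()


def k1_of_t(state_traj: np.ndarray, params: Syt7Params) -> np.ndarray:
    """Docking rate k1(t) = k1_base + K1_max * (fully bound fraction)."""
    traj = np.asarray(state_traj, dtype=float)
    return params.k1_base + params.K1_max * traj[:, -1]


def simulate_stp(
    pool: PoolParams,
    syt7: Syt7Params,
    ca: CaWaveformParams,
    frequency: float,
    n_pulses: int = 20,
    kd_mode: bool = False,
    fine_dt: float = 5e-6,
    coarse_dt: float = 1e-3,
    return_trajectory: bool = False,
) -> np.ndarray | tuple[np.ndarray, pd.DataFrame, PoolTrajectory]:
    """Short-term plasticity of a train: normalized EPSC amplitudes.

    Composes the Ca2+ waveform, the Syt7 binding chain, the k1(t)
    modulation law and the deterministic pool integration on a shared
    two-timescale grid.  With ``kd_mode=True`` (sensor knockdown) k1 is
    frozen at ``k1_base`` and the model can only depress.

    Returns the per-pulse baseline-normalized amplitude sequence, or
    (amplitudes, detail DataFrame, PoolTrajectory) when
    ``return_trajectory`` is set.
    """
    if frequency <= 0:
        raise ValueError("frequency must be positive")
    stim = StimTrain.regular(frequency, n_pulses)
    t_end = stim.ap_times[-1] + 1.0 / frequency
    grid = make_two_timescale_grid(stim, t_end, fine_dt=fine_dt, coarse_dt=coarse_dt)

    if kd_mode:
        k1_series = np.full(grid.size, syt7.k1_base)
        detail_cols = {"ca_uM": np.zeros(grid.size)}
        traj_state = None
    else:
        ca_series = build_ca_waveform(ca, stim, grid)
        traj_state = integrate_binding_chain(
            syt7, ca_series, BindingState.ground(syt7.n_ca_sites), grid
        )
        k1_series = k1_of_t(traj_state, syt7)
        detail_cols = {"ca_uM": ca_series}

    params = PoolParams(pool.n_sites, syt7.k1_base, pool.b1, pool.p_v)
    traj = integrate_deterministic(params, stim, k1_series=k1_series, times=grid)

    if not return_trajectory:
        return traj.normalized_amplitudes
    detail = pd.DataFrame({"time_s": grid, **detail_cols, "k1_per_s": k1_series,
                           "occupancy": traj.occupancy})
    if traj_state is not None:
        for j in range(traj_state.shape[1]):
            detail[f"s{j}"] = traj_state[:, j]
    return traj.normalized_amplitudes, detail, traj
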