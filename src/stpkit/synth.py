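"""Seeded synthetic-data generators with known ground truth.

Every analysis stage in the package has a matching generator here, so
the full pipeline is testable end to end without recorded data:

- EPSC amplitude trains from per-site stochastic pool simulations with
  Gaussian quantal variability and additive recording noise,
- two-pulse success/failure trial tables for the failure analysis,
- asynchronous-release event amplitude lists for quantal-size fits,
- two-channel ratiometric line-scan fluorescence from a known calcium
  transient and buffering parameters.

All randomness flows from the configured seed; repeated runs with the
same configuration are identical.  Each generator returns its data
together with a ground-truth dictionary recording every parameter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from stpkit.calcium import RatiometryCalib, ca_to_ratio, kappa_b
from stpkit.pool import PoolParams, StimTrain, simulate_stochastic
from stpkit.syt7 import CaWaveformParams

__all__ = [
    "SynthEPSCConfig",
    "SynthLinescanConfig",
    "gen_epsc_trains",
    "gen_paired_trials",
    "gen_async_events",
    "gen_linescan",
]


@dataclass(frozen=True)
class SynthEPSCConfig:
    """Configuration of the EPSC-train generator.

    Quantal amplitudes are Normal(q, q * cv_qs) truncated at zero;
    recording noise is additive Normal(0, noise_sd).  The dialect
    selects the per-site occupancy scheme (see
    :func:`stpkit.pool.simulate_stochastic`).
    """

    pool: PoolParams
    stim: StimTrain
    q: float = 25.0           # pA
    cv_qs: float = 0.2
    noise_sd: float = 0.0     # pA
    n_trials: int = 100
    seed: int = 0
    dialect: Literal["continuous-time", "per-interval-BF"] = "continuous-time"

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.q <= 0:
            raise ValueError("q must be positive")
        if self.cv_qs < 0 or self.noise_sd < 0:
            raise ValueError("cv_qs and noise_sd must be nonnegative")


@dataclass(frozen=True)
class SynthLinescanConfig:
    """Configuration of the two-dye line-scan generator.

    The underlying buffer-free transient is defined by the endogenous
    binding ratio ``kappa_s``, the extrusion rate ``gamma`` (per s) and
    the total per-AP calcium increment ``delta_ca_total`` (uM).  The
    indicator at ``indicator_total`` uM (dissociation constant
    ``indicator_kd``) loads the compartment with binding ratio kappa_B,
    scaling the measured transient amplitude by 1/(1+kappa_S+kappa_B)
    and its decay time by (1+kappa_S+kappa_B)/gamma.  Defaults emulate
    a small cortical bouton (kappa_S ~ 96, buffer-free amplitude
    ~1.16 uM, decay ~43 ms, rest 50 nM).
    """

    calib: RatiometryCalib
    indicator_total: float = 150.0   # uM
    indicator_kd: float = 2.3        # uM
    waveform: CaWaveformParams = field(
        default_factory=lambda: CaWaveformParams(ca_rest=0.05))
    kappa_s: float = 96.4
    gamma: float = (1.0 + 96.4) / 0.043        # per s
    delta_ca_total: float = 1.16 * (1.0 + 96.4)  # uM
    noise_cv: float = 0.0
    n_sweeps: int = 3
    duration: float = 0.4            # s
    sample_rate: float = 640.0       # lines per s; onset falls on a sample
    t_onset: float = 0.05            # s
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.indicator_total, self.indicator_kd, self.gamma,
               self.delta_ca_total) <= 0:
            raise ValueError("concentrations and rates must be positive")
        if self.n_sweeps < 1:
            raise ValueError("n_sweeps must be >= 1")


def _truncated_quantal(rng: np.random.Generator, q: float, cv: float,
                       n: int) -> np.ndarray:
    """Normal(q, q*cv) truncated at zero by resampling."""
    if n == 0:
        return np.empty(0)
    if cv == 0:
        return np.full(n, q)
    out = rng.normal(q, q * cv, size=n)
    bad = out <= 0
    while np.any(bad):
        out[bad] = rng.normal(q, q * cv, size=int(bad.sum()))
        bad = out <= 0
    return out


def _amplitudes_from_counts(rng: np.random.Generator, counts: np.ndarray,
                            q: float, cv_qs: float, noise_sd: float) -> np.ndarray:
    """Sum per-quantum amplitude draws for each entry of `counts`, plus
    additive recording noise."""
    flat = counts.reshape(-1)
    total = int(flat.sum())
    draws = _truncated_quantal(rng, q, cv_qs, total)
    owner = np.repeat(np.arange(flat.size), flat)
    sums = np.bincount(owner, weights=draws, minlength=flat.size)
    if noise_sd > 0:
        sums = sums + rng.normal(0.0, noise_sd, size=flat.size)
    return sums.reshape(counts.shape)


def gen_epsc_trains(cfg: SynthEPSCConfig) -> tuple[pd.DataFrame, dict]:
    """Per-trial, per-pulse EPSC amplitude table.

    Returns a long DataFrame (trial, pulse_index, amp_pA) and the
    ground-truth record.
    """
    rng = np.random.default_rng(cfg.seed)
    quanta = simulate_stochastic(
        cfg.pool, cfg.stim, cfg.n_trials, seed=int(rng.integers(2**31)),
        dialect=cfg.dialect,
    )
    n_pulses = len(cfg.stim.ap_times)
    counts = quanta["quanta_released"].to_numpy().reshape(cfg.n_trials, n_pulses)
    amps = _amplitudes_from_counts(rng, counts, cfg.q, cfg.cv_qs, cfg.noise_sd)
    df = pd.DataFrame({
        "trial": np.repeat(np.arange(cfg.n_trials), n_pulses),
        "pulse_index": np.tile(np.arange(1, n_pulses + 1), cfg.n_trials),
        "amp_pA": amps.reshape(-1),
    })
    truth = {
        "n_sites": cfg.pool.n_sites, "k1_per_s": cfg.pool.k1_base,
        "b1_per_s": cfg.pool.b1, "p_v": cfg.pool.p_v,
        "p_occ": cfg.pool.p_occ, "q_pA": cfg.q, "cv_qs": cfg.cv_qs,
        "noise_sd_pA": cfg.noise_sd, "n_trials": cfg.n_trials,
        "ap_times_s": list(cfg.stim.ap_times), "seed": cfg.seed,
        "dialect": cfg.dialect,
    }
    return df, truth


def gen_paired_trials(
    cfg: SynthEPSCConfig, detection_threshold: float | None = None
) -> tuple[pd.DataFrame, dict]:
    """Two-pulse success/failure trials for the failure analysis.

    A pulse counts as a success when its amplitude exceeds the
    detection threshold (default q/2).  Returns (trial, s1, s2) plus a
    ground-truth record containing the tallied joint frequencies.
    """
    if len(cfg.stim.ap_times) != 2:
        raise ValueError("gen_paired_trials needs a two-AP stimulation train")
    thr = cfg.q / 2.0 if detection_threshold is None else float(detection_threshold)
    if thr > cfg.pool.n_sites * cfg.q:
        import warnings
        warnings.warn("detection threshold exceeds N*q: everything will "
                      "be scored as failure", stacklevel=2)
    df, truth = gen_epsc_trains(cfg)
    wide = df.pivot(index="trial", columns="pulse_index", values="amp_pA")
    s1 = (wide[1] > thr).to_numpy()
    s2 = (wide[2] > thr).to_numpy()
    out = pd.DataFrame({"trial": wide.index.to_numpy(),
                        "s1": s1.astype(int), "s2": s2.astype(int)})
    n = len(out)
    truth = dict(truth)
    truth.update({
        "detection_threshold_pA": thr,
        "joint_observed": {
            "P11": float(np.sum(s1 & s2)) / n,
            "P10": float(np.sum(s1 & ~s2)) / n,
            "P01": float(np.sum(~s1 & s2)) / n,
            "P00": float(np.sum(~s1 & ~s2)) / n,
        },
    })
    return out, truth


def gen_async_events(
    q: float, cv: float, n: int, noise_sd: float = 0.0, seed: int = 0
) -> np.ndarray:
    """Asynchronous-release event amplitudes: Normal(q, q*cv) truncated
    at zero, plus additive detection noise."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    amps = _truncated_quantal(rng, q, cv, n)
    if noise_sd > 0:
        amps = amps + rng.normal(0.0, noise_sd, size=n)
    return amps


def linescan_transient(cfg: SynthLinescanConfig) -> dict:
    """Solve the measured transient implied by the buffering load.

    kappa_B depends on the transient peak, which depends on kappa_B;
    a short fixed-point iteration resolves the pair.  Returns the
    consistent (kappa_b, amplitude, tau) for this indicator load.
    """
    rest = cfg.waveform.ca_rest
    amp = cfg.delta_ca_total / (1.0 + cfg.kappa_s)  # start from buffer-free
    for _ in range(100):
        kb = kappa_b(cfg.indicator_total, cfg.indicator_kd, rest, rest + amp)
        new_amp = cfg.delta_ca_total / (1.0 + cfg.kappa_s + kb)
        if abs(new_amp - amp) < 1e-12:
            amp = new_amp
            break
        amp = new_amp
    kb = kappa_b(cfg.indicator_total, cfg.indicator_kd, rest, rest + amp)
    tau = (1.0 + cfg.kappa_s + kb) / cfg.gamma
    return {"kappa_b": kb, "amplitude_uM": amp, "tau_s": tau}


def gen_linescan(cfg: SynthLinescanConfig) -> tuple[pd.DataFrame, dict]:
    """Two-channel line-scan fluorescence sweeps.

    The free-calcium trace is rest level, then a step to the
    buffering-consistent amplitude at ``t_onset`` with mono-exponential
    decay.  It is converted to a fluorescence ratio through the inverse
    calibration and split into green (ratio x reference) and red
    (reference) channels with multiplicative Gaussian noise of
    coefficient ``noise_cv`` per sample.  Returns a long DataFrame
    (sweep, time_s, f_green, f_red) and the ground truth.
    """
    rng = np.random.default_rng(cfg.seed)
    tr = linescan_transient(cfg)
    t = np.arange(0.0, cfg.duration, 1.0 / cfg.sample_rate)
    ca = np.full(t.size, cfg.waveform.ca_rest)
    after = t >= cfg.t_onset
    ca[after] += tr["amplitude_uM"] * np.exp(-(t[after] - cfg.t_onset) / tr["tau_s"])
    ratio = np.asarray(ca_to_ratio(ca, cfg.calib))
    frames = []
    for sweep in range(cfg.n_sweeps):
        red = np.ones(t.size)
        green = ratio.copy()
        if cfg.noise_cv > 0:
            green = green * (1.0 + cfg.noise_cv * rng.standard_normal(t.size))
            red = red * (1.0 + cfg.noise_cv * rng.standard_normal(t.size))
        frames.append(pd.DataFrame({
            "sweep": sweep, "time_s": t, "f_green": green, "f_red": red,
        }))
    truth = {
        "kappa_s": cfg.kappa_s, "gamma_per_s": cfg.gamma,
        "delta_ca_total_uM": cfg.delta_ca_total,
        "indicator_total_uM": cfg.indicator_total,
        "indicator_kd_uM": cfg.indicator_kd,
        "ca_rest_uM": cfg.waveform.ca_rest,
        "kappa_b": tr["kappa_b"],
        "amplitude_uM": tr["amplitude_uM"],
        "tau_s": tr["tau_s"],
        "noise_cv": cfg.noise_cv, "n_sweeps": cfg.n_sweeps, "seed": cfg.seed,
    }
    return pd.concat(frames, ignore_index=True), truth
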