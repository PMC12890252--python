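"""Ratiometric calcium imaging and calcium-binding-ratio analysis.

Two-dye ratiometry converts a background-corrected fluorescence ratio
R = F_green / F_red into free calcium via

    [Ca2+]_i = Kd * (R - Rmin) / (Rmax - R)

In a single-compartment model, an AP-evoked Ca2+ influx rises to an
amplitude A_Ca and decays mono-exponentially with time constant tau_Ca,
both set by how much of the entering calcium is captured by buffers.
With endogenous binding ratio kappa_S and indicator binding ratio
kappa_B:

    1 / A_Ca  = (1 + kappa_S + kappa_B) / delta_Ca_T
    tau_Ca    = (1 + kappa_S + kappa_B) / gamma

so plotting tau (or 1/A) against kappa_B across indicator
concentrations is linear with x-intercept -(1 + kappa_S); the
extrapolation to kappa_B = 0 yields the unperturbed transient.  The
linearized indicator binding ratio between two calcium levels is

    kappa_B = [B]_t * Kd / (([Ca]_1 + Kd) * ([Ca]_2 + Kd))

The module also evaluates the classical fourth-power dependence of the
EPSC on external calcium (with Ca/Mg competition) used to predict the
effect of raising [Ca2+]_o.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "RatiometryCalib",
    "BufferingFit",
    "ratio_to_ca",
    "ca_to_ratio",
    "kappa_b",
    "fit_transient",
    "extrapolate_buffering",
    "ca_cooperativity_ratio",
]


@dataclass(frozen=True)
class RatiometryCalib:
    """Indicator calibration: limiting ratios and dissociation constant.

    Defaults describe a 2.3 uM-Kd single-wavelength indicator referenced
    to a calcium-insensitive dye.
    """

    r_min: float
    r_max: float
    kd: float = 2.3  # uM

    def __post_init__(self) -> None:
        if not (self.r_max > self.r_min > 0):
            raise ValueError("need r_max > r_min > 0")
        if self.kd <= 0:
            raise ValueError("kd must be positive")


@dataclass
class BufferingFit:
    """Buffer-free transient parameters from the kappa extrapolation.

    kappa_s_tau / kappa_s_amp are the endogenous binding ratios from
    the decay-time and inverse-amplitude plots respectively (the two
    need not agree; both are reported).  a_ca (uM) and tau_ca (s) are
    the kappa_B = 0 transient; gamma (per s) the extrusion rate;
    delta_ca_total (uM) the total calcium increment per AP.
    """

    kappa_s_tau: float
    kappa_s_amp: float
    a_ca: float
    tau_ca: float
    gamma: float
    delta_ca_total: float

    @property
    def kappa_s(self) -> float:
        """Primary endogenous binding ratio (decay-time plot)."""
        return self.kappa_s_tau

    def to_dict(self) -> dict:
        return {
            "kappa_s_tau": self.kappa_s_tau,
            "kappa_s_amp": self.kappa_s_amp,
            "a_ca_uM": self.a_ca,
            "tau_ca_ms": self.tau_ca * 1e3,
            "gamma_per_s": self.gamma,
            "delta_ca_total_uM": self.delta_ca_total,
        }


def ratio_to_ca(r: float | np.ndarray, calib: RatiometryCalib) -> float | np.ndarray:
    """Convert fluorescence ratio(s) to [Ca2+]_i in uM.

    Ratios at or above r_max are saturated (error); ratios below r_min
    are clipped to zero with a warning.
    """
    r_arr = np.asarray(r, dtype=float)
    if np.any(r_arr >= calib.r_max):
        raise ValueError("ratio at or above r_max: indicator saturated")
    if np.any(r_arr < calib.r_min):
        warnings.warn("ratio below r_min: clipping negative [Ca2+] to 0",
                      stacklevel=2)
    ca = calib.kd * (r_arr - calib.r_min) / (calib.r_max - r_arr)
    ca = np.clip(ca, 0.0, None)
    return float(ca) if np.isscalar(r) else ca


def ca_to_ratio(ca: float | np.ndarray, calib: RatiometryCalib) -> float | np.ndarray:
    """Inverse conversion: R = (Kd*Rmin + [Ca]*Rmax) / (Kd + [Ca])."""
    ca_arr = np.asarray(ca, dtype=float)
    if np.any(ca_arr < 0):
        raise ValueError("[Ca2+] must be nonnegative")
    r = (calib.kd * calib.r_min + ca_arr * calib.r_max) / (calib.kd + ca_arr)
    return float(r) if np.isscalar(ca) else r


def kappa_b(b_total: float, kd: float, ca1: float, ca2: float) -> float:
    """Linearized indicator calcium-binding ratio between two calcium
    levels (e.g. rest and transient peak), in uM inputs."""
    if b_total < 0 or kd <= 0 or ca1 < 0 or ca2 < 0:
        raise ValueError("concentrations must be nonnegative, kd positive")
    return b_total * kd / ((ca1 + kd) * (ca2 + kd))


def fit_transient(
    times: np.ndarray, ca: np.ndarray
) -> tuple[float, float]:
    """Amplitude and decay time constant of a calcium transient.

    Takes a (time, concentration) trace containing a rise and a decay;
    the amplitude is the peak above the pre-rise baseline and the decay
    is a least-squares mono-exponential fit from the peak onward.
    Returns (amplitude, tau) in the units of the inputs.
    """
    times = np.asarray(times, dtype=float)
    ca = np.asarray(ca, dtype=float)
    if times.shape != ca.shape or times.size < 5:
        raise ValueError("need matching time/concentration arrays, >= 5 samples")
    i_peak = int(np.argmax(ca))
    baseline = float(np.median(ca[: max(i_peak, 1)])) if i_peak > 0 else float(ca.min())
    amp = float(ca[i_peak] - baseline)
    if amp <= 0 or np.ptp(ca) < 1e-12:
        raise ValueError("no transient found (non-decaying or constant trace)")
    t_dec = times[i_peak:] - times[i_peak]
    y_dec = ca[i_peak:] - baseline
    if t_dec.size < 4:
        raise ValueError("too few samples after the peak to fit a decay")

    def model(t, a, tau):
        return a * np.exp(-t / tau)

    tau0 = max((t_dec[-1] - t_dec[0]) / 3.0, 1e-9)
    popt, _ = curve_fit(model, t_dec, y_dec, p0=[amp, tau0],
                        bounds=([0, 1e-12], [np.inf, np.inf]), maxfev=20000)
    return float(popt[0]), float(popt[1])


def extrapolate_buffering(
    kappa_b_values: np.ndarray,
    taus: np.ndarray,
    amplitudes: np.ndarray,
) -> BufferingFit:
    """Endogenous buffering and buffer-free transient via linear
    extrapolation over indicator load.

    Fits tau = m_t * kappa_B + c_t and 1/A = m_a * kappa_B + c_a.
    Both lines have x-intercept -(1 + kappa_S), so kappa_S = c/m - 1
    for each plot (reported separately).  At kappa_B = 0 the transient
    is tau_ca = c_t and a_ca = 1/c_a; the extrusion rate is
    gamma = 1/m_t and the total per-AP calcium increment is
    delta_ca_total = 1/m_a.  Time units follow the inputs (use seconds).
    """
    kb = np.asarray(kappa_b_values, dtype=float)
    taus = np.asarray(taus, dtype=float)
    amps = np.asarray(amplitudes, dtype=float)
    if not (kb.shape == taus.shape == amps.shape):
        raise ValueError("inputs must have matching shapes")
    if np.unique(kb).size < 2:
        raise ValueError("need >= 2 distinct kappa_B values to extrapolate")
    if np.any(amps <= 0):
        raise ValueError("amplitudes must be positive")

    m_t, c_t = np.polyfit(kb, taus, 1)
    m_a, c_a = np.polyfit(kb, 1.0 / amps, 1)
    if m_t <= 0 or m_a <= 0 or c_t <= 0 or c_a <= 0:
        raise ValueError("degenerate extrapolation: non-positive slope or "
                         "intercept (tau and 1/A must increase with kappa_B)")
    kappa_s_tau = c_t / m_t - 1.0
    kappa_s_amp = c_a / m_a - 1.0
    return BufferingFit(
        kappa_s_tau=float(kappa_s_tau),
        kappa_s_amp=float(kappa_s_amp),
        a_ca=float(1.0 / c_a),
        tau_ca=float(c_t),
        gamma=float(1.0 / m_t),
        delta_ca_total=float(1.0 / m_a),
    )


def ca_cooperativity_ratio(
    ca_lo: float, ca_hi: float, k_ca: float = 1.1, k_mg: float = 3.0,
    mg: float = 1.0,
) -> float:
    """Predicted EPSC fold change for an external calcium step.

    Uses the classical fourth-power saturable Ca/Mg competition model
    f(c) = (c / (1 + c/K_Ca + [Mg]/K_Mg))**4 and returns
    f(ca_hi) / f(ca_lo).  All concentrations in mM.
    """
    if min(ca_lo, ca_hi, k_ca, k_mg) <= 0 or mg < 0:
        raise ValueError("concentrations and constants must be positive")

    def f(c: float) -> float:
        return (c / (1.0 + c / k_ca + mg / k_mg)) ** 4

    return f(ca_hi) / f(ca_lo)
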