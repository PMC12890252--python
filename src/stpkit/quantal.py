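"""Quantal analysis of evoked EPSC amplitudes.

Multiple-probability fluctuation analysis (MPFA) fits the ensemble
variance of EPSC amplitudes against their mean across conditions that
vary release probability.  For N independent sites with quantal size q
and intra-site quantal coefficient of variation CV_QS, the variance is
a parabola in the mean amplitude I:

    Var(I) = q * I * (1 + CV_QS**2) - I**2 / N

The vertex parameters (N, q) give the release probability of the first
pulse as p_r = I_1 / (N * q).  The module also provides quantal-size
estimation from asynchronous release event amplitudes (Gaussian mixture,
first-component rule), per-train summaries (paired-pulse ratio,
steady-state EPSC, synaptic efficacy) and the exponential rate constant
of short-term facilitation, k_STF.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from sklearn.mixture import GaussianMixture

__all__ = [
    "VMPoint",
    "QuantalFit",
    "TrainSummary",
    "mpfa_variance",
    "fit_mpfa",
    "fit_quantal_size",
    "summarize_train",
    "fit_kstf",
]


@dataclass(frozen=True)
class VMPoint:
    """One variance-mean point: ensemble mean (pA) and variance (pA^2)
    of a given pulse's EPSC amplitude across trials."""

    mean_amp: float
    var_amp: float
    pulse_index: int = 0
    frequency: float = 0.0

    def __post_init__(self) -> None:
        if self.var_amp < 0:
            raise ValueError("variance must be nonnegative")


@dataclass
class QuantalFit:
    """MPFA parabola parameters and derived release probability."""

    n_sites: float
    q: float
    cv_qs: float
    pr_first: float | None = None
    p_occ_first: float | None = None

    def to_dict(self) -> dict:
        return {
            "n_sites": self.n_sites, "q_pA": self.q, "cv_qs": self.cv_qs,
            "pr_first": self.pr_first, "p_occ_first": self.p_occ_first,
        }


@dataclass
class TrainSummary:
    """Per-train summary statistics of normalized EPSC amplitudes."""

    normalized_amps: np.ndarray
    ppr: float
    epsc_ss: float
    efficacy: float
    frequency: float
    k_stf: float | None = None

    def to_dict(self) -> dict:
        return {
            "normalized_amps": list(map(float, self.normalized_amps)),
            "ppr": self.ppr, "epsc_ss": self.epsc_ss,
            "efficacy_per_s": self.efficacy, "frequency_hz": self.frequency,
            "k_stf_per_s": self.k_stf,
        }


def mpfa_variance(
    mean_amp: float | np.ndarray, q: float, n_sites: float, cv_qs: float
) -> float | np.ndarray:
    """MPFA variance parabola Var = q*I*(1+CV_QS^2) - I^2/N.

    Raises when the mean exceeds N*q (release probability above 1).
    """
    if q <= 0 or n_sites <= 0:
        raise ValueError("q and n_sites must be positive")
    if cv_qs < 0:
        raise ValueError("cv_qs must be nonnegative")
    mean_arr = np.asarray(mean_amp, dtype=float)
    if np.any(mean_arr < 0):
        raise ValueError("mean amplitude must be nonnegative")
    if np.any(mean_arr > n_sites * q * (1 + 1e-12)):
        raise ValueError("mean amplitude exceeds N*q (implies p > 1)")
    out = q * mean_arr * (1.0 + cv_qs**2) - mean_arr**2 / n_sites
    return float(out) if np.isscalar(mean_amp) else out


def fit_mpfa(
    points: list[VMPoint],
    cv_qs: float = 0.2,
    first_pulse_mean: float | None = None,
    p_v: float = 1.0,
    weights: np.ndarray | None = None,
) -> QuantalFit:
    """Least-squares fit of (q, N) to variance-mean points.

    Requires at least 3 points with distinct means and enough spread to
    identify the parabola's curvature (points confined to the rising
    limb leave N unidentified and raise).  ``first_pulse_mean`` (the
    mean amplitude of the first pulse of a low-frequency train) yields
    pr_first = first_pulse_mean / (N * q), and p_occ_first = pr_first /
    p_v under the stated fusion probability.
    """
    means = np.asarray([p.mean_amp for p in points], dtype=float)
    variances = np.asarray([p.var_amp for p in points], dtype=float)
    if means.size < 3:
        raise ValueError("need at least 3 variance-mean points")
    if np.unique(means).size < 3:
        raise ValueError("degenerate design: need >= 3 distinct mean amplitudes")

    def model(i, q, n):
        return q * i * (1.0 + cv_qs**2) - i**2 / n

    q0 = max(np.max(variances) / max(np.max(means), 1e-12), 1e-6)
    n0 = max(np.max(means) / q0, 1.0)
    sigma = None if weights is None else 1.0 / np.sqrt(np.asarray(weights, float))
    popt, pcov = curve_fit(
        model, means, variances, p0=[q0, n0], sigma=sigma,
        bounds=([1e-9, 1e-9], [np.inf, np.inf]), maxfev=20000,
    )
    q, n = map(float, popt)
    # Identifiability: the curvature is only constrained when the design
    # reaches an appreciable fraction of the pool capacity N*q (p not
    # uniformly small) and when the covariance of N is finite.
    with np.errstate(invalid="ignore"):
        n_sd = float(np.sqrt(pcov[1, 1]))
    if (not np.isfinite(n_sd) or n_sd > 10.0 * n
            or np.max(means) < 0.2 * n * q):
        raise ValueError(
            "N unidentifiable: variance-mean points do not constrain the "
            "parabola curvature (all points on the linear limb?)"
        )
    pr = p_occ = None
    if first_pulse_mean is not None:
        pr = float(first_pulse_mean / (n * q))
        p_occ = pr / p_v
    return QuantalFit(n_sites=n, q=q, cv_qs=cv_qs, pr_first=pr, p_occ_first=p_occ)


def fit_quantal_size(
    event_amps: np.ndarray, max_components: int = 2, min_events: int = 50
) -> tuple[float, float]:
    """Quantal size from asynchronous event amplitudes.

    Fits 1- and 2-component Gaussian mixtures (deterministic
    quantile-based initializations) to the amplitude distribution,
    selects the model by BIC, and returns (mean, CV) of the
    lowest-mean component — the single-quantum peak; the higher
    component absorbs double events.
    """
    amps = np.asarray(event_amps, dtype=float).ravel()
    if amps.size < min_events:
        raise ValueError(f"need at least {min_events} events, got {amps.size}")
    x = amps.reshape(-1, 1)
    best = None
    best_bic = np.inf
    for k in range(1, max_components + 1):
        quantiles = np.quantile(amps, (np.arange(k) + 0.5) / k).reshape(-1, 1)
        gm = GaussianMixture(
            n_components=k, covariance_type="full",
            means_init=quantiles, n_init=1, random_state=0, max_iter=500,
        ).fit(x)
        bic = gm.bic(x)
        if bic < best_bic:
            best, best_bic = gm, bic
    assert best is not None
    order = np.argsort(best.means_.ravel())
    mu = float(best.means_.ravel()[order[0]])
    sd = float(np.sqrt(best.covariances_.reshape(-1)[order[0]]))
    return mu, sd / mu


def summarize_train(
    amps: np.ndarray,
    frequency: float,
    times: np.ndarray | None = None,
    with_kstf: bool = False,
) -> TrainSummary:
    """Standard train summary of (normalized) per-pulse amplitudes.

    ppr = amp2/amp1; epsc_ss = mean of the last five normalized
    amplitudes; efficacy = epsc_ss * frequency (per second).  Raw
    amplitudes are normalized to the first pulse, so the summary is
    invariant under rescaling.
    """
    amps = np.asarray(amps, dtype=float)
    if amps.size < 2:
        raise ValueError("need at least 2 pulses for PPR")
    if amps[0] <= 0:
        raise ValueError("first amplitude must be positive for normalization")
    norm = amps / amps[0]
    ppr = float(norm[1])
    if amps.size >= 6:
        epsc_ss = float(np.mean(norm[-5:]))
    else:
        raise ValueError("need at least 6 pulses for steady-state EPSC")
    k_stf = None
    if with_kstf:
        t = times if times is not None else np.arange(amps.size) / frequency
        k_stf, _ = fit_kstf(norm, np.asarray(t, dtype=float))
    return TrainSummary(
        normalized_amps=norm, ppr=ppr, epsc_ss=epsc_ss,
        efficacy=epsc_ss * frequency, frequency=frequency, k_stf=k_stf,
    )


def fit_kstf(
    amps: np.ndarray, times: np.ndarray
) -> tuple[float, float]:
    """Rate constant of short-term facilitation.

    Fits A(t) = a_ss - (a_ss - 1) * exp(-k_stf * (t - t1)) to the
    normalized amplitude sequence (t1 = time of the first pulse) and
    returns (k_stf, a_ss).  A flat sequence leaves k_stf unidentifiable
    and raises.
    """
    amps = np.asarray(amps, dtype=float)
    times = np.asarray(times, dtype=float)
    if amps.size < 4:
        raise ValueError("need at least 4 pulses")
    if np.any(amps <= 0):
        raise ValueError("amplitudes must be positive")
    if np.ptp(amps) < 1e-9:
        raise ValueError("flat amplitude sequence: k_stf unidentifiable")
    t1 = times[0]

    def model(t, k, a_ss):
        return a_ss - (a_ss - 1.0) * np.exp(-k * (t - t1))

    a_guess = float(np.mean(amps[-3:]))
    span = max(times[-1] - t1, 1e-9)
    try:
        popt, _ = curve_fit(
            model, times, amps, p0=[1.0 / span, a_guess],
            bounds=([1e-9, 1e-9], [np.inf, np.inf]), maxfev=20000,
        )
    except RuntimeError as exc:
        raise ValueError(f"k_stf fit did not converge: {exc}") from exc
    return float(popt[0]), float(popt[1])
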