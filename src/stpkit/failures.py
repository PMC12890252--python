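"""Two-pulse success/failure analysis over binomial release sites.

For a synapse with N independent sites at occupancy p_occ, the joint
probabilities of success (1) and failure (0) on a pair of pulses
separated by an interval isi constrain the docking rate k1 and the
vesicular fusion probability p_v.  Writing

- n0: docked vesicles before the 1st AP  (~ Binomial(N, p_occ)),
- n1: docked vesicles remaining after the 1st AP,
- n2: docked vesicles just before the 2nd AP,

the inter-pulse occupancy dynamics assume at most one transition per
site per interval: a docked site undocks with probability
B = 1 - exp(-b1 * isi) and an empty site docks with probability
F = 1 - exp(-k1 * isi), with sites vacated by release not refilled
within the same interval (the vacancy count available for docking is
o1 = N - n1).  A pulse fails when no docked vesicle fuses, probability
(1 - p_v)^(docked count).

Fitting pins the per-site release probability p_r to the observed
first-pulse failure rate via P(F1) = (1 - p_r)^N, leaving (k1, p_v)
free with p_occ = p_r / p_v and b1 = k1 (1 - p_occ) / p_occ.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize as _opt
from scipy.special import gammaln
from scipy.stats import binom

__all__ = [
    "FailureObservation",
    "FailureModelFit",
    "pr_from_failure",
    "predict_joint",
    "cost",
    "optimize",
    "observed_joint_from_trials",
]

DEFAULT_BOUNDS = ((4.0, 8.0), (0.8, 1.0))


@dataclass(frozen=True)
class FailureObservation:
    """Observed two-pulse failure statistics.

    Either supply the full joint 4-vector (P11, P10, P01, P00) or just
    the marginal failure rates ``p_f1`` and ``p_f1f2``; in the latter
    case the success side of the cost is split pro rata to the model
    prediction (its residuals are then zero by construction).
    """

    p_f1: float
    p_f1f2: float
    n_sites: int = 6
    isi: float = 0.02
    joint: tuple[float, float, float, float] | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_f1 <= 1.0 and 0.0 <= self.p_f1f2 <= 1.0):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.p_f1f2 > self.p_f1 + 1e-12:
            raise ValueError("P(F1,F2) cannot exceed P(F1)")
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if self.isi <= 0:
            raise ValueError("isi must be positive")
        if self.joint is not None:
            j = np.asarray(self.joint, dtype=float)
            if j.shape != (4,) or np.any(j < 0) or abs(j.sum() - 1.0) > 1e-6:
                raise ValueError("joint must be 4 nonnegative values summing to 1")


@dataclass
class FailureModelFit:
    """Fitted refilling-model parameters and derived quantities."""

    k1: float
    p_v: float
    b1: float
    p_occ: float
    p_r: float
    predicted_joint: tuple[float, float, float, float]
    cost: float
    converged: bool = True
    on_boundary: bool = False
    message: str = ""

    def to_dict(self) -> dict:
        p11, p10, p01, p00 = self.predicted_joint
        return {
            "k1_per_s": self.k1, "p_v": self.p_v, "b1_per_s": self.b1,
            "p_occ": self.p_occ, "p_r": self.p_r,
            "predicted": {"P11": p11, "P10": p10, "P01": p01, "P00": p00},
            "cost": self.cost, "converged": self.converged,
            "on_boundary": self.on_boundary,
        }


def pr_from_failure(p_f1: float, n_sites: int) -> float:
    """Per-site release probability from the first-pulse failure rate.

    Inverts P(F1) = (1 - p_r)^N:  p_r = 1 - p_f1**(1/N).
    """
    if not 0.0 < p_f1 <= 1.0:
        raise ValueError("p_f1 must be in (0, 1]; p_r is unidentifiable at 0")
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    return 1.0 - p_f1 ** (1.0 / n_sites)


def _log_comb(n: np.ndarray | int, k: np.ndarray | int) -> np.ndarray:
    """log C(n, k), valid for n up to a few hundred."""
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def _p_n2_given_n1(n2: int, n1: int, n_sites: int, big_b: float, big_f: float) -> float:
    """One-transition-per-interval refilling kernel.

    P(n2 | n1) = sum_j C(n1, j) C(o1, i+j) B^j (1-B)^(n1-j)
                 * F^(i+j) (1-F)^(o1-i-j),  i = n2 - n1, o1 = N - n1,
    restricted to 0 <= i + j <= o1 (j docked sites undock, i + j of the
    o1 vacancies refill).
    """
    o1 = n_sites - n1
    i = n2 - n1
    total = 0.0
    for j in range(n1 + 1):
        m = i + j
        if not 0 <= m <= o1:
            continue
        log_term = (_log_comb(n1, j) + _log_comb(o1, m)
                    + _xlogy(j, big_b) + _xlogy(n1 - j, 1 - big_b)
                    + _xlogy(m, big_f) + _xlogy(o1 - m, 1 - big_f))
        total += float(np.exp(log_term))
    return total


def _xlogy(k: float, p: float) -> float:
    if k == 0:
        return 0.0
    if p <= 0:
        return -np.inf
    return k * np.log(p)


def predict_joint(
    k1: float,
    p_v: float,
    n_sites: int,
    p_occ: float,
    isi: float,
) -> tuple[float, float, float, float]:
    """Exact joint outcome probabilities (P11, P10, P01, P00).

    Sums P(n0) * P(n1 | n0) * P(n2 | n1) over all triples, applying the
    second-pulse failure factor (1 - p_v)^n2; splits the failure mass by
    whether the first pulse released anything (n1 == n0 vs n1 < n0) and
    recovers the success entries from the exact marginals
    P(F1) = sum_n0 P(n0) (1 - p_v)^n0 and P(S1) = 1 - P(F1).
    """
    if not 0.0 <= p_v <= 1.0:
        raise ValueError("p_v must be in [0, 1]")
    if not 0.0 <= p_occ <= 1.0:
        raise ValueError(
            f"p_occ={p_occ:.4f} outside [0, 1]; (p_occ, p_v) imply p_r > 1"
        )
    if k1 < 0 or isi <= 0:
        raise ValueError("need k1 >= 0 and isi > 0")
    n = n_sites
    if p_occ in (0.0, 1.0):
        b1 = 0.0 if p_occ == 1.0 else np.inf
    else:
        b1 = k1 * (1.0 - p_occ) / p_occ
    big_b = 1.0 - np.exp(-b1 * isi) if np.isfinite(b1) else 1.0
    big_f = 1.0 - np.exp(-k1 * isi)

    p_n0 = binom.pmf(np.arange(n + 1), n, p_occ)
    p00 = 0.0
    p10 = 0.0
    for n0 in range(n + 1):
        if p_n0[n0] == 0.0:
            continue
        for n1 in range(n0 + 1):
            p_rel = binom.pmf(n0 - n1, n0, p_v)  # release n0-n1 of n0
            if p_rel == 0.0:
                continue
            for n2 in range(n + 1):
                p_ref = _p_n2_given_n1(n2, n1, n, big_b, big_f)
                if p_ref == 0.0:
                    continue
                contrib = p_n0[n0] * p_rel * p_ref * (1.0 - p_v) ** n2
                if n1 == n0:
                    p00 += contrib
                else:
                    p10 += contrib
    p_f1 = float(np.sum(p_n0 * (1.0 - p_v) ** np.arange(n + 1)))
    p_s1 = 1.0 - p_f1
    p01 = p_f1 - p00
    p11 = p_s1 - p10
    return (p11, p10, max(p01, 0.0), p00)


def _observed_vector(
    obs: FailureObservation, predicted: tuple[float, float, float, float]
) -> np.ndarray:
    """Observed 4-vector; success mass split pro rata to the model
    prediction when only failure marginals were recorded."""
    if obs.joint is not None:
        return np.asarray(obs.joint, dtype=float)
    p11_m, p10_m, _, _ = predicted
    p_s1 = 1.0 - obs.p_f1
    s_tot = p11_m + p10_m
    if s_tot > 0:
        p11 = p_s1 * p11_m / s_tot
        p10 = p_s1 * p10_m / s_tot
    else:
        p11 = p10 = p_s1 / 2.0
    p00 = obs.p_f1f2
    p01 = obs.p_f1 - obs.p_f1f2
    return np.asarray([p11, p10, p01, p00])


def cost(params: Sequence[float], obs: FailureObservation) -> float:
    """Sum of squared errors between observed and predicted joint
    probabilities at (k1, p_v), with p_r pinned by the observed
    first-pulse failure rate."""
    k1, p_v = float(params[0]), float(params[1])
    p_r = pr_from_failure(obs.p_f1, obs.n_sites)
    p_occ = p_r / p_v
    if p_occ > 1.0:
        return np.inf
    pred = predict_joint(k1, p_v, obs.n_sites, p_occ, obs.isi)
    observed = _observed_vector(obs, pred)
    return float(np.sum((observed - np.asarray(pred)) ** 2))


def optimize(
    obs: FailureObservation,
    bounds: tuple[tuple[float, float], tuple[float, float]] = DEFAULT_BOUNDS,
    n_starts: int = 5,
) -> FailureModelFit:
    """Bounded minimization of the failure cost over (k1, p_v).

    Runs a deterministic n_starts x n_starts grid of L-BFGS-B starts
    over the box and keeps the best minimum.  Default box is
    k1 in [4, 8] /s and p_v in [0.8, 1].
    """
    (k_lo, k_hi), (v_lo, v_hi) = bounds
    if not (k_lo < k_hi and v_lo < v_hi):
        raise ValueError("bounds must be nonempty intervals")
    p_r = pr_from_failure(obs.p_f1, obs.n_sites)
    v_lo = max(v_lo, p_r)  # p_occ = p_r / p_v must stay <= 1

    best = None
    any_converged = False
    starts_k = np.linspace(k_lo, k_hi, n_starts)
    starts_v = np.linspace(v_lo, v_hi, n_starts)
    for k0 in starts_k:
        for v0 in starts_v:
            res = _opt.minimize(
                cost, x0=[k0, v0], args=(obs,),
                method="L-BFGS-B", bounds=[(k_lo, k_hi), (v_lo, v_hi)],
            )
            any_converged |= bool(res.success)
            if best is None or res.fun < best.fun:
                best = res
    assert best is not None
    k1, p_v = map(float, best.x)
    p_occ = p_r / p_v
    b1 = k1 * (1.0 - p_occ) / p_occ
    on_boundary = (
        min(k1 - k_lo, k_hi - k1) < 1e-6 * (k_hi - k_lo)
        or min(p_v - v_lo, v_hi - p_v) < 1e-6 * (v_hi - v_lo)
    )
    return FailureModelFit(
        k1=k1, p_v=p_v, b1=b1, p_occ=p_occ, p_r=p_r,
        predicted_joint=predict_joint(k1, p_v, obs.n_sites, p_occ, obs.isi),
        cost=float(best.fun),
        converged=any_converged,
        on_boundary=on_boundary,
        message=str(best.message),
    )


def observed_joint_from_trials(s1: np.ndarray, s2: np.ndarray) -> tuple[float, float, float, float]:
    """Tally per-trial success booleans into joint frequencies
    (P11, P10, P01, P00)."""
    s1 = np.asarray(s1, dtype=bool)
    s2 = np.asarray(s2, dtype=bool)
    if s1.shape != s2.shape or s1.ndim != 1 or s1.size == 0:
        raise ValueError("s1 and s2 must be equal-length nonempty 1-D arrays")
    n = s1.size
    return (
        float(np.sum(s1 & s2)) / n,
        float(np.sum(s1 & ~s2)) / n,
        float(np.sum(~s1 & s2)) / n,
        float(np.sum(~s1 & ~s2)) / n,
    )
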