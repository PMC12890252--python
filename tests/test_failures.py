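"""Two-pulse failure analysis: closed-form predictions, brute-force
enumeration oracle, cost structure and (k1, p_v) optimization."""

from math import comb, exp

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from stpkit.failures import (FailureObservation, cost, observed_joint_from_trials,
                             optimize, pr_from_failure, predict_joint)
from stpkit.pool import PoolParams, StimTrain, simulate_stochastic


def enumerate_joint(k1, p_v, n, p_occ, isi):
    """Independent oracle: direct float summation over all (n0, n1, n2)
    triples with plain combinadics (no log-space, no scipy)."""
    b1 = k1 * (1 - p_occ) / p_occ
    B = 1 - exp(-b1 * isi)
    F = 1 - exp(-k1 * isi)

    def p_n0(n0):
        return comb(n, n0) * p_occ**n0 * (1 - p_occ) ** (n - n0)

    def p_n1(n1, n0):
        return comb(n0, n1) * (1 - p_v) ** n1 * p_v ** (n0 - n1)

    def p_n2(n2, n1):
        o1, i = n - n1, n2 - n1
        return sum(
            comb(n1, j) * comb(o1, i + j) * B**j * (1 - B) ** (n1 - j)
            * F ** (i + j) * (1 - F) ** (o1 - i - j)
            for j in range(n1 + 1) if 0 <= i + j <= o1
        )

    p00 = p10 = 0.0
    for n0 in range(n + 1):
        for n1 in range(n0 + 1):
            for n2 in range(n + 1):
                p = p_n0(n0) * p_n1(n1, n0) * p_n2(n2, n1) * (1 - p_v) ** n2
                if n1 == n0:
                    p00 += p
                else:
                    p10 += p
    pf1 = sum(p_n0(n0) * (1 - p_v) ** n0 for n0 in range(n + 1))
    return 1 - pf1 - p10, p10, pf1 - p00, p00


PAPER_OPT = dict(k1=5.21, p_v=0.999, n_sites=6, isi=0.02)


def _paper_p_occ():
    return pr_from_failure(0.106, 6) / 0.999


class TestPrFromFailure:
    @pytest.mark.parametrize("p_f1, n, expected", [
        (0.106, 6, 0.312),
        (1.0, 6, 0.0),
        (0.5, 1, 0.5),
    ])
    def test_examples(self, p_f1, n, expected):
        assert pr_from_failure(p_f1, n) == pytest.approx(expected, abs=5e-4)

    def test_zero_failure_unidentifiable(self):
        with pytest.raises(ValueError, match="unidentifiable"):
            pr_from_failure(0.0, 6)


class TestPredictJoint:
    def test_reference_optimum(self):
        p11, p10, p01, p00 = predict_joint(
            PAPER_OPT["k1"], PAPER_OPT["p_v"], 6, _paper_p_occ(), 0.02)
        assert 100 * p11 == pytest.approx(41.5, rel=5e-3)
        assert 100 * p10 == pytest.approx(47.9, rel=5e-3)
        assert 100 * p01 == pytest.approx(4.93, rel=5e-3)
        assert 100 * p00 == pytest.approx(5.67, rel=5e-3)

    def test_no_refill_limit(self):
        # k1=0, p_v=1: an emptied synapse cannot refill, so the second
        # pulse fails iff the first one did: P00 = (1-p_occ)^N
        p11, p10, p01, p00 = predict_joint(0.0, 1.0, 6, 0.3, 0.02)
        assert p00 == pytest.approx(0.7**6, abs=1e-12)
        assert p01 == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("k1, p_v, n, p_occ", [
        (5.21, 0.999, 6, 0.3123), (2.0, 0.9, 4, 0.5),
        (10.0, 0.85, 8, 0.25), (0.5, 1.0, 3, 0.8),
    ])
    def test_matches_enumeration_oracle(self, k1, p_v, n, p_occ):
        ours = predict_joint(k1, p_v, n, p_occ, 0.02)
        brute = enumerate_joint(k1, p_v, n, p_occ, 0.02)
        assert np.allclose(ours, brute, atol=1e-12)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(k1=st.floats(0.1, 30.0), p_v=st.floats(0.0, 1.0),
           p_occ=st.floats(0.01, 0.99), n=st.integers(1, 8))
    def test_sums_to_one_and_failure_marginal(self, k1, p_v, p_occ, n):
        out = predict_joint(k1, p_v, n, p_occ, 0.02)
        assert sum(out) == pytest.approx(1.0, abs=1e-10)
        pf1 = out[2] + out[3]
        assert pf1 == pytest.approx((1 - p_v * p_occ) ** n, abs=1e-10)

    def test_double_failure_decreases_with_k1(self):
        p00 = [predict_joint(k1, 0.999, 6, 0.31, 0.02)[3]
               for k1 in (1.0, 3.0, 5.0, 8.0, 12.0)]
        assert np.all(np.diff(p00) < 0)

    def test_monte_carlo_oracle_agreement(self):
        # per-interval-BF stochastic dialect against the closed form
        p_occ = _paper_p_occ()
        k1 = PAPER_OPT["k1"]
        b1 = k1 * (1 - p_occ) / p_occ
        pool = PoolParams(6, k1, b1, PAPER_OPT["p_v"])
        df = simulate_stochastic(pool, StimTrain((0.0, 0.02)), 1_000_000,
                                 seed=42, dialect="per-interval-BF")
        q = df["quanta_released"].to_numpy().reshape(-1, 2)
        emp = observed_joint_from_trials(q[:, 0] > 0, q[:, 1] > 0)
        pred = predict_joint(k1, PAPER_OPT["p_v"], 6, p_occ, 0.02)
        n = q.shape[0]
        for e, p in zip(emp, pred):
            se = np.sqrt(p * (1 - p) / n)
            assert abs(e - p) < 3 * se


class TestCost:
    def test_zero_at_exact_match(self):
        p_occ = _paper_p_occ()
        pred = predict_joint(5.21, 0.999, 6, p_occ, 0.02)
        pf1 = pred[2] + pred[3]
        obs = FailureObservation(p_f1=pf1, p_f1f2=pred[3], n_sites=6,
                                 isi=0.02, joint=pred)
        assert cost((5.21, 0.999), obs) == pytest.approx(0.0, abs=1e-20)

    def test_failure_only_residuals_at_reference(self):
        # with the success side split pro rata to the prediction, the
        # cost at the reference optimum is the two failure residuals:
        # (0.062 - P00)^2 + (0.044 - P01)^2 ~ 5.6e-5
        obs = FailureObservation(p_f1=0.106, p_f1f2=0.062)
        c = cost((5.21, 0.999), obs)
        assert c == pytest.approx(5.6e-5, rel=0.05)

    def test_nonnegative(self):
        obs = FailureObservation(p_f1=0.106, p_f1f2=0.062)
        for k1 in (4.0, 6.0, 8.0):
            for p_v in (0.8, 0.9, 1.0):
                assert cost((k1, p_v), obs) >= 0.0


class TestOptimize:
    def test_parameter_recovery_from_self_generated_joint(self):
        k1_true, pv_true, p_occ_true = 6.0, 0.95, 0.33
        joint = predict_joint(k1_true, pv_true, 6, p_occ_true, 0.02)
        obs = FailureObservation(
            p_f1=joint[2] + joint[3], p_f1f2=joint[3],
            n_sites=6, isi=0.02, joint=joint)
        fit = optimize(obs)
        assert fit.k1 == pytest.approx(k1_true, abs=1e-3)
        assert fit.p_v == pytest.approx(pv_true, abs=1e-3)
        assert fit.cost < 1e-12

    def test_derived_fields_consistent(self):
        obs = FailureObservation(p_f1=0.106, p_f1f2=0.062)
        fit = optimize(obs)
        assert fit.p_occ == pytest.approx(fit.p_r / fit.p_v, abs=1e-9)
        assert fit.b1 == pytest.approx(
            fit.k1 * (1 - fit.p_occ) / fit.p_occ, abs=1e-9)
        assert sum(fit.predicted_joint) == pytest.approx(1.0, abs=1e-10)

    def test_boundary_optimum_flagged(self):
        # an observation demanding more refilling than the box allows
        # pushes k1 to the upper bound
        joint = predict_joint(15.0, 0.95, 6, 0.33, 0.02)
        obs = FailureObservation(p_f1=joint[2] + joint[3], p_f1f2=joint[3],
                                 n_sites=6, isi=0.02, joint=joint)
        fit = optimize(obs)
        assert fit.on_boundary
        assert fit.k1 == pytest.approx(8.0, abs=1e-6)


class TestObservationValidation:
    def test_double_failure_cannot_exceed_first_failure(self):
        with pytest.raises(ValueError):
            FailureObservation(p_f1=0.05, p_f1f2=0.1)

    def test_joint_must_sum_to_one(self):
        with pytest.raises(ValueError):
            FailureObservation(p_f1=0.1, p_f1f2=0.05,
                               joint=(0.5, 0.3, 0.05, 0.05))
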