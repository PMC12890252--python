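"""MPFA, quantal-size, train-summary and facilitation-rate tests."""

import numpy as np
import pytest

from stpkit.pool import PoolParams, StimTrain, simulate_stochastic
from stpkit.quantal import (VMPoint, fit_kstf, fit_mpfa, fit_quantal_size,
                            mpfa_variance, summarize_train)
from stpkit.synth import SynthEPSCConfig, gen_async_events, gen_epsc_trains


class TestMpfaVariance:
    def test_zero_mean_zero_variance(self):
        assert mpfa_variance(0.0, 25.0, 5.3, 0.2) == 0.0

    def test_saturation_leaves_pure_quantal_variance(self):
        # at p=1 the binomial term vanishes; Var = N q^2 CV^2
        n, q, cv = 5.0, 20.0, 0.2
        var = mpfa_variance(n * q, q, n, cv)
        assert var == pytest.approx(n * q**2 * cv**2 + q * n * q - n * q**2)
        assert var == pytest.approx(n * q**2 * cv**2)

    def test_reference_evaluation(self):
        # parabola at the fitted synapse parameters, p ~ 0.32
        assert mpfa_variance(42.4, 25.0, 5.3, 0.2) == pytest.approx(763.2, abs=0.5)

    def test_mean_above_pool_capacity_rejected(self):
        with pytest.raises(ValueError, match="p > 1"):
            mpfa_variance(200.0, 25.0, 5.3, 0.2)

    def test_concave_with_root_at_zero_and_beyond_saturation(self):
        # the parabola q*I*(1+cv^2) - I^2/N vanishes at I=0 and at
        # I = N*q*(1+cv^2); the physical domain ends at I = N*q where
        # the residual variance is the pure quantal term
        q, n, cv = 25.0, 5.3, 0.2
        means = np.linspace(0, n * q, 50)
        var = mpfa_variance(means, q, n, cv)
        assert var[0] == pytest.approx(0.0, abs=1e-9)
        assert np.all(np.diff(var, 2) < 0)  # concave
        coeff_lin = q * (1 + cv**2)
        nontrivial_root = coeff_lin * n
        assert coeff_lin * nontrivial_root - nontrivial_root**2 / n == \
            pytest.approx(0.0, abs=1e-9)


class TestFitMpfa:
    def test_exact_recovery_noise_free(self):
        means = np.array([10.0, 30.0, 60.0, 90.0, 110.0])
        pts = [VMPoint(m, mpfa_variance(m, 25.0, 5.3, 0.2)) for m in means]
        fit = fit_mpfa(pts, cv_qs=0.2, first_pulse_mean=42.4)
        assert fit.n_sites == pytest.approx(5.3, abs=1e-6)
        assert fit.q == pytest.approx(25.0, abs=1e-6)
        assert fit.pr_first == pytest.approx(42.4 / (5.3 * 25.0), abs=1e-6)

    def test_recovery_under_sampling_noise(self):
        # occupancy manipulated via k1 to sweep p over ~0.1-0.9,
        # 100 trials per point
        rng_seeds = iter(range(100, 200))
        pts = []
        for p_occ in (0.1, 0.2, 0.35, 0.5, 0.65, 0.8, 0.9):
            k1 = 16.1 * p_occ / (1 - p_occ)
            cfg = SynthEPSCConfig(
                pool=PoolParams(6, k1, 16.1, 1.0), stim=StimTrain((0.0,)),
                q=25.0, cv_qs=0.2, n_trials=100, seed=next(rng_seeds))
            df, _ = gen_epsc_trains(cfg)
            amps = df["amp_pA"].to_numpy()
            pts.append(VMPoint(amps.mean(), amps.var(ddof=1)))
        fit = fit_mpfa(pts, cv_qs=0.2)
        assert fit.n_sites == pytest.approx(6.0, rel=0.15)
        assert fit.q == pytest.approx(25.0, rel=0.15)

    def test_recovery_from_stochastic_pool_large_n(self):
        # continuous-time dialect, p_v=1, 1e4 trials/point: bias < 5%
        pts = []
        for i, p_occ in enumerate((0.15, 0.3, 0.5, 0.7, 0.85)):
            k1 = 16.1 * p_occ / (1 - p_occ)
            cfg = SynthEPSCConfig(
                pool=PoolParams(6, k1, 16.1, 1.0), stim=StimTrain((0.0,)),
                q=25.0, cv_qs=0.2, n_trials=10_000, seed=300 + i)
            df, _ = gen_epsc_trains(cfg)
            amps = df["amp_pA"].to_numpy()
            pts.append(VMPoint(amps.mean(), amps.var(ddof=1)))
        fit = fit_mpfa(pts, cv_qs=0.2)
        assert fit.n_sites == pytest.approx(6.0, rel=0.05)
        assert fit.q == pytest.approx(25.0, rel=0.05)

    def test_rising_limb_only_unidentifiable(self):
        means = np.array([1.0, 2.0, 3.0, 4.0])  # p << 1: linear regime
        pts = [VMPoint(m, mpfa_variance(m, 25.0, 5.3, 0.2)) for m in means]
        with pytest.raises(ValueError, match="unidentifiable"):
            fit_mpfa(pts, cv_qs=0.2)

    def test_degenerate_design_rejected(self):
        pts = [VMPoint(10.0, 100.0)] * 4
        with pytest.raises(ValueError, match="degenerate"):
            fit_mpfa(pts)


class TestFitQuantalSize:
    def test_unimodal_recovery(self):
        amps = gen_async_events(q=24.0, cv=0.25, n=5000, seed=9)
        q, cv = fit_quantal_size(amps)
        assert q == pytest.approx(24.0, rel=0.05)
        assert cv == pytest.approx(0.25, rel=0.1)

    def test_bimodal_returns_first_component(self):
        a1 = gen_async_events(q=24.0, cv=0.12, n=3000, seed=10)
        a2 = gen_async_events(q=48.0, cv=0.12, n=1000, seed=11)
        q, _ = fit_quantal_size(np.concatenate([a1, a2]))
        assert q == pytest.approx(24.0, rel=0.08)

    def test_too_few_events_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            fit_quantal_size(np.ones(10) * 24.0)


class TestSummarizeTrain:
    def test_flat_train(self):
        s = summarize_train(np.ones(20), frequency=10.0)
        assert s.ppr == 1.0
        assert s.epsc_ss == 1.0
        assert s.efficacy == 10.0

    def test_ppr_io_format(self):
        amps = np.array([1.0, 0.19, 0.3, 0.5, 0.8, 1.0, 1.1])
        s = summarize_train(amps, frequency=40.0)
        assert s.ppr == pytest.approx(0.19)

    def test_scale_invariance(self):
        amps = np.array([120.0, 60.0, 80.0, 100.0, 130.0, 140.0, 150.0])
        a = summarize_train(amps, frequency=20.0)
        b = summarize_train(amps * 7.3, frequency=20.0)
        assert a.ppr == pytest.approx(b.ppr)
        assert a.epsc_ss == pytest.approx(b.epsc_ss)

    def test_average_of_identical_trains_matches_single(self):
        amps = np.array([1.0, 0.5, 0.8, 1.1, 1.5, 1.8, 2.0, 2.1])
        stacked = np.mean([amps] * 20, axis=0)
        a = summarize_train(amps, frequency=5.0)
        b = summarize_train(stacked, frequency=5.0)
        assert a.epsc_ss == pytest.approx(b.epsc_ss)

    def test_too_few_pulses(self):
        with pytest.raises(ValueError):
            summarize_train(np.array([1.0, 0.5, 0.8]), frequency=5.0)


class TestFitKstf:
    @pytest.mark.parametrize("k_true, freq, n, rel", [
        (1.27, 5.0, 20, 0.02),    # slow facilitation on a 5 Hz grid
        (24.27, 40.0, 20, 0.05),  # fast facilitation on a 40 Hz grid
    ])
    def test_rate_recovery(self, k_true, freq, n, rel):
        t = np.arange(n) / freq
        a_ss = 2.4
        amps = a_ss - (a_ss - 1.0) * np.exp(-k_true * t)
        k, a = fit_kstf(amps, t)
        assert k == pytest.approx(k_true, rel=rel)
        assert a == pytest.approx(a_ss, rel=0.02)

    def test_flat_sequence_flagged(self):
        with pytest.raises(ValueError, match="unidentifiable"):
            fit_kstf(np.ones(10), np.arange(10) / 5.0)
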