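import numpy as np
import pytest

from striatal_gamma.signal_core import TimeSeries
from striatal_gamma.gamma_events import GammaEvent, GammaEventSet
from striatal_gamma.phase_circular import (
    ChannelDismissedError,
    CircularDistribution,
    PhaseSeries,
    amplitude_modulation,
    dip_test,
    phase_difference,
    phase_lock_vector,
    phase_slope,
    phases_at_events,
    rayleigh_test,
    resultant_vector,
    wrap_angle,
)
from striatal_gamma._dip import dip_statistic

from oracles import dip_lp


def phase_of(freq, duration=10.0, rate=1000.0, phi0=0.0):
    t = np.arange(0, duration, 1 / rate)
    return PhaseSeries(wrap_angle(2 * np.pi * freq * t + phi0), rate)


class TestPhaseSlope:
    def test_pure_sine(self):
        mean_freq, mod = phase_slope(phase_of(1.5))
        assert mean_freq == pytest.approx(1.5, abs=0.01)
        assert mod < 0.1

    def test_chirp(self):
        t = np.arange(0, 10, 0.001)
        inst = 1.0 + 0.2 * t  # 1 -> 3 Hz
        ph = PhaseSeries(wrap_angle(2 * np.pi * (t + 0.1 * t**2)), 1000.0)
        mean_freq, mod = phase_slope(ph)
        assert mean_freq == pytest.approx(2.0, abs=0.02)
        assert mod > 0.1

    def test_unwrap_across_jump(self):
        ph = phase_of(1.5)
        m1, s1 = phase_slope(ph)
        # same phases rotated so wraps occur elsewhere
        ph2 = PhaseSeries(wrap_angle(ph.wrapped + 1.0), ph.rate)
        m2, s2 = phase_slope(ph2)
        assert m1 == pytest.approx(m2, abs=1e-9)
        assert s1 == pytest.approx(s2, abs=1e-6)


class TestAmplitudeModulation:
    def test_single_channel_zero_sd(self):
        a = np.abs(np.random.default_rng(0).standard_normal(1000)) + 0.1
        summary = amplitude_modulation(a[None, :])
        assert summary.amp_mod[0] == pytest.approx(0.0, abs=1e-12)

    def test_two_identical_channels(self):
        a = np.abs(np.random.default_rng(0).standard_normal(1000)) + 0.1
        summary = amplitude_modulation(np.vstack([a, a]))
        np.testing.assert_allclose(summary.amp_mod, 0.0, atol=1e-12)

    def test_shares_sum_to_one(self, rng):
        A = np.abs(rng.standard_normal((4, 500))) + 0.05
        sq = A**2
        shares = sq / sq.sum(axis=0)
        np.testing.assert_allclose(shares.sum(axis=0), 1.0, atol=1e-12)
        s = amplitude_modulation(A)
        assert s.amp_mod_mean > 0

    def test_modulated_channel_larger_sd(self):
        t = np.arange(5000) / 1000.0
        const = np.ones_like(t)
        mod = 1.0 + 0.5 * np.sin(2 * np.pi * 0.5 * t)
        s = amplitude_modulation(np.vstack([const, const, mod]))
        assert s.amp_mod[2] > s.amp_mod[0]
        assert s.amp_mod[2] > s.amp_mod[1]


class TestPhaseDifference:
    def test_identical_zero(self):
        p = phase_of(1.5)
        d = phase_difference(p, p)
        assert np.abs(d.angles).max() < 1e-12

    def test_delay_closed_form(self):
        f, dt = 2.0, 0.05
        p1 = phase_of(f)
        p2 = phase_of(f, phi0=-2 * np.pi * f * dt)
        d = phase_difference(p1, p2)
        assert np.allclose(wrap_angle(d.angles), wrap_angle(-2 * np.pi * f * dt))

    def test_antisymmetry(self, rng):
        p1 = PhaseSeries(wrap_angle(rng.uniform(-np.pi, np.pi, 100)), 1.0)
        p2 = PhaseSeries(wrap_angle(rng.uniform(-np.pi, np.pi, 100)), 1.0)
        d12 = phase_difference(p1, p2).angles
        d21 = phase_difference(p2, p1).angles
        np.testing.assert_allclose(wrap_angle(d12 + d21), 0.0, atol=1e-10)

    def test_white_noise_pair_flat(self):
        # null reference: delta phase difference between two white-noise
        # signals is uniform on the circle
        from striatal_gamma.signal_core import BANDS, TimeSeries, analytic_signal, zero_phase_filter

        ps = []
        for seed in range(10):
            phases = []
            for off in (0, 1000):
                rng = np.random.default_rng(seed + off)
                b = TimeSeries(rng.standard_normal(120_000), 1000.0)
                d = zero_phase_filter(b, BANDS["delta"])
                phases.append(PhaseSeries.from_analytic(analytic_signal(d).phase, b.rate))
            diff = phase_difference(*phases).angles[::1000]
            ps.append(rayleigh_test(CircularDistribution(diff)))
        assert np.mean(np.array(ps) > 0.05) >= 0.7


class TestPhasesAtEvents:
    def _events(self, times, half=0.004):
        return GammaEventSet(
            tuple(GammaEvent(t, 3.0, t - half, t + half) for t in times),
            threshold=2.5,
        )

    def test_peak_convention(self):
        # events at delta maxima of cos -> angle 0
        ph = phase_of(1.5)
        times = np.arange(1, 9) / 1.5  # cosine peaks
        d = phases_at_events(ph, self._events(times), enforce_min=False)
        assert np.abs(d.angles).max() < 0.02

    def test_upsweep_convention(self):
        # upward zero-crossings of cos sit at -pi/2
        ph = phase_of(1.5)
        times = (np.arange(1, 9) - 0.25) / 1.5
        d = phases_at_events(ph, self._events(times), enforce_min=False)
        assert np.allclose(d.angles, -np.pi / 2, atol=0.02)

    def test_dismissal_below_50(self):
        ph = phase_of(1.5, duration=100.0)
        with pytest.raises(ChannelDismissedError):
            phases_at_events(ph, self._events(np.arange(1, 30)))

    def test_von_mises_round_trip(self):
        # place events where the wrapped phase equals a von Mises draw; the
        # recovered circular mean must sit at the injected preferred phase
        rng = np.random.default_rng(3)
        ph = phase_of(1.5, duration=400.0)
        target = rng.vonmises(np.pi / 4, 4.0, 200)
        cycles = rng.choice(np.arange(2, 580), 200, replace=False)
        times = np.sort((cycles + target / (2 * np.pi)) / 1.5)
        d = phases_at_events(ph, self._events(times), enforce_min=False)
        _, mean_angle = resultant_vector(d.angles)
        assert abs(wrap_angle(mean_angle - np.pi / 4)) < 0.15


class TestPhaseLockVector:
    def test_all_equal_r1(self):
        plv = phase_lock_vector(CircularDistribution(np.full(50, 0.7)), with_tests=False)
        assert plv.r == pytest.approx(1.0)
        assert plv.angle == pytest.approx(0.7)

    def test_uniform_grid_r0(self):
        a = np.linspace(-np.pi, np.pi, 360, endpoint=False)
        plv = phase_lock_vector(CircularDistribution(a), with_tests=False)
        assert plv.r < 1e-10

    def test_von_mises_bessel_ratio(self):
        from scipy.special import iv

        rng = np.random.default_rng(0)
        d = CircularDistribution(rng.vonmises(0.0, 2.0, 10_000))
        plv = phase_lock_vector(d, with_tests=False)
        assert plv.r == pytest.approx(iv(1, 2) / iv(0, 2), abs=0.02)

    def test_rotation_invariance(self, rng):
        a = rng.vonmises(0.3, 2.0, 500)
        r1, ang1 = resultant_vector(a)
        r2, ang2 = resultant_vector(wrap_angle(a + 1.1))
        assert r1 == pytest.approx(r2, abs=1e-12)
        assert wrap_angle(ang2 - ang1) == pytest.approx(1.1, abs=1e-9)

    def test_r_increases_with_kappa(self):
        """Parameter recovery: estimated r strictly increasing in kappa."""
        wins = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            rs = [
                resultant_vector(rng.vonmises(0.0, k, 500))[0]
                for k in (0.5, 1.0, 2.0, 4.0)
            ]
            wins += all(a < b for a, b in zip(rs, rs[1:]))
        assert wins >= 6  # majority over seeds


class TestRayleigh:
    def test_type_one_error_calibration(self):
        rng = np.random.default_rng(0)
        rejections = 0
        n_sims = 2000
        for _ in range(n_sims):
            p = rayleigh_test(CircularDistribution(rng.uniform(-np.pi, np.pi, 100)))
            rejections += p < 0.05
        rate = rejections / n_sims
        assert abs(rate - 0.05) < 0.015

    def test_concentrated_tiny_p(self):
        p = rayleigh_test(CircularDistribution(np.full(50, 1.0)))
        assert p < 1e-6

    def test_matches_asymptotic_for_moderate_r(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            a = rng.vonmises(0, 0.4, 500)
            d = CircularDistribution(a)
            r, _ = resultant_vector(a)
            if r > 0.3:
                continue
            p = rayleigh_test(d)
            asym = np.exp(-500 * r**2)
            assert p / 2 <= max(asym, 1e-300) * 2 and asym / 2 <= p * 2

    def test_cross_check_against_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(2)
        a = rng.vonmises(0.5, 1.0, 80)
        _, p_ref = pingouin.circ_rayleigh(a)
        p = rayleigh_test(CircularDistribution(a))
        assert p == pytest.approx(p_ref, rel=1e-6)

    def test_small_n_error(self):
        with pytest.raises(ValueError):
            rayleigh_test(CircularDistribution(np.array([0.0, 1.0])))


class TestDip:
    def test_exact_small_cases(self):
        assert dip_statistic(np.array([0.0, 1.0])) == pytest.approx(0.25)
        grid = np.arange(1, 11) / 10.0
        assert dip_statistic(grid) == pytest.approx(0.05, abs=1e-12)

    def test_matches_lp_oracle(self):
        rng = np.random.default_rng(5)
        for trial in range(12):
            n = int(rng.integers(5, 30))
            if trial % 3 == 0:
                s = rng.uniform(size=n)
            elif trial % 3 == 1:
                s = rng.normal(size=n)
            else:
                s = np.concatenate(
                    [rng.normal(-3, 0.3, n // 2), rng.normal(3, 0.3, n - n // 2)]
                )
            assert dip_statistic(s) == pytest.approx(dip_lp(s), abs=1e-8)

    def test_affine_invariance(self, rng):
        x = rng.normal(size=100)
        assert dip_statistic(x) == pytest.approx(dip_statistic(5.0 * x - 3.0), abs=1e-12)

    def test_unimodal_von_mises_high_p(self):
        rng = np.random.default_rng(0)
        d = CircularDistribution(rng.vonmises(0.0, 4.0, 500))
        dip, p = dip_test(d)
        assert p > 0.5

    def test_bimodal_low_p_dip_point_one(self):
        rng = np.random.default_rng(0)
        d = CircularDistribution(
            np.concatenate([rng.vonmises(0, 8, 250), rng.vonmises(np.pi, 8, 250)])
        )
        dip, p = dip_test(d)
        assert p < 0.05
        assert dip == pytest.approx(0.1, abs=0.05)

    def test_uniform_not_extreme(self):
        rng = np.random.default_rng(4)
        d = CircularDistribution(rng.uniform(-np.pi, np.pi, 500))
        dip, p = dip_test(d)
        assert 0.01 < p

    def test_small_n_error(self):
        with pytest.raises(ValueError):
            dip_test(CircularDistribution(np.arange(5) / 5))
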