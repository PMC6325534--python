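import numpy as np
import pytest

from striatal_gamma.signal_core import BandSpec, DegenerateInputError, TimeSeries
from striatal_gamma.gamma_events import (
    GammaEvent,
    GammaEventSet,
    band_exclusion,
    binarize,
    circular_shuffle,
    detect_events,
    event_correlation,
    event_peak_fraction,
    gamma_envelope,
    inter_event_intervals,
    interval_ks_vs_exponential,
)


def burst_signal(rate=1000.0, duration=30.0, burst_times=(5.0, 12.0, 21.0),
                 freq=40.0, burst_dur=0.2, noise=0.05, seed=0):
    rng = np.random.default_rng(seed)
    n = int(duration * rate)
    x = noise * rng.standard_normal(n)
    m = int(burst_dur * rate)
    win = np.hanning(m)
    t = np.arange(m) / rate
    for bt in burst_times:
        s = int(bt * rate)
        x[s : s + m] += win * np.sin(2 * np.pi * freq * t)
    return TimeSeries(x, rate)


class TestGammaEnvelope:
    def test_stationary_carrier_flat(self):
        t = np.arange(0, 30, 0.001)
        env = gamma_envelope(TimeSeries(np.sin(2 * np.pi * 40 * t), 1000.0))
        inner = slice(2000, -2000)
        assert np.abs(env.samples[inner]).max() < 1.0  # no >1 SD excursions

    def test_burst_peak_inside_window(self):
        ts = burst_signal(burst_times=(10.0,))
        env = gamma_envelope(ts)
        peak_t = np.argmax(env.samples) / 1000.0
        assert 9.95 <= peak_t <= 10.25

    def test_out_of_band_silent(self):
        t = np.arange(0, 30, 0.001)
        # 5 Hz sine: envelope after z-scoring has no structure in-band
        env = gamma_envelope(TimeSeries(np.sin(2 * np.pi * 5 * t) + 1e-6 * np.sin(2 * np.pi * 40 * t), 1000.0))
        assert env.samples.std() == pytest.approx(1.0, abs=1e-6)  # z-scored

    def test_silent_channel(self):
        with pytest.raises(DegenerateInputError):
            gamma_envelope(TimeSeries(np.zeros(2000), 1000.0))


class TestDetectEvents:
    def test_subthreshold_empty(self):
        env = TimeSeries(np.zeros(5000), 1000.0)
        assert len(detect_events(env, 2.5)) == 0

    def test_single_epoch_argmax(self):
        z = np.zeros(5000)
        z[1000:1100] = 3.0
        z[1050] = 5.0
        evs = detect_events(TimeSeries(z, 1000.0), 2.5)
        assert len(evs) == 1
        assert evs.events[0].t_peak == pytest.approx(1.050, abs=1e-9)
        assert evs.events[0].z_peak == 5.0
        assert evs.events[0].epoch_start == pytest.approx(1.000)
        assert evs.events[0].epoch_end == pytest.approx(1.099)

    def test_amplitude_invariance(self, white_noise_ts):
        env1 = gamma_envelope(white_noise_ts)
        scaled = white_noise_ts.with_samples(white_noise_ts.samples * 57.3)
        env2 = gamma_envelope(scaled)
        e1 = detect_events(env1, 2.5)
        e2 = detect_events(env2, 2.5)
        np.testing.assert_allclose(e1.peak_times, e2.peak_times)

    def test_epoch_restriction_drops_straddlers(self):
        z = np.zeros(5000)
        z[900:1100] = 3.0  # straddles the 1.0 s boundary
        z[2000:2100] = 3.0  # inside
        epochs = np.array([[1.0, 4.0]])
        evs = detect_events(TimeSeries(z, 1000.0), 2.5, epochs=epochs)
        assert len(evs) == 1
        assert evs.events[0].t_peak >= 2.0

    def test_event_set_invariants(self):
        with pytest.raises(ValueError):
            GammaEventSet((GammaEvent(1.0, 2.0, 0.9, 1.1),), threshold=2.5)


class TestBandExclusion:
    def test_clean_burst_retained_click_removed(self):
        ts = burst_signal(burst_times=(10.0,), noise=0.05)
        # broadband click at t=20 s: power in every band
        x = ts.samples.copy()
        x[20_000:20_050] += 10.0 * np.hanning(50)
        ts2 = ts.with_samples(x)
        env = gamma_envelope(ts2)
        evs = detect_events(env, 2.5)
        kept = band_exclusion(evs, ts2)
        times_before = set(np.round(evs.peak_times, 1))
        times_after = set(np.round(kept.peak_times, 1))
        assert any(9.9 <= t <= 10.3 for t in times_after)  # smooth burst kept
        assert not any(19.9 <= t <= 20.2 for t in times_after)  # click dropped
        assert times_after <= times_before  # subset
        # idempotent
        again = band_exclusion(kept, ts2)
        assert len(again) == len(kept)

    def test_empty_set(self):
        ts = burst_signal()
        empty = GammaEventSet((), channel_id="a")
        assert len(band_exclusion(empty, ts, channel_id="a")) == 0

    def test_channel_mismatch(self):
        ts = burst_signal()
        evs = GammaEventSet((), channel_id="a")
        with pytest.raises(ValueError):
            band_exclusion(evs, ts, channel_id="b")


class TestBinarizeAndCorrelation:
    def test_binarize_runs(self):
        z = np.zeros(5000)
        for s in (100, 2000, 4000):
            z[s : s + 50] = 3.0
        b = binarize(TimeSeries(z, 1000.0), 2.5)
        runs = np.diff(np.concatenate(([0], b.values, [0])))
        assert (runs == 1).sum() == 3

    def test_binarize_all_zero(self):
        b = binarize(TimeSeries(np.zeros(100) - 1.0, 1000.0), 2.5)
        assert b.values.sum() == 0

    def test_identical_series_r1(self):
        z = np.zeros(5000)
        z[100:200] = 3.0
        b = binarize(TimeSeries(z, 1000.0), 2.5)
        assert event_correlation(b, b) == pytest.approx(1.0)

    def test_independent_series_near_zero(self):
        rs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            e1 = gamma_envelope(TimeSeries(rng.standard_normal(60_000), 1000.0))
            e2 = gamma_envelope(TimeSeries(rng.standard_normal(60_000), 1000.0))
            rs.append(event_correlation(binarize(e1, 2.5), binarize(e2, 2.5)))
        assert np.max(np.abs(rs)) < 0.05

    def test_circular_shuffle_destroys_correlation(self, white_noise_ts):
        env = gamma_envelope(white_noise_ts)
        b = binarize(env, 2.5)
        rng = np.random.default_rng(7)
        sh = circular_shuffle(b, rng)
        assert sh.values.sum() == b.values.sum()  # run structure preserved
        assert abs(event_correlation(b, sh)) < 0.05

    def test_zero_variance_flag(self):
        b = binarize(TimeSeries(np.zeros(100), 1000.0), 2.5)
        assert np.isnan(event_correlation(b, b))


class TestInterEventIntervals:
    def test_two_events(self):
        evs = GammaEventSet(
            (GammaEvent(1.0, 3.0, 0.9, 1.1), GammaEvent(3.0, 3.0, 2.9, 3.1)),
            threshold=2.5,
        )
        intervals, _, rate = inter_event_intervals(evs)
        np.testing.assert_allclose(intervals, [2.0])
        assert rate == pytest.approx(0.5)

    def test_insufficient(self):
        with pytest.raises(ValueError):
            inter_event_intervals(GammaEventSet((), threshold=2.5))

    def test_poisson_intervals_exponential(self):
        pvals = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            times = np.cumsum(np.clip(rng.exponential(1 / 0.5, 200), 0.02, None))
            events = tuple(
                GammaEvent(t, 3.0, t - 0.005, t + 0.005) for t in times
            )
            evs = GammaEventSet(events, threshold=2.5)
            intervals, _, _ = inter_event_intervals(evs)
            pvals.append(interval_ks_vs_exponential(intervals))
        assert np.median(pvals) > 0.01


def test_event_peak_fraction_on_noise():
    """On band-limited Gaussian noise, event peaks make up about 0.6% of the
    recording's detected peaks at the 2.5-SD threshold."""
    fracs = [
        event_peak_fraction(TimeSeries(np.random.default_rng(s).standard_normal(300_000), 1000.0))
        for s in range(3)
    ]
    assert 0.3 < np.mean(fracs) < 0.9
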