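"""Surrogate LFP generator with the statistical structure the analysis
assumes: a slow delta carrier with amplitude/phase modulation, transient
low-gamma bursts whose timing is von Mises phase-locked to the delta phase,
and 1/f-like background noise. Ground truth (burst times and true delta
phases) is returned so every analysis stage can be validated round-trip
without any recording.

Phase convention matches the analysis: 0 is the delta peak, -pi/2 the
upsweep. Bursts are raised-cosine-windowed gamma tones, so their envelopes
are smooth and contain no broadband edges that would trip the cross-band
exclusion.
"""

from __future__ import annotations

from dataclasses import dataclass, replace, field

import numpy as np

from .signal_core import TimeSeries

__all__ = ["SyntheticSpec", "gen_brownian", "gen_pac_lfp", "gen_multichannel", "synthetic_delta_drive"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the surrogate recording.

    Defaults mimic a quiet-rest-scale recording: 600 s at 1000 samples/s,
    1.5 Hz delta, 40 Hz gamma bursts at ~0.5/s locked to the delta peak.
    """

    duration: float = 600.0
    rate: float = 1000.0
    delta_freq: float = 1.5
    delta_amp: float = 1.0
    amp_mod_depth: float = 0.3  # slow multiplicative amplitude modulation
    phase_jitter: float = 0.3  # rad/s random-walk SD of the carrier phase
    burst_rate: float = 0.5  # events/s (Poisson)
    kappa: float = 4.0  # von Mises concentration of burst phases
    preferred_phase: float = 0.0  # rad; 0 = delta peak
    gamma_freq: float = 40.0
    burst_duration: float = 0.15  # s
    burst_amp: float = 1.0
    noise_kind: str = "brownian"
    noise_amp: float = 0.5
    n_channels: int = 2
    channel_lag: float = 0.0  # s, per-channel delta lag
    shared_burst_prob: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.kappa < 0 or self.burst_rate < 0 or self.noise_amp < 0:
            raise ValueError("rates, amplitudes and kappa must be >= 0")
        if self.noise_kind not in ("white", "brownian"):
            raise ValueError(f"unknown noise kind {self.noise_kind!r}")
        if not 0 <= self.shared_burst_prob <= 1:
            raise ValueError("shared_burst_prob must be in [0, 1]")


def _noise(spec: SyntheticSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    w = rng.standard_normal(n)
    if spec.noise_kind == "white":
        return spec.noise_amp * w
    b = np.cumsum(w)
    b -= b.mean()
    # normalize Brownian path to unit SD so noise_amp sets the scale
    sd = b.std()
    return spec.noise_amp * (b / sd if sd > 0 else b)


def gen_brownian(spec: SyntheticSpec) -> TimeSeries:
    """Brownian-motion (1/f^2) null signal: cumulative sum of zero-mean white
    noise, re-centered. Deterministic given the seed."""
    n = int(round(spec.duration * spec.rate))
    if n < 2:
        raise ValueError("need at least 2 samples")
    rng = np.random.default_rng(spec.seed)
    b = np.cumsum(rng.standard_normal(n))
    return TimeSeries(b - b.mean(), spec.rate)


def _delta_carrier(spec: SyntheticSpec, n: int, rng: np.random.Generator, lag: float = 0.0):
    """Delta oscillation with slow amplitude and phase modulation.

    Returns (signal, instantaneous phase) where phase 0 is the carrier peak
    (cosine convention).
    """
    dt = 1.0 / spec.rate
    jitter = rng.standard_normal(n) * spec.phase_jitter * np.sqrt(dt)
    phase = (
        2 * np.pi * spec.delta_freq * (np.arange(n) * dt - lag)
        + np.cumsum(jitter)
    )
    # slow amplitude modulation around 1 with depth amp_mod_depth
    mod_f = 0.05  # Hz, much slower than delta
    am = 1.0 + spec.amp_mod_depth * np.sin(
        2 * np.pi * mod_f * np.arange(n) * dt + rng.uniform(0, 2 * np.pi)
    )
    sig = spec.delta_amp * am * np.cos(phase)
    wrapped = np.mod(phase + np.pi, 2 * np.pi) - np.pi
    return sig, wrapped


def _burst_times_phases(
    spec: SyntheticSpec, phase: np.ndarray, rng: np.random.Generator
):
    """Poisson burst count; each burst center placed at the nearest time the
    delta phase crosses a von Mises draw around the preferred phase."""
    n = phase.size
    dt = 1.0 / spec.rate
    n_bursts = rng.poisson(spec.burst_rate * spec.duration)
    # nominal (uniform) times, then snapped to the drawn phase within a cycle
    t_nominal = np.sort(rng.uniform(0, spec.duration, n_bursts))
    if spec.kappa > 0:
        target = rng.vonmises(spec.preferred_phase, spec.kappa, n_bursts)
    else:
        target = rng.uniform(-np.pi, np.pi, n_bursts)
    half_cycle = int(round(spec.rate / spec.delta_freq / 2))
    centers, phases = [], []
    for t, th in zip(t_nominal, target):
        i = int(round(t / dt))
        lo, hi = max(0, i - half_cycle), min(n, i + half_cycle)
        if hi - lo < 2:
            continue
        seg = phase[lo:hi]
        j = int(np.argmin(np.abs(np.mod(seg - th + np.pi, 2 * np.pi) - np.pi)))
        centers.append((lo + j) * dt)
        phases.append(phase[lo + j])
    return np.array(centers), np.array(phases)


def _add_bursts(sig: np.ndarray, centers: np.ndarray, spec: SyntheticSpec, rate: float):
    n = sig.size
    dur = int(round(spec.burst_duration * rate))
    t = np.arange(dur) / rate
    window = 0.5 * (1 - np.cos(2 * np.pi * np.arange(dur) / max(dur - 1, 1)))
    tone = spec.burst_amp * window * np.sin(2 * np.pi * spec.gamma_freq * t)
    for c in centers:
        s = int(round(c * rate)) - dur // 2
        e = s + dur
        if s < 0 or e > n:
            continue
        sig[s:e] += tone
    return sig


def gen_pac_lfp(spec: SyntheticSpec) -> tuple[TimeSeries, dict]:
    """Single-channel surrogate LFP with delta-phase-locked gamma bursts.

    Returns the signal and a ground-truth dict with burst center times, the
    true delta phase at each burst center, and the true per-sample delta
    phase.
    """
    if not (25 <= spec.gamma_freq <= 55):
        raise ValueError("gamma_freq must lie in the 25-55 Hz band")
    if spec.burst_duration < 3.0 / spec.gamma_freq:
        raise ValueError("bursts must span at least 3 gamma cycles")
    if spec.burst_rate * spec.burst_duration > 0.5:
        import warnings

        warnings.warn("burst rate high enough that bursts overlap > 50% of time")
    n = int(round(spec.duration * spec.rate))
    rng = np.random.default_rng(spec.seed)
    delta, phase = _delta_carrier(spec, n, rng)
    centers, center_phases = _burst_times_phases(spec, phase, rng)
    sig = delta + _noise(spec, n, rng)
    sig = _add_bursts(sig, centers, spec, spec.rate)
    truth = dict(
        burst_times=centers, burst_phases=center_phases, delta_phase=phase
    )
    return TimeSeries(sig, spec.rate), truth


def gen_multichannel(spec: SyntheticSpec) -> tuple[list[TimeSeries], dict]:
    """Multichannel surrogate: shared delta carrier with per-channel lag,
    bursts shared across channels with probability ``shared_burst_prob``.

    Channel c's delta lags channel 0 by ``c * channel_lag`` seconds.
    """
    if spec.n_channels < 2:
        raise ValueError("need at least 2 channels")
    n = int(round(spec.duration * spec.rate))
    rng = np.random.default_rng(spec.seed)
    # one shared modulated carrier phase; per-channel lag applied to it
    base_rng = np.random.default_rng(spec.seed + 1)
    _, phase0 = _delta_carrier(spec, n, base_rng)
    shift0 = int(round(spec.channel_lag * spec.rate))
    centers0, phases0 = _burst_times_phases(spec, phase0, rng)

    channels, truths = [], []
    for c in range(spec.n_channels):
        lag_samples = c * shift0
        phase_c = np.roll(phase0, lag_samples)
        am_rng = np.random.default_rng(spec.seed + 10 + c)
        delta_c = spec.delta_amp * np.cos(phase_c)
        shared = rng.random(centers0.size) < spec.shared_burst_prob
        own_centers = centers0[shared]
        extra_spec = replace(
            spec, seed=spec.seed + 100 + c, duration=spec.duration
        )
        extra_rng = np.random.default_rng(extra_spec.seed)
        n_extra = int(round((1 - spec.shared_burst_prob) * centers0.size))
        if n_extra > 0:
            extra_centers, extra_phases = _burst_times_phases(
                replace(spec, burst_rate=n_extra / spec.duration),
                phase_c,
                extra_rng,
            )
        else:
            extra_centers = np.empty(0)
        all_centers = np.sort(np.concatenate([own_centers, extra_centers]))
        sig = delta_c + _noise(spec, n, am_rng)
        sig = _add_bursts(sig, all_centers, spec, spec.rate)
        channels.append(TimeSeries(sig, spec.rate))
        idx = np.clip((all_centers * spec.rate).round().astype(int), 0, n - 1)
        truths.append(
            dict(
                burst_times=all_centers,
                burst_phases=phase_c[idx],
                delta_phase=phase_c,
            )
        )
    return channels, dict(channels=truths, shared_times=centers0)


def synthetic_delta_drive(
    duration: float, seed: int = 0, rate: float = 1000.0, delta_freq: float = 1.5
) -> TimeSeries:
    """Standard surrogate cortical LFP used to drive the FSI network model:
    a 1.5 Hz delta oscillation with mild amplitude modulation and Brownian
    background, without gamma bursts (the model must generate its own)."""
    spec = SyntheticSpec(
        duration=duration,
        rate=rate,
        delta_freq=delta_freq,
        amp_mod_depth=0.15,
        noise_amp=0.2,
        burst_amp=0.0,
        burst_rate=0.0,
        seed=seed,
    )
    ts, _ = gen_pac_lfp(spec)
    return ts
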