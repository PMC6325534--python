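"""Multitaper power spectra, Morlet spectrograms, and event-epoch complex
coherence.

The PSD grid runs from 0.5 Hz to 100 Hz with an increment of ~0.503 Hz so no
grid point lands on the 60 Hz power line; spectra can be normalized either to
the mean power of the 15-20 Hz beta band (not modulated at rest, so it removes
channel gain bias) or by 1/f^2 (multiplying by f^2) to flatten Brownian-like
backgrounds and emphasize the low-gamma peak.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps
from scipy.signal.windows import dpss

from .signal_core import TimeSeries
from .gamma_events import GammaEventSet

__all__ = [
    "PowerSpectrum",
    "Spectrogram",
    "ComplexCoherence",
    "multitaper_psd",
    "normalize_spectrum",
    "morlet_spectrogram",
    "complex_coherence",
    "spectral_peak",
]

#: Frequency increment "close to but not equal to 0.5" so that k*df never
#: equals 60.000 Hz on the 0.5-100 Hz grid.
FREQ_STEP = 0.503

BETA_NORM_BAND = (15.0, 20.0)
LOW_GAMMA_BAND = (25.0, 55.0)


@dataclass(frozen=True)
class PowerSpectrum:
    freqs: np.ndarray
    power: np.ndarray
    normalization: str = "raw"

    def __post_init__(self):
        if np.any(self.power < 0):
            raise ValueError("power must be non-negative")
        if np.any(np.isclose(self.freqs, 60.0, atol=1e-9)):
            raise ValueError("60 Hz must not be on the frequency grid")

    def band_mean(self, low: float, high: float) -> float:
        m = (self.freqs >= low) & (self.freqs <= high)
        return float(self.power[m].mean())


@dataclass(frozen=True)
class Spectrogram:
    freqs: np.ndarray
    times: np.ndarray
    coefficients: np.ndarray  # freqs x times, real part of the wavelet output

    def normalized(self) -> np.ndarray:
        """Coefficient magnitudes normalized to sum to 1 (display form)."""
        mag = np.abs(self.coefficients)
        return mag / mag.sum()


@dataclass(frozen=True)
class ComplexCoherence:
    freqs: np.ndarray
    value: np.ndarray  # complex per frequency

    @property
    def r(self) -> np.ndarray:
        return np.abs(self.value)

    @property
    def phi(self) -> np.ndarray:
        return np.angle(self.value)


def _mt_segment_psd(segs: np.ndarray, rate: float, nw: float, n_tapers: int):
    """Average multitaper periodogram over segments (segments x samples)."""
    n = segs.shape[1]
    tapers = dpss(n, nw, n_tapers)  # tapers x samples
    # each taper normalized so the PSD is unbiased for white noise
    psd = None
    for t in tapers:
        spec = np.fft.rfft(segs * t, axis=1)
        p = (np.abs(spec) ** 2) / (rate * np.sum(t**2))
        p[:, 1:-1] *= 2  # one-sided
        psd = p if psd is None else psd + p
    psd /= n_tapers
    return np.fft.rfftfreq(n, 1 / rate), psd.mean(axis=0)


def multitaper_psd(
    ts: TimeSeries,
    nw: float = 4.0,
    n_tapers: int = 7,
    f_lo: float = 0.5,
    f_hi: float = 100.0,
) -> PowerSpectrum:
    """Thomson multitaper PSD on the 60-Hz-skipping grid.

    The signal is cut into segments whose length sets the frequency increment
    to ~0.503 Hz; DPSS-tapered periodograms are averaged over tapers and
    segments. Requires at least 2 s of signal.
    """
    if ts.duration < 2.0:
        raise ValueError("need at least 2 s of signal for a PSD")
    nper = int(round(ts.rate / FREQ_STEP))
    x = ts.samples - ts.samples.mean()
    if x.size < nper:
        nper = x.size
    n_segs = x.size // nper
    segs = x[: n_segs * nper].reshape(n_segs, nper)
    segs = segs - segs.mean(axis=1, keepdims=True)
    freqs, psd = _mt_segment_psd(segs, ts.rate, nw, n_tapers)
    m = (freqs >= f_lo) & (freqs <= f_hi) & ~np.isclose(freqs, 60.0, atol=1e-9)
    return PowerSpectrum(freqs[m], psd[m], "raw")


def normalize_spectrum(ps: PowerSpectrum, mode: str) -> PowerSpectrum:
    """Apply the beta-band or 1/f^2 normalization to a raw spectrum."""
    if ps.normalization != "raw":
        raise ValueError(f"spectrum already normalized ({ps.normalization})")
    if mode == "beta_band":
        ref = ps.band_mean(*BETA_NORM_BAND)
        if ref <= 0:
            raise ValueError("zero beta-band power; cannot normalize")
        return replace(ps, power=ps.power / ref, normalization="beta_band")
    if mode == "one_over_f2":
        return replace(ps, power=ps.power * ps.freqs**2, normalization="one_over_f2")
    raise ValueError(f"unknown normalization mode {mode!r}")


def spectral_peak(
    ps: PowerSpectrum,
    f_min: float = 15.0,
    smooth_hz: float = 0.0,
    min_prominence_rel: float = 0.0,
) -> float | None:
    """Frequency of the largest local spectral maximum above ``f_min``.

    Returns None when no local maximum exists above ``f_min`` (monotone
    spectrum = no peak). ``smooth_hz`` applies a moving-average of that
    bandwidth first, stabilizing broad-bump peak location against estimator
    noise; ``min_prominence_rel`` optionally requires the peak to be
    prominent relative to the maximum power above f_min.
    """
    m = ps.freqs >= f_min
    f, p = ps.freqs[m], ps.power[m]
    if len(p) < 3:
        return None
    if smooth_hz > 0:
        k = max(1, int(round(smooth_hz / (f[1] - f[0]))))
        p = np.convolve(p, np.ones(k) / k, "same")
    peaks, props = sps.find_peaks(p, prominence=min_prominence_rel * p.max())
    if len(peaks) == 0:
        return None
    best = peaks[np.argmax(p[peaks])]
    return float(f[best])


def _morlet_kernel(f0: float, rate: float, q: float = 5.0):
    """Complex Morlet wavelet at center frequency f0 with q cycles of spectral
    width; temporal support is 4 sigma_t (2 sigma_t each side)."""
    sigma_f = f0 / q
    sigma_t = 1.0 / (2 * np.pi * sigma_f)
    half = int(np.ceil(2 * sigma_t * rate))
    t = np.arange(-half, half + 1) / rate
    A = 1.0 / (np.sqrt(2 * np.pi) * sigma_t * rate)
    return A * np.exp(2j * np.pi * f0 * t) * np.exp(-(t**2) / (2 * sigma_t**2))


def morlet_spectrogram(
    ts: TimeSeries,
    f_lo: float = 0.5,
    f_hi: float = 100.0,
    f_step: float = 0.5,
    q: float = 5.0,
) -> Spectrogram:
    """Time-frequency map from convolution with complex Morlet wavelets,
    keeping the real part of the coefficients.

    Center frequencies span ``f_lo``..``f_hi`` in steps of ``f_step``; each
    wavelet has spectral SD f0/q and temporal SD 1/(2*pi*sigma_f), truncated
    at a total width of 4 sigma_t.
    """
    freqs = np.arange(f_lo, f_hi + f_step / 2, f_step)
    widest = int(np.ceil(2 * (q / (2 * np.pi * f_lo)) * ts.rate)) * 2 + 1
    if len(ts) < widest:
        raise ValueError(
            f"series of {len(ts)} samples shorter than the widest wavelet ({widest})"
        )
    x = ts.samples - ts.samples.mean()
    coeffs = np.empty((freqs.size, x.size))
    for i, f0 in enumerate(freqs):
        w = _morlet_kernel(f0, ts.rate, q)
        coeffs[i] = np.real(sps.fftconvolve(x, w, mode="same"))
    return Spectrogram(freqs, ts.times, coeffs)


def _event_epoch_slices(
    events: GammaEventSet, rate: float, t0: float, n: int, min_len_s: float = 0.256
):
    """Sample slices for event epochs, symmetrically padded to >= min_len_s
    using adjacent signal."""
    min_len = int(np.ceil(min_len_s * rate))
    slices = []
    for ev in events.events:
        s = int(round((ev.epoch_start - t0) * rate))
        e = int(round((ev.epoch_end - t0) * rate)) + 1
        if e - s < min_len:
            pad = (min_len - (e - s) + 1) // 2
            s, e = s - pad, e + pad
        s = max(0, s)
        e = min(n, e)
        if e - s >= min_len:
            slices.append((s, e))
    return slices


def complex_coherence(
    x1: TimeSeries,
    x2: TimeSeries,
    events: GammaEventSet | list,
    f_band: tuple[float, float] = LOW_GAMMA_BAND,
    min_epochs: int = 5,
) -> ComplexCoherence:
    """Complex coherence over gamma-event epochs, restricted to 25-55 Hz.

    Cross- and auto-spectra are averaged over the epochs during which a gamma
    event occurred in at least one channel; the coherence is the cross
    spectrum normalized by the square root of the product of auto-spectra. Its
    magnitude r is 1 for identical frequency content and its angle phi the
    mean phase shift; a nonzero imaginary part excludes zero-lag (volume
    conducted) coupling.
    """
    if x1.rate != x2.rate:
        raise ValueError("rates must match")
    ev_sets = events if isinstance(events, (list, tuple)) else [events]
    n = min(len(x1), len(x2))
    slices = []
    for evs in ev_sets:
        slices += _event_epoch_slices(evs, x1.rate, x1.t0, n)
    # merge duplicates/overlaps
    slices = sorted(set(slices))
    if len(slices) < min_epochs:
        raise ValueError(f"need >= {min_epochs} event epochs, got {len(slices)}")
    nfft = max(e - s for s, e in slices)
    sxx = syy = sxy = 0.0
    for s, e in slices:
        w = np.hanning(e - s)
        a = np.fft.rfft((x1.samples[s:e] - x1.samples[s:e].mean()) * w, nfft)
        b = np.fft.rfft((x2.samples[s:e] - x2.samples[s:e].mean()) * w, nfft)
        sxx = sxx + np.abs(a) ** 2
        syy = syy + np.abs(b) ** 2
        sxy = sxy + np.conj(a) * b  # phi < 0 when x2 lags x1
    freqs = np.fft.rfftfreq(nfft, 1 / x1.rate)
    with np.errstate(invalid="ignore", divide="ignore"):
        coh = sxy / np.sqrt(sxx * syy)
    m = (freqs >= f_band[0]) & (freqs <= f_band[1])
    return ComplexCoherence(freqs[m], coh[m])
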