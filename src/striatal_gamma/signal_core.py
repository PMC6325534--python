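"""Filtering and analytic-signal primitives shared by all analysis stages.

All signals travel as :class:`TimeSeries` (uniformly sampled real values with a
rate and a start time). Band-pass/low-pass filtering is zero-phase (Butterworth
applied forward and reverse), the instantaneous amplitude and phase come from
the Hilbert analytic signal, and z-scoring normalizes a series to zero mean and
unit SD.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

__all__ = [
    "TimeSeries",
    "BandSpec",
    "AnalyticSignal",
    "BANDS",
    "DegenerateInputError",
    "zero_phase_filter",
    "analytic_signal",
    "zscore",
]


class DegenerateInputError(ValueError):
    """Raised for inputs that make an operation meaningless (zero variance,
    silent channel, constant signal)."""


@dataclass(frozen=True)
class TimeSeries:
    """Uniformly sampled real-valued signal.

    Parameters
    ----------
    samples : ndarray
        Real samples (volts or normalized units).
    rate : float
        Sampling rate in samples/s; must be > 0.
    t0 : float
        Time of the first sample, in seconds.
    """

    samples: np.ndarray
    rate: float
    t0: float = 0.0

    def __post_init__(self):
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if self.rate <= 0:
            raise ValueError(f"rate must be > 0, got {self.rate}")
        if samples.ndim != 1 or samples.size < 1:
            raise ValueError("samples must be a non-empty 1-D array")
        if not np.all(np.isfinite(samples)):
            raise ValueError("samples must be finite")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        return self.samples.size / self.rate

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.rate

    def index_of(self, t: float) -> int:
        """Nearest sample index for time ``t`` (seconds)."""
        return int(round((t - self.t0) * self.rate))

    def with_samples(self, samples: np.ndarray) -> "TimeSeries":
        return TimeSeries(samples, self.rate, self.t0)


@dataclass(frozen=True)
class BandSpec:
    """Frequency band: ``low == 0`` means a low-pass with cutoff ``high``."""

    low: float
    high: float
    name: str = ""

    def __post_init__(self):
        if not (0 <= self.low < self.high):
            raise ValueError(f"need 0 <= low < high, got ({self.low}, {self.high})")


#: Named bands used throughout the analysis. High gamma's upper edge is capped
#: at 0.9 * Nyquist at filter time when it exceeds it.
BANDS = {
    "delta": BandSpec(0.0, 4.0, "delta"),
    "alpha": BandSpec(8.0, 12.0, "alpha"),
    "beta": BandSpec(13.0, 24.0, "beta"),
    "beta_norm": BandSpec(15.0, 20.0, "beta_norm"),
    "low_gamma": BandSpec(25.0, 55.0, "low_gamma"),
    "high_gamma": BandSpec(60.0, 100.0, "high_gamma"),
}


@dataclass(frozen=True)
class AnalyticSignal:
    """Per-sample instantaneous amplitude A(t) >= 0 and wrapped phase P(t) in
    [-pi, pi), from the Hilbert analytic signal."""

    amplitude: np.ndarray
    phase: np.ndarray
    rate: float
    degenerate: bool = False


def _design_sos(band: BandSpec, rate: float, order: int) -> np.ndarray:
    nyq = rate / 2.0
    if band.high >= nyq:
        raise ValueError(f"band {band} extends above Nyquist ({nyq} Hz)")
    if band.low == 0:
        return sps.butter(order, band.high, btype="lowpass", fs=rate, output="sos")
    return sps.butter(
        order, [band.low, band.high], btype="bandpass", fs=rate, output="sos"
    )


def zero_phase_filter(ts: TimeSeries, band: BandSpec, order: int = 4) -> TimeSeries:
    """Butterworth zero-phase (forward-reverse) filter.

    The filter is designed at ``order`` and applied forward and backward, so
    the net phase shift is zero at every frequency and the effective magnitude
    response is the squared design response.

    Raises
    ------
    ValueError
        If the band extends above Nyquist, or the series is shorter than the
        filter warm-up (3x the filter order in samples).
    """
    if len(ts) <= 3 * order:
        raise ValueError(
            f"series of {len(ts)} samples shorter than filter warm-up ({3 * order})"
        )
    sos = _design_sos(band, ts.rate, order)
    out = sps.sosfiltfilt(sos, ts.samples)
    return ts.with_samples(out)


def edge_guard_samples(band: BandSpec, rate: float, order: int = 4) -> int:
    """Number of samples at each end contaminated by filter edge transients:
    3 * order cycles of the low cutoff, capped at one second of samples."""
    low = band.low if band.low > 0 else band.high
    return int(min(3 * order * rate / low, rate))


def analytic_signal(ts: TimeSeries) -> AnalyticSignal:
    """Instantaneous amplitude and phase from the Hilbert analytic signal.

    The mean is subtracted defensively. Amplitude is the modulus of the
    analytic signal; phase is the four-quadrant angle in [-pi, pi), falling
    from pi to -pi once per cycle.
    """
    x = ts.samples - ts.samples.mean()
    if np.allclose(x, 0.0):
        n = len(ts)
        return AnalyticSignal(np.zeros(n), np.zeros(n), ts.rate, degenerate=True)
    z = sps.hilbert(x)
    phase = np.angle(z)
    # np.angle returns (-pi, pi]; map +pi to -pi so phase lies in [-pi, pi)
    phase[phase == np.pi] = -np.pi
    return AnalyticSignal(np.abs(z), phase, ts.rate)


def zscore(ts: TimeSeries) -> TimeSeries:
    """Normalize to zero mean and unit SD (population SD)."""
    sd = ts.samples.std()
    if sd == 0:
        raise DegenerateInputError("zero-variance input cannot be z-scored")
    return ts.with_samples((ts.samples - ts.samples.mean()) / sd)
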