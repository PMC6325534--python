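"""Phase/amplitude modulation measures and circular statistics for
delta-phase-at-gamma-event distributions.

Phase convention: angle 0 is the delta peak, -pi/2 the upsweep (rising flank)
and +pi/2 the downsweep. This follows directly from the analytic phase of a
cosine-like delta oscillation and makes model/experiment comparisons of
preferred phases meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._dip import dip_pvalue, dip_statistic
from .gamma_events import MIN_EVENTS_PER_CHANNEL, GammaEventSet

__all__ = [
    "PhaseSeries",
    "CircularDistribution",
    "PhaseLockVector",
    "ModulationSummary",
    "ChannelDismissedError",
    "phase_slope",
    "amplitude_modulation",
    "phase_difference",
    "phases_at_events",
    "phase_lock_vector",
    "rayleigh_test",
    "dip_test",
    "wrap_angle",
]


class ChannelDismissedError(ValueError):
    """A channel has too few gamma events for phase statistics."""


def wrap_angle(a: np.ndarray) -> np.ndarray:
    """Wrap angles to [-pi, pi)."""
    return np.mod(np.asarray(a) + np.pi, 2 * np.pi) - np.pi


@dataclass(frozen=True)
class PhaseSeries:
    """Wrapped per-sample phase in [-pi, pi) plus its unwrapped (continuous)
    counterpart."""

    wrapped: np.ndarray
    rate: float
    t0: float = 0.0

    @property
    def unwrapped(self) -> np.ndarray:
        return np.unwrap(self.wrapped)

    def __len__(self) -> int:
        return len(self.wrapped)

    @classmethod
    def from_analytic(cls, phase: np.ndarray, rate: float, t0: float = 0.0):
        return cls(wrap_angle(phase), rate, t0)


@dataclass(frozen=True)
class CircularDistribution:
    """Sample of angles on the circle, wrapped to [-pi, pi)."""

    angles: np.ndarray

    def __post_init__(self):
        a = wrap_angle(np.asarray(self.angles, dtype=float))
        if a.size < 1:
            raise ValueError("need at least one angle")
        object.__setattr__(self, "angles", a)

    @property
    def n(self) -> int:
        return self.angles.size


@dataclass(frozen=True)
class PhaseLockVector:
    """Mean resultant vector of a circular sample, with attached tests.

    ``r`` is the vector strength (1 = perfect locking, 0 = uniform), ``angle``
    the mean phase, ``rayleigh_p`` the non-uniformity test p-value, and
    ``dip``/``dip_p`` Hartigan's unimodality test on the rotated sample.
    """

    r: float
    angle: float
    n: int
    rayleigh_p: float = float("nan")
    dip: float = float("nan")
    dip_p: float = float("nan")

    def __post_init__(self):
        if not (0 <= self.r <= 1 + 1e-12):
            raise ValueError(f"resultant norm must be in [0,1], got {self.r}")


@dataclass(frozen=True)
class ModulationSummary:
    """Per-channel mean frequency / phase-modulation / amplitude-modulation
    summary, with channel averages."""

    mean_freq: np.ndarray
    phase_mod: np.ndarray
    amp_mod: np.ndarray
    amp_mod_mean: float
    degenerate: bool = False


def phase_slope(ps: PhaseSeries) -> tuple[float, float]:
    """Mean frequency (Hz) and phase modulation (SD of the instantaneous
    slope, rad/s) of an unwrapped phase ramp.

    The slope is the first difference of the unwrapped phase times the rate;
    its mean divided by 2*pi is the mean frequency (1 Hz = 2*pi rad/s), and
    its SD quantifies phase slips away from a pure ramp.
    """
    if len(ps) < 2:
        raise ValueError("need at least 2 samples")
    d = np.diff(ps.unwrapped) * ps.rate
    return float(d.mean() / (2 * np.pi)), float(d.std())


def amplitude_modulation(amps: np.ndarray) -> ModulationSummary:
    """Temporal amplitude modulation from per-channel analytic amplitudes.

    The squared amplitude of each channel is normalized at every sample by the
    sum of squared amplitudes over channels (so channel shares sum to 1); the
    SD over time of each channel's share measures its amplitude modulation,
    and the cross-channel average is the global summary. A single channel has
    share identically 1 and hence zero SD.
    """
    A = np.atleast_2d(np.asarray(amps, dtype=float))  # channels x time
    sq = A**2
    total = sq.sum(axis=0)
    degenerate = bool(np.any(total == 0))
    with np.errstate(invalid="ignore", divide="ignore"):
        share = np.where(total > 0, sq / total, np.nan)
    sd_t = np.nanstd(share, axis=1)
    # mean frequency / phase modulation are not derivable from amplitudes
    nan = np.full(A.shape[0], np.nan)
    return ModulationSummary(nan, nan, sd_t, float(sd_t.mean()), degenerate)


def phase_difference(p1: PhaseSeries, p2: PhaseSeries) -> CircularDistribution:
    """Per-sample wrapped phase difference p2 - p1."""
    if len(p1) != len(p2) or p1.rate != p2.rate:
        raise ValueError("phase series must share length and rate")
    return CircularDistribution(wrap_angle(p2.wrapped - p1.wrapped))


def phases_at_events(
    delta_phase: PhaseSeries, events: GammaEventSet, enforce_min: bool = True
) -> CircularDistribution:
    """Delta phase sampled at each gamma event's peak time.

    Channels with fewer than 50 events are dismissed (raises
    :class:`ChannelDismissedError`) unless ``enforce_min`` is False.
    """
    if enforce_min and len(events) < MIN_EVENTS_PER_CHANNEL:
        raise ChannelDismissedError(
            f"channel {events.channel_id!r} has {len(events)} events "
            f"(< {MIN_EVENTS_PER_CHANNEL}); dismissed from phase statistics"
        )
    if len(events) == 0:
        raise ValueError("no events to sample phases at")
    n = len(delta_phase)
    idx = np.round((events.peak_times - delta_phase.t0) * delta_phase.rate).astype(int)
    if idx.min() < 0 or idx.max() >= n:
        raise ValueError("event outside the phase series' time span")
    return CircularDistribution(delta_phase.wrapped[idx])


def resultant_vector(angles: np.ndarray) -> tuple[float, float]:
    """Norm and argument of the mean of unit phasors."""
    z = np.exp(1j * np.asarray(angles)).mean()
    return float(np.abs(z)), float(np.angle(z))


def rayleigh_test(dist: CircularDistribution) -> float:
    """Rayleigh test for non-uniformity of a circular sample.

    Uses the standard finite-n corrected formula
    ``p = exp(sqrt(1 + 4n + 4(n^2 - R^2)) - (1 + 2n))`` with R = n*r.
    """
    n = dist.n
    if n < 5:
        raise ValueError(f"Rayleigh test needs n >= 5, got {n}")
    r, _ = resultant_vector(dist.angles)
    R = n * r
    p = np.exp(np.sqrt(1 + 4 * n + 4 * (n**2 - R**2)) - (1 + 2 * n))
    return float(min(p, 1.0))


def dip_test(
    dist: CircularDistribution, n_boot: int = 500, seed: int | None = 0
) -> tuple[float, float]:
    """Hartigan's dip test for unimodality of a circular sample.

    The dip is defined for linear data; the circular sample is first rotated
    so its circular mean sits at 0 and the angles on [-pi, pi) are then
    treated as linear. p approaches 1 for unimodal samples and 0 (with dip
    around 0.1) for clearly multimodal ones.
    """
    if dist.n < 10:
        raise ValueError(f"dip test needs n >= 10, got {dist.n}")
    _, mean_angle = resultant_vector(dist.angles)
    rotated = wrap_angle(dist.angles - mean_angle)
    dip = dip_statistic(rotated)
    p = dip_pvalue(dip, dist.n, n_boot=n_boot, seed=seed)
    return float(dip), float(p)


def phase_lock_vector(
    dist: CircularDistribution,
    with_tests: bool = True,
    dip_boot: int = 500,
    seed: int | None = 0,
) -> PhaseLockVector:
    """Mean resultant vector with Rayleigh and dip tests attached."""
    r, angle = resultant_vector(dist.angles)
    ray_p = dip = dip_p = float("nan")
    if with_tests:
        if dist.n >= 5:
            ray_p = rayleigh_test(dist)
        if dist.n >= 10:
            dip, dip_p = dip_test(dist, n_boot=dip_boot, seed=seed)
    return PhaseLockVector(r, angle, dist.n, ray_p, dip, dip_p)
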