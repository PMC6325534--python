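"""End-to-end workflows.

``run_analysis`` takes a multichannel recording (real or model-reconstructed)
through the full analysis: delta phase extraction, gamma-event detection with
cross-band exclusion, delta-phase-at-event circular statistics, inter-event
intervals, binary-series correlations, multitaper spectra (both
normalizations) and event-epoch complex coherence.

``run_model_loop`` preprocesses a cortical drive signal, simulates the FSI
network, reconstructs multichannel LFPs through the forward model, and runs
the same analysis on the model output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import itertools

import numpy as np
import pandas as pd

from . import gamma_events as ge
from . import phase_circular as pc
from .signal_core import BANDS, TimeSeries, analytic_signal, zero_phase_filter
from .spectral import complex_coherence, multitaper_psd, normalize_spectrum
from .fsi_network import (
    DriveSpec,
    NeuronParams,
    SynapseParams,
    build_topology,
    preprocess_drive,
    simulate,
)
from .lfp_forward import ElectrodeGrid, OrientationField, reconstruct

__all__ = ["AnalysisResult", "run_analysis", "run_model_loop", "ModelLoopConfig"]


@dataclass
class AnalysisResult:
    events: dict  # channel -> GammaEventSet (after exclusion)
    phase_locking: pd.DataFrame  # per channel pair
    psd: dict  # channel -> {raw, beta_band, one_over_f2}
    correlations: pd.DataFrame
    intervals: dict  # channel -> ndarray
    coherence: dict  # (ch_i, ch_j) -> ComplexCoherence
    dismissed: list = field(default_factory=list)
    manifest: dict = field(default_factory=dict)


def _restrict_to_epochs(ts: TimeSeries, epochs: np.ndarray | None) -> TimeSeries:
    if epochs is None or len(epochs) == 0:
        return ts
    keep = np.zeros(len(ts), dtype=bool)
    for a, b in np.atleast_2d(epochs):
        s = max(0, ts.index_of(a))
        e = min(len(ts), ts.index_of(b) + 1)
        keep[s:e] = True
    if keep.sum() < ts.rate:
        raise ValueError("epochs cover less than 1 s of signal")
    return ts


def run_analysis(
    channels: dict[str, TimeSeries],
    epochs: np.ndarray | None = None,
    threshold: float = 2.5,
    apply_exclusion: bool = True,
    coherence_pairs: bool = True,
    min_events: int | None = None,
    seed: int = 0,
) -> AnalysisResult:
    """Full analysis of a multichannel recording.

    ``epochs`` (rows of start_s, end_s — e.g. quiet rest) restrict event
    detection; channels with fewer than ``min_events`` (default 50, the
    experimental-data quality rule) retained events are dismissed from phase
    statistics but still contribute spectra and correlations. Short
    desk-scale model runs may pass a smaller ``min_events``.
    """
    if not channels:
        raise ValueError("need at least one channel")
    names = list(channels)
    events, envelopes, delta_phases, psds, intervals = {}, {}, {}, {}, {}
    for name, ts in channels.items():
        env = ge.gamma_envelope(ts)
        evs = ge.detect_events(env, threshold, channel_id=name, epochs=epochs)
        if apply_exclusion:
            evs = ge.band_exclusion(evs, ts, channel_id=name)
        events[name] = evs
        envelopes[name] = env
        delta = zero_phase_filter(
            ts.with_samples(ts.samples - ts.samples.mean()), BANDS["delta"]
        )
        asig = analytic_signal(delta)
        delta_phases[name] = pc.PhaseSeries.from_analytic(asig.phase, ts.rate, ts.t0)
        raw = multitaper_psd(ts)
        psds[name] = {
            "raw": raw,
            "beta_band": normalize_spectrum(raw, "beta_band"),
            "one_over_f2": normalize_spectrum(raw, "one_over_f2"),
        }
        if len(evs) >= 2:
            intervals[name], _, _ = ge.inter_event_intervals(evs)

    # phase-locking per (phase channel, event channel) pair
    dismissed = []
    rows = []
    from .gamma_events import MIN_EVENTS_PER_CHANNEL

    min_ev = MIN_EVENTS_PER_CHANNEL if min_events is None else min_events
    for ch_phase, ch_events in itertools.product(names, names):
        evs = events[ch_events]
        try:
            if len(evs) < min_ev:
                raise pc.ChannelDismissedError(ch_events)
            dist = pc.phases_at_events(delta_phases[ch_phase], evs, enforce_min=False)
        except pc.ChannelDismissedError:
            if ch_events not in dismissed:
                dismissed.append(ch_events)
            continue
        except ValueError:
            continue
        plv = pc.phase_lock_vector(dist, seed=seed)
        rows.append(
            dict(
                chan_phase=ch_phase,
                chan_events=ch_events,
                n_events=plv.n,
                r=plv.r,
                angle_rad=plv.angle,
                rayleigh_p=plv.rayleigh_p,
                dip=plv.dip,
                dip_p=plv.dip_p,
            )
        )
    locking = pd.DataFrame(
        rows,
        columns=[
            "chan_phase", "chan_events", "n_events", "r",
            "angle_rad", "rayleigh_p", "dip", "dip_p",
        ],
    )

    # correlations of binary event series
    corr_rows = []
    coherences = {}
    for a, b in itertools.combinations(names, 2):
        r = ge.event_correlation(
            ge.binarize(envelopes[a], threshold), ge.binarize(envelopes[b], threshold)
        )
        corr_rows.append(dict(chan_a=a, chan_b=b, r=r))
        if coherence_pairs:
            try:
                coherences[(a, b)] = complex_coherence(
                    channels[a], channels[b], [events[a], events[b]]
                )
            except ValueError:
                pass
    correlations = pd.DataFrame(corr_rows, columns=["chan_a", "chan_b", "r"])

    manifest = dict(threshold=threshold, seed=seed, channels=names)
    return AnalysisResult(
        events, locking, psds, correlations, intervals, coherences, dismissed, manifest
    )


@dataclass(frozen=True)
class ModelLoopConfig:
    """Reduced-scale defaults for the model loop; the full printed scale is
    n_side=27, 64 electrodes and long simulations."""

    n_side: int = 15
    duration: float = 10.0
    dt: float = 1e-4
    rho: float = 1000.0
    g_s: float = 0.0008
    gain: float = 1.25
    n_electrodes: int = 4
    gap_enabled: bool = True
    topology_seed: int = 0
    sim_seed: int = 0
    orientation_mode: str = "toward_electrode"
    #: event floor for phase statistics; desk-scale runs are short, the
    #: experimental 50-event rule applies at full scale
    min_events: int = 20


def run_model_loop(
    raw_drive: TimeSeries,
    config: ModelLoopConfig = ModelLoopConfig(),
    neuron_params: NeuronParams | None = None,
) -> tuple[AnalysisResult, "SimulationResult", list[TimeSeries]]:
    """Preprocess drive, simulate the FSI network, reconstruct LFPs, and run
    the full analysis on the reconstructed channels.

    The drive's delta phase is appended as a reference channel so the
    analysis can report model-gamma-to-drive-delta phase locking.
    """
    p = neuron_params or NeuronParams()
    drive_ts = preprocess_drive(raw_drive, gain=config.gain)
    drive = DriveSpec(drive_ts.samples[None, :], drive_ts.rate, gain=config.gain)
    topo = build_topology(n_side=config.n_side, seed=config.topology_seed)
    result = simulate(
        topo,
        p,
        SynapseParams(g_s=config.g_s),
        drive,
        dt=config.dt,
        duration=config.duration,
        gap_enabled=config.gap_enabled,
        rho=config.rho,
        seed=config.sim_seed,
    )
    grid = ElectrodeGrid.centered(config.n_side, config.n_electrodes)
    orientation = OrientationField(config.orientation_mode, seed=config.sim_seed)
    lfps = reconstruct(result, grid, orientation)
    channels = {f"model_e{i}": ts for i, ts in enumerate(lfps)}
    # reference channel carrying the driving delta rhythm
    channels["drive"] = raw_drive.with_samples(
        raw_drive.samples[: len(lfps[0])]
    )
    analysis = run_analysis(channels, apply_exclusion=False, min_events=config.min_events)
    analysis.manifest.update(
        config=config.__dict__, non_physiologic=result.non_physiologic
    )
    return analysis, result, lfps
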