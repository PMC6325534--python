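"""Static figure helpers: polar phase-locking plots and spectra."""

from __future__ import annotations

import numpy as np

__all__ = ["plot_phase_locking", "plot_spectrum"]


def plot_phase_locking(dists, vectors, labels=None, ax=None, bins=24):
    """Polar histogram of event phases with mean-resultant arrows.

    ``dists`` is a list of CircularDistribution, ``vectors`` the matching
    PhaseLockVector per distribution. Angle 0 (delta peak) points right,
    -pi/2 (upsweep) points down.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(subplot_kw={"projection": "polar"})
    edges = np.linspace(-np.pi, np.pi, bins + 1)
    for i, (dist, plv) in enumerate(zip(dists, vectors)):
        counts, _ = np.histogram(dist.angles, bins=edges)
        dens = counts / counts.sum() if counts.sum() else counts
        label = labels[i] if labels else None
        ax.bar(
            (edges[:-1] + edges[1:]) / 2, dens, width=edges[1] - edges[0],
            alpha=0.4, label=label,
        )
        ax.annotate(
            "", xy=(plv.angle, plv.r * dens.max() / max(plv.r, 1e-9)),
            xytext=(0, 0), arrowprops=dict(arrowstyle="->", lw=2),
        )
    if labels:
        ax.legend(loc="upper right", fontsize="small")
    return ax


def plot_spectrum(ps, ax=None, label=None, logy=True):
    """Line plot of a PowerSpectrum with its normalization in the label."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(ps.freqs, ps.power, label=label or ps.normalization)
    if logy:
        ax.set_yscale("log")
    ax.set_xlabel("frequency (Hz)")
    ax.set_ylabel(f"power ({ps.normalization})")
    ax.legend(fontsize="small")
    return ax
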