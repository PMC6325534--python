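"""Plain-text containers for multichannel recordings, epoch labels, events
and result tables.

Recordings: CSV with one time column (s) and one column per channel, plus an
optional YAML sidecar (``<file>.meta.yaml``) holding per-channel metadata
(region label, animal id). Epoch labels: whitespace-separated three-column
text (start_s, end_s, state).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .signal_core import TimeSeries

__all__ = [
    "write_multichannel",
    "read_multichannel",
    "read_epochs",
    "write_epochs",
    "write_events_table",
]


def write_multichannel(
    path, channels: list[TimeSeries], names=None, metadata: dict | None = None
):
    path = Path(path)
    names = names or [f"ch{i}" for i in range(len(channels))]
    if len(names) != len(channels):
        raise ValueError("one name per channel required")
    rate = channels[0].rate
    n = len(channels[0])
    for ts in channels:
        if ts.rate != rate or len(ts) != n:
            raise ValueError("channels must share rate and length")
    df = pd.DataFrame({"time_s": channels[0].times})
    for name, ts in zip(names, channels):
        df[name] = ts.samples
    df.to_csv(path, index=False, float_format="%.8g")
    if metadata is not None:
        side = path.with_suffix(path.suffix + ".meta.yaml")
        side.write_text(yaml.safe_dump(metadata, sort_keys=False))


def read_multichannel(path) -> tuple[dict[str, TimeSeries], dict]:
    path = Path(path)
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy()
    if len(t) < 2:
        raise ValueError("need at least two samples")
    rate = 1.0 / np.median(np.diff(t))
    channels = {
        c: TimeSeries(df[c].to_numpy(), rate, t0=float(t[0]))
        for c in df.columns
        if c != "time_s"
    }
    side = path.with_suffix(path.suffix + ".meta.yaml")
    metadata = yaml.safe_load(side.read_text()) if side.exists() else {}
    return channels, metadata


def read_epochs(path, state: str | None = None) -> np.ndarray:
    """Epoch rows (start_s, end_s), optionally restricted to one state."""
    rows = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        start, end, st = line.split(None, 2)
        if state is None or st == state:
            rows.append((float(start), float(end)))
    return np.array(rows) if rows else np.empty((0, 2))


def write_epochs(path, epochs, state: str = "quiet_rest"):
    lines = [f"{a:.3f}\t{b:.3f}\t{state}" for a, b in epochs]
    Path(path).write_text("\n".join(lines) + "\n")


def write_events_table(path, event_sets: list):
    """Tabular export: channel, t_peak_s, z_peak, epoch_start_s, epoch_end_s."""
    rows = []
    for evs in event_sets:
        for ev in evs.events:
            rows.append(
                dict(
                    channel=evs.channel_id,
                    t_peak_s=ev.t_peak,
                    z_peak=ev.z_peak,
                    epoch_start_s=ev.epoch_start,
                    epoch_end_s=ev.epoch_end,
                )
            )
    pd.DataFrame(
        rows, columns=["channel", "t_peak_s", "z_peak", "epoch_start_s", "epoch_end_s"]
    ).to_csv(path, index=False)
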