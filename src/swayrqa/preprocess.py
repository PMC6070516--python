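"""Signal conditioning: low-pass filtering, whole-body CoM, epoch segmentation.

Raw kinematic signals are low-pass filtered with a zero-phase (forward-
backward) second-order Butterworth at 4 Hz.  Zero-phase filtering is used so
the CoM-platform phase relation — the quantity the recurrence analysis lives
on — is not distorted; the price is that the magnitude response is squared.

Epoch boundaries come from the protocol clock (platform and motion capture
are assumed trigger-synchronized), not from detected zero crossings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, filtfilt

from .core import Epoch, Protocol, TimeSeries

__all__ = ["SegmentSet", "lowpass_filter", "compute_com", "segment_epochs",
           "read_segments", "write_segments"]


@dataclass(frozen=True)
class SegmentSet:
    """Per-segment CoM trajectories plus segmental mass fractions."""

    trajectories: tuple[TimeSeries, ...]
    mass_fractions: np.ndarray

    def __post_init__(self) -> None:
        trajs = tuple(self.trajectories)
        w = np.asarray(self.mass_fractions, dtype=float)
        if len(trajs) == 0:
            raise ValueError("SegmentSet needs at least one segment")
        if w.size != len(trajs):
            raise ValueError("one mass fraction per trajectory required")
        n, fs = trajs[0].n, trajs[0].fs
        if any(t.n != n or t.fs != fs for t in trajs):
            raise ValueError("all segment trajectories must share length and rate")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError(f"mass fractions sum to {w.sum():.12f}, not 1")
        object.__setattr__(self, "trajectories", trajs)
        object.__setattr__(self, "mass_fractions", w)


def lowpass_filter(ts: TimeSeries, cutoff: float = 4.0, order: int = 2) -> TimeSeries:
    """Zero-phase Butterworth low-pass (defaults: 4 Hz cutoff, 2nd order).

    Applied forward and backward, so the effective magnitude response is
    |H(f)|² and the phase response is zero.
    """
    if not (0 < cutoff < ts.fs / 2):
        raise ValueError(f"cutoff must lie in (0, {ts.fs / 2}) Hz, got {cutoff}")
    if order < 1:
        raise ValueError("filter order must be >= 1")
    b, a = butter(order, cutoff, btype="low", fs=ts.fs)
    return TimeSeries(filtfilt(b, a, ts.values), ts.fs, ts.t0)


def compute_com(segments: SegmentSet) -> TimeSeries:
    """Whole-body CoM: mass-weighted sum of the segment CoM trajectories."""
    stack = np.stack([t.values for t in segments.trajectories])
    ref = segments.trajectories[0]
    return TimeSeries(segments.mass_fractions @ stack, ref.fs, ref.t0)


def segment_epochs(ts: TimeSeries, protocol: Protocol, trim: float = 0.0) -> list[Epoch]:
    """Cut a trial into per-epoch sample windows from the protocol clock.

    Returns one :class:`Epoch` per protocol stage, tiling the protocol span
    with half-open 0-based ranges.  ``trim`` (s) optionally drops a transient
    at the start of each epoch; the default keeps every sample.
    """
    if trim < 0:
        raise ValueError("trim must be non-negative")
    need = protocol.n_samples
    if ts.n < need - 1:  # one-sample slack for rounding
        raise ValueError(
            f"signal has {ts.n} samples but the protocol spans {need}"
        )
    b = np.minimum(protocol.boundaries(), ts.n)
    skip = int(round(trim * protocol.fs))
    out = []
    for epoch, lo, hi in zip(protocol.epochs, b[:-1], b[1:]):
        out.append(Epoch(epoch.label, epoch.frequency, lo + skip, hi))
    return out


def write_segments(path, segments: SegmentSet, weights_path=None) -> None:
    """Write segments as wide TSV (time_s, seg01_cm, ...) plus a weights file."""
    import pandas as pd

    ref = segments.trajectories[0]
    data = {"time_s": ref.time()}
    for k, traj in enumerate(segments.trajectories, start=1):
        data[f"seg{k:02d}_cm"] = traj.values
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)
    if weights_path is not None:
        pd.DataFrame(
            {
                "segment": [f"seg{k:02d}" for k in range(1, len(segments.trajectories) + 1)],
                "mass_fraction": segments.mass_fractions,
            }
        ).to_csv(weights_path, sep="\t", index=False)


def read_segments(path, weights_path) -> SegmentSet:
    """Read the wide-TSV segment dialect written by :func:`write_segments`."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    wdf = pd.read_csv(weights_path, sep="\t")
    t = df["time_s"].to_numpy()
    fs = 1.0 / np.median(np.diff(t))
    cols = [c for c in df.columns if c != "time_s"]
    trajs = tuple(TimeSeries(df[c].to_numpy(), fs=fs, t0=t[0]) for c in cols)
    return SegmentSet(trajs, wdf["mass_fraction"].to_numpy())
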