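"""Core containers: uniformly sampled time series and the staircase protocol.

The experimental paradigm is a person standing on a platform that translates
sinusoidally in the medio-lateral direction.  A trial steps the drive frequency
through 0.2-1.2 Hz in ascending then descending order (six full cycles per
step) with 15 s of quiet standing at either end.  Everything downstream
(filtering, embedding, cross-recurrence) operates on pairs of
:class:`TimeSeries` cut into per-frequency :class:`Epoch` windows derived from
a :class:`Protocol`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "TimeSeries",
    "ProtocolEpoch",
    "Protocol",
    "Epoch",
    "ProtocolError",
    "default_protocol",
    "DEFAULT_FREQUENCIES",
]

#: Ascending drive frequencies of the staircase, in Hz.
DEFAULT_FREQUENCIES = (0.2, 0.4, 0.6, 0.8, 1.0, 1.2)


class ProtocolError(ValueError):
    """Raised for protocols with non-positive durations or inconsistent timing."""


@dataclass(frozen=True)
class TimeSeries:
    """A uniformly sampled scalar signal.

    Parameters
    ----------
    values : ndarray
        Signal samples (cm for positions).
    fs : float
        Sampling rate in Hz; must be positive.
    t0 : float
        Time of the first sample in seconds.
    """

    values: np.ndarray
    fs: float = 100.0
    t0: float = 0.0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1:
            raise ValueError("TimeSeries values must be one-dimensional")
        if not np.all(np.isfinite(v)):
            raise ValueError("TimeSeries values must be finite")
        if not (self.fs > 0):
            raise ValueError("sampling rate must be positive")
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def duration(self) -> float:
        """Span covered by the samples, in seconds (n / fs)."""
        return self.n / self.fs

    def time(self) -> np.ndarray:
        """Sample times in seconds."""
        return self.t0 + np.arange(self.n) / self.fs

    def slice(self, start: int, end: int) -> "TimeSeries":
        """Return the half-open sample window [start, end) as a new series."""
        if not (0 <= start < end <= self.n):
            raise IndexError(f"invalid window [{start}, {end}) for n={self.n}")
        return TimeSeries(self.values[start:end], self.fs, self.t0 + start / self.fs)


@dataclass(frozen=True)
class ProtocolEpoch:
    """One stage of the trial: a drive frequency (0 for quiet standing) and a duration."""

    label: str
    frequency: float  # Hz; 0 during quiet standing
    duration: float  # s

    def __post_init__(self) -> None:
        if self.frequency < 0:
            raise ProtocolError(f"epoch {self.label!r}: negative frequency")
        if not (self.duration > 0):
            raise ProtocolError(f"epoch {self.label!r}: duration must be positive")


@dataclass(frozen=True)
class Protocol:
    """Ordered list of epochs defining one trial, plus the sampling rate."""

    epochs: tuple[ProtocolEpoch, ...]
    fs: float = 100.0

    def __post_init__(self) -> None:
        if not (self.fs > 0):
            raise ProtocolError("sampling rate must be positive")
        object.__setattr__(self, "epochs", tuple(self.epochs))

    @property
    def total_duration(self) -> float:
        return float(sum(e.duration for e in self.epochs))

    @property
    def n_samples(self) -> int:
        return int(round(self.total_duration * self.fs))

    def boundaries(self) -> np.ndarray:
        """Cumulative sample indices of epoch edges (length n_epochs + 1).

        Each edge is the rounded cumulative time, so the epochs tile
        [0, n_samples) without gaps or overlaps.
        """
        t = np.concatenate([[0.0], np.cumsum([e.duration for e in self.epochs])])
        return np.round(t * self.fs).astype(int)

    def frequency_per_sample(self) -> np.ndarray:
        """Drive frequency at every sample (Hz, 0 during quiet standing)."""
        f = np.empty(self.n_samples)
        b = self.boundaries()
        for epoch, lo, hi in zip(self.epochs, b[:-1], b[1:]):
            f[lo:hi] = epoch.frequency
        return f

    def moving_epochs(self) -> tuple[ProtocolEpoch, ...]:
        return tuple(e for e in self.epochs if e.frequency > 0)


@dataclass(frozen=True)
class Epoch:
    """A labelled half-open sample window [start, end) of an analyzed signal."""

    label: str
    frequency: float
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"epoch {self.label!r}: invalid range [{self.start}, {self.end})")

    @property
    def n(self) -> int:
        return self.end - self.start


def default_protocol(
    frequencies: Sequence[float] = DEFAULT_FREQUENCIES,
    cycles_per_step: int = 6,
    quiet_duration: float = 15.0,
    fs: float = 100.0,
) -> Protocol:
    """The staircase trial: quiet, ascending steps, descending steps, quiet.

    The descending limb omits the top frequency (it is not repeated), so the
    default yields 13 epochs: 2 quiet + 11 moving conditions, 172 s in total
    at the default frequencies.
    """
    freqs = list(frequencies)
    if any(f <= 0 for f in freqs):
        raise ProtocolError("staircase frequencies must be positive")
    epochs = [ProtocolEpoch("quiet_start", 0.0, quiet_duration)]
    for f in freqs[:-1]:
        epochs.append(ProtocolEpoch(f"{f:g}Hz_up", f, cycles_per_step / f))
    top = freqs[-1]
    epochs.append(ProtocolEpoch(f"{top:g}Hz", top, cycles_per_step / top))
    for f in reversed(freqs[:-1]):
        epochs.append(ProtocolEpoch(f"{f:g}Hz_down", f, cycles_per_step / f))
    epochs.append(ProtocolEpoch("quiet_end", 0.0, quiet_duration))
    return Protocol(tuple(epochs), fs=fs)
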