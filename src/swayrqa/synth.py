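"""Synthetic platform and center-of-mass trajectories for the staircase task.

No public motion-capture data accompanies the paradigm, so this module
generates series pairs carrying the statistical structure the analysis
assumes:

* a phase-continuous sinusoidal platform stepping through the frequency
  staircase,
* a CoM that tracks the platform through a saturating (tanh) nonlinearity with
  a frequency-proportional phase lag and a first-order gain roll-off — the
  "comfortable amplitude" a standing person is willing to ride the platform
  over, and the mechanical low-pass character of the standing body,
* intermittent decoupling: a two-state Markov regime (track / hold) whose
  per-sample decoupling hazard grows linearly with the drive frequency above
  an onset near the known in-/anti-phase transition band, producing the
  laminar (vertical-line) structure seen at fast platform motion,
* intrinsic postural sway riding on the decoupled (quasi-static) state —
  a held CoM wanders slowly, it does not freeze,
* band-limited Gaussian measurement noise.

All randomness flows from a single integer seed through `numpy` seed-sequence
spawning, so every trial/stream is independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy.signal import butter, filtfilt

from .core import Protocol, ProtocolError, TimeSeries

__all__ = [
    "CouplingParams",
    "generate_platform",
    "generate_com",
    "simulate_regime",
    "simulate_trial",
    "decompose_to_segments",
    "dempster_fractions",
    "write_trial",
    "write_epochs_sidecar",
    "read_trial",
    "DEFAULT_HALF_AMPLITUDE",
]

#: Platform half-amplitude in cm (20 cm peak-to-peak drive).
DEFAULT_HALF_AMPLITUDE = 10.0


def _rng(seed: int, *key: int) -> np.random.Generator:
    """Counter-based stream splitting: one root seed, a spawn key per purpose."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


@dataclass(frozen=True)
class CouplingParams:
    """How the CoM follows the platform.

    Parameters
    ----------
    gain : float
        Small-signal tracking gain (1 = rides the platform).
    comfortable_amplitude : float
        Saturation scale A_c in cm; the CoM excursion approaches this bound as
        the platform moves beyond it.  ``inf`` disables saturation.
    gain_rolloff_hz : float or None
        Corner frequency of a first-order tracking-gain roll-off,
        ``g(f) = gain / sqrt(1 + (f / gain_rolloff_hz)^2)``: the standing
        body follows slow drives faithfully but cannot ride fast ones at
        full amplitude.  ``None`` disables the roll-off.
    lag_per_hz : float
        Tracking delay in seconds per Hz of drive frequency; models the
        growing phase lag of postural responses at faster drives.
    p_decouple : float
        Per-sample decoupling hazard per Hz of drive frequency above
        ``decouple_onset_hz``: the probability of dropping out of tracking at
        drive frequency f is ``p_decouple * max(0, f - decouple_onset_hz)``.
        Slow drives are ridden continuously; above the onset the hazard grows
        linearly with frequency.
    decouple_onset_hz : float
        Drive frequency at which decoupling episodes start to occur (the
        postural in-/anti-phase transition band lies around 0.4-0.6 Hz).
    p_recouple : float
        Per-sample probability of resuming tracking from a hold.  The default
        gives quasi-static trapped states lasting seconds.
    sway_sd : float
        Standard deviation (cm) of the intrinsic medio-lateral sway that the
        decoupled CoM performs around its held position.
    sway_cutoff : float
        Low-pass cutoff (Hz) of the intrinsic sway; quiet-stance CoM sway
        concentrates below ~0.5 Hz.
    noise_sd : float
        Standard deviation of additive Gaussian measurement noise (cm)
        before low-pass filtering.
    noise_cutoff : float
        Low-pass cutoff applied to the noise (Hz), matching the analysis
        filter band.
    seed : int
        Root seed for the regime chain, sway and noise streams.
    """

    gain: float = 1.0
    comfortable_amplitude: float = 6.0
    gain_rolloff_hz: float | None = 0.8
    lag_per_hz: float = 0.1
    p_decouple: float = 0.05
    decouple_onset_hz: float = 0.5
    p_recouple: float = 0.002
    sway_sd: float = 0.8
    sway_cutoff: float = 0.5
    noise_sd: float = 0.3
    noise_cutoff: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_decouple <= 1.0 and 0.0 <= self.p_recouple <= 1.0):
            raise ValueError("regime probabilities must lie in [0, 1]")
        if not (self.comfortable_amplitude > 0):
            raise ValueError("comfortable_amplitude must be positive")
        if self.noise_sd < 0 or self.sway_sd < 0:
            raise ValueError("noise_sd and sway_sd must be non-negative")

    def replace(self, **kw) -> "CouplingParams":
        return replace(self, **kw)


def generate_platform(
    protocol: Protocol,
    amplitude: float = DEFAULT_HALF_AMPLITUDE,
    seed: int = 0,
) -> TimeSeries:
    """Piecewise sinusoidal platform drive for the staircase protocol.

    The phase is accumulated continuously across frequency steps (no reset),
    so there is no discontinuity a real motor would not produce.  The signal
    is identically zero during quiet epochs.  ``amplitude`` is the
    half-amplitude (zero-to-peak) in cm; ``seed`` is accepted for interface
    symmetry (the platform is deterministic).
    """
    if amplitude < 0:
        raise ValueError("amplitude must be non-negative")
    f = protocol.frequency_per_sample()  # validates the protocol
    # phase[i] = 2*pi * sum_{k<i} f_k / fs  -> continuous across steps
    phase = 2.0 * np.pi * np.concatenate([[0.0], np.cumsum(f[:-1])]) / protocol.fs
    values = amplitude * np.sin(phase)
    values[f == 0] = 0.0
    return TimeSeries(values, fs=protocol.fs, t0=0.0)


def generate_com(
    platform: TimeSeries,
    protocol: Protocol,
    params: CouplingParams | None = None,
) -> TimeSeries:
    """Simulate the CoM response to a platform drive.

    In the tracking regime the CoM is a saturating, lagged, low-passed copy
    of the platform::

        com_track(t) = A_c * tanh(g(f) * platform(t - lag(f)) / A_c)

    with ``lag(f) = lag_per_hz * f`` and ``g(f)`` the first-order gain
    roll-off.  A two-state Markov chain switches between tracking and a
    quasi-static hold; the decoupling hazard is proportional to the drive
    frequency above ``decouple_onset_hz``, so holds become frequent at fast
    drives (the intermittent, laminar behaviour).  During a hold the CoM is
    not frozen: it performs intrinsic low-frequency sway around the held
    position, continuous at the moment of decoupling.  Band-limited Gaussian
    measurement noise is added last.  Deterministic given ``params.seed``.
    """
    if params is None:
        params = CouplingParams()
    n = protocol.n_samples
    if platform.n != n or platform.fs != protocol.fs:
        raise ValueError(
            f"platform ({platform.n} samples @ {platform.fs} Hz) does not match "
            f"protocol ({n} samples @ {protocol.fs} Hz)"
        )
    fs = protocol.fs
    f = protocol.frequency_per_sample()
    t = platform.time()

    # frequency-dependent lag, realised by resampling the drive at t - lag
    lagged = np.interp(t - params.lag_per_hz * f, t, platform.values)
    g = params.gain
    if params.gain_rolloff_hz is not None:
        g = g / np.sqrt(1.0 + (f / params.gain_rolloff_hz) ** 2)
    if np.isinf(params.comfortable_amplitude):
        tracked = g * lagged
    else:
        a_c = params.comfortable_amplitude
        tracked = a_c * np.tanh(g * lagged / a_c)

    # intrinsic sway path followed by the CoM while decoupled
    sway = np.zeros(n)
    if params.sway_sd > 0:
        sway = _rng(params.seed, 4).normal(0.0, 1.0, n)
        if 0 < params.sway_cutoff < fs / 2:
            b, a = butter(2, params.sway_cutoff, btype="low", fs=fs)
            sway = filtfilt(b, a, sway)
        sd = sway.std()
        if sd > 0:
            sway *= params.sway_sd / sd

    regime = simulate_regime(protocol, params)
    com = np.where(regime, tracked, 0.0)
    # fill each maximal hold with the last tracked value plus relative sway
    edges = np.flatnonzero(np.diff(regime.astype(np.int8)))
    starts = edges[~regime[edges + 1]] + 1
    for a in starts:
        b = a
        while b < n and not regime[b]:
            b += 1
        com[a:b] = com[a - 1] + sway[a:b] - sway[a - 1]

    if params.noise_sd > 0:
        noise = _rng(params.seed, 2).normal(0.0, params.noise_sd, n)
        if 0 < params.noise_cutoff < fs / 2:
            b, a = butter(2, params.noise_cutoff, btype="low", fs=fs)
            noise = filtfilt(b, a, noise)
        com = com + noise

    return TimeSeries(com, fs=fs, t0=platform.t0)


def simulate_regime(protocol: Protocol, params: CouplingParams) -> np.ndarray:
    """Two-state coupling regime per sample: True = tracking, False = hold.

    A Markov chain starting in tracking; the per-sample decoupling hazard is
    ``p_decouple * max(0, f - decouple_onset_hz)`` at drive frequency f and
    the recoupling probability is ``p_recouple``.  At a fixed drive the
    stationary hold fraction is hazard / (hazard + p_recouple).
    """
    f = protocol.frequency_per_sample()
    n = f.size
    p_dec = np.clip(
        params.p_decouple * np.maximum(0.0, f - params.decouple_onset_hz), 0.0, 1.0
    )
    u = _rng(params.seed, 1).random(n)
    regime = np.empty(n, dtype=bool)
    regime[0] = tracking = True
    for i in range(1, n):
        if tracking:
            tracking = not (u[i] < p_dec[i])
        else:
            tracking = u[i] < params.p_recouple
        regime[i] = tracking
    return regime


def simulate_trial(
    protocol: Protocol,
    params: CouplingParams | None = None,
    amplitude: float = DEFAULT_HALF_AMPLITUDE,
) -> tuple[TimeSeries, TimeSeries]:
    """Convenience: platform drive plus CoM response for one trial."""
    platform = generate_platform(protocol, amplitude=amplitude)
    com = generate_com(platform, protocol, params)
    return platform, com


def dempster_fractions() -> np.ndarray:
    """Dempster segmental mass fractions for a 13-segment body model.

    Head-and-trunk plus paired upper arms, forearms, hands, thighs, shanks
    and feet; fractions sum to 1.
    """
    paired = [0.028, 0.016, 0.006, 0.100, 0.0465, 0.0145]
    return np.array([0.578] + [w for w in paired for _ in range(2)])


def decompose_to_segments(
    com: TimeSeries,
    n_segments: int,
    mass_fractions,
    seed: int = 0,
    perturbation_sd: float = 1.0,
) -> list[TimeSeries]:
    """Split a whole-body CoM into per-segment trajectories.

    Each segment is the CoM plus a random perturbation; the perturbations are
    projected so their mass-weighted sum vanishes, hence the weighted sum of
    the returned segments reproduces ``com`` exactly (up to float rounding).
    Used to round-trip test the whole-body CoM computation.
    """
    w = np.asarray(mass_fractions, dtype=float)
    if w.size != n_segments:
        raise ValueError(f"expected {n_segments} mass fractions, got {w.size}")
    if abs(w.sum() - 1.0) > 1e-9:
        raise ValueError(f"mass fractions sum to {w.sum():.12f}, not 1")
    u = _rng(seed, 3).normal(0.0, perturbation_sd, size=(n_segments, com.n))
    u -= w @ u  # weighted mean of perturbations is now zero
    return [TimeSeries(com.values + u[k], com.fs, com.t0) for k in range(n_segments)]


# ---------------------------------------------------------------------------
# TSV interchange


def write_trial(path, platform: TimeSeries, com: TimeSeries) -> None:
    """Write one trial as TSV with columns time_s, platform_cm, com_cm."""
    if platform.n != com.n or platform.fs != com.fs:
        raise ValueError("platform and com must share length and rate")
    import pandas as pd

    pd.DataFrame(
        {"time_s": platform.time(), "platform_cm": platform.values, "com_cm": com.values}
    ).to_csv(path, sep="\t", index=False)


def write_epochs_sidecar(path, protocol: Protocol) -> None:
    """Write epoch boundaries as TSV: epoch_label, f_hz, t_start_s, t_end_s."""
    import pandas as pd

    b = protocol.boundaries() / protocol.fs
    pd.DataFrame(
        {
            "epoch_label": [e.label for e in protocol.epochs],
            "f_hz": [e.frequency for e in protocol.epochs],
            "t_start_s": b[:-1],
            "t_end_s": b[1:],
        }
    ).to_csv(path, sep="\t", index=False)


def read_trial(path) -> tuple[TimeSeries, TimeSeries]:
    """Read a trial TSV written by :func:`write_trial`."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    for col in ("time_s", "platform_cm", "com_cm"):
        if col not in df.columns:
            raise ValueError(f"trial file {Path(path).name} lacks column {col!r}")
    t = df["time_s"].to_numpy()
    if t.size < 2:
        raise ValueError("trial file must contain at least two samples")
    fs = 1.0 / np.median(np.diff(t))
    return (
        TimeSeries(df["platform_cm"].to_numpy(), fs=fs, t0=t[0]),
        TimeSeries(df["com_cm"].to_numpy(), fs=fs, t0=t[0]),
    )
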