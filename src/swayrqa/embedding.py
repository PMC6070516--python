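"""Delay-embedding parameter selection and state-space reconstruction.

The scalar CoM and platform series are lifted to m-dimensional trajectories
by the standard time-delay method.  The delay tau is chosen at the first
local minimum of the average mutual information (AMI) between the series and
its lagged copy; the dimension m is the smallest one at which the fraction of
false nearest neighbours (FNN, Abarbanel criteria) drops below threshold.
Per-series estimates are pooled to a single (m, tau) for the recurrence maps:
the maximum m (topological sufficiency for every series) and the median tau,
after discarding 1.5x-IQR outliers.  The analysis defaults are m = 6,
tau = 25 samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .core import TimeSeries

__all__ = [
    "EmbeddingParams",
    "EmbeddedTrajectory",
    "ZeroInformationError",
    "ami_delay",
    "fnn_dimension",
    "delay_embed",
    "pool_params",
]


class ZeroInformationError(ValueError):
    """Raised when a signal is constant and carries no mutual information."""


@dataclass(frozen=True)
class EmbeddingParams:
    """Embedding dimension m and delay tau (samples); defaults m=6, tau=25."""

    m: int = 6
    tau: int = 25

    def __post_init__(self) -> None:
        if self.m < 1 or self.tau < 1:
            raise ValueError("need m >= 1 and tau >= 1")


@dataclass(frozen=True)
class EmbeddedTrajectory:
    """An (n_points, m) array of delay vectors with its embedding parameters."""

    points: np.ndarray
    m: int
    tau: int

    def __post_init__(self) -> None:
        p = np.asarray(self.points, dtype=float)
        if p.ndim != 2 or p.shape[1] != self.m:
            raise ValueError("points must be an (n, m) array")
        if p.shape[0] < 1:
            raise ValueError("embedded trajectory must contain at least one point")
        object.__setattr__(self, "points", p)

    @property
    def n(self) -> int:
        return self.points.shape[0]


def _default_bins(n: int) -> int:
    return max(2, int(np.ceil(np.sqrt(n / 5))))


def _mutual_information(x: np.ndarray, y: np.ndarray, ex: np.ndarray, ey: np.ndarray) -> float:
    """Plug-in MI (nats) from an equal-width 2-D histogram."""
    h, _, _ = np.histogram2d(x, y, bins=[ex, ey])
    p = h / h.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    return float(np.sum(p[nz] * np.log(p[nz] / (px @ py)[nz])))


def _smooth(a: np.ndarray, w: int) -> np.ndarray:
    if w <= 1:
        return a
    pad = np.concatenate([np.repeat(a[0], w // 2), a, np.repeat(a[-1], w // 2)])
    return np.convolve(pad, np.ones(w) / w, mode="valid")


def ami_delay(
    ts: TimeSeries,
    max_lag: int = 100,
    n_bins: int | None = None,
    n_offsets: int = 4,
) -> tuple[np.ndarray, int]:
    """Average mutual information curve and the delay at its first minimum.

    ``ami_curve[k]`` is the MI in nats between ``x[t]`` and ``x[t+k]`` from an
    equal-width 2-D histogram (by default ceil(sqrt(N/5)) bins per axis),
    averaged over ``n_offsets``^2 phase-shifted copies of the bin grid.  The
    grid dithering removes the resonance ripple that plain binning produces
    on strongly periodic signals (which only visit a finite set of values);
    ``n_offsets=1`` recovers the single-grid estimator.

    The delay ``tau`` is the first local minimum of the lightly smoothed
    curve; when that minimum sits in a flat valley (curve within 1.5% of the
    valley floor, relative to the lag-0 drop), the centre of the valley is
    reported, which pins the quarter-period delay of periodic signals whose
    binned-MI valley is wide and flat.  If the curve has no local minimum the
    global argmin over k >= 1 is returned with a warning.
    """
    x = ts.values
    n = x.size
    if n <= 2 * max_lag:
        raise ValueError(f"need N > 2*max_lag; N={n}, max_lag={max_lag}")
    if np.ptp(x) == 0:
        raise ZeroInformationError("constant signal carries no mutual information")
    if n_bins is None:
        n_bins = _default_bins(n)
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if n_offsets < 1:
        raise ValueError("n_offsets must be >= 1")

    lo, hi = x.min(), x.max()
    if n_offsets == 1:
        grids = [np.linspace(lo, hi, n_bins + 1)]
    else:
        bw = (hi - lo) / n_bins
        grids = [
            lo - o * bw + np.arange(n_bins + 2) * bw
            for o in np.arange(n_offsets) / n_offsets
        ]
    ami = np.zeros(max_lag + 1)
    for ex in grids:
        for ey in grids:
            ami += [
                _mutual_information(x[: n - k], x[k:], ex, ey)
                for k in range(max_lag + 1)
            ]
    ami /= len(grids) ** 2

    smoothed = _smooth(ami, 5)
    tau = None
    for k in range(1, max_lag):
        if smoothed[k] < smoothed[k - 1] and smoothed[k] <= smoothed[k + 1]:
            tau = k
            break
    if tau is None:
        tau = int(np.argmin(ami[1:]) + 1)
        warnings.warn(
            "AMI curve has no local minimum up to max_lag; using the global "
            f"argmin tau={tau}",
            stacklevel=2,
        )
        return ami, tau

    # flat-valley refinement on the unsmoothed curve
    floor_k = int(np.argmin(ami[1:]) + 1)
    tol = 0.015 * max(ami[0] - ami[floor_k], 0.0)
    level = ami[floor_k] + tol
    lo_k = hi_k = floor_k
    while lo_k > 1 and ami[lo_k - 1] <= level:
        lo_k -= 1
    while hi_k < max_lag and ami[hi_k + 1] <= level:
        hi_k += 1
    if lo_k <= tau <= hi_k:
        tau = int(round((lo_k + hi_k) / 2))
    return ami, tau


def fnn_dimension(
    ts: TimeSeries,
    tau: int,
    m_max: int = 10,
    rtol: float = 15.0,
    atol: float = 2.0,
    threshold: float = 0.01,
) -> tuple[np.ndarray, int]:
    """False-nearest-neighbour fractions for m = 1..m_max and the selected m.

    A nearest neighbour in dimension m is false if, on unfolding to m+1, the
    added-coordinate separation exceeds ``rtol`` times the m-dimensional
    distance, or the unfolded distance exceeds ``atol`` times the signal's
    standard deviation (Abarbanel's two criteria; defaults 15, 2).  The
    selected m is the smallest with a false fraction <= ``threshold`` (1%);
    if none qualifies, ``m_max`` is returned with a warning.
    """
    if m_max < 2:
        raise ValueError("m_max must be >= 2")
    if tau < 1:
        raise ValueError("tau must be >= 1")
    x = ts.values
    n = x.size
    need = m_max * tau + 2
    if n < need:
        raise ValueError(
            f"series too short for m_max={m_max}, tau={tau}: need N >= {need}, got {n}"
        )
    r_a = float(np.std(x))
    if r_a == 0:
        raise ZeroInformationError("constant signal has no neighbourhood structure")

    fracs = np.empty(m_max)
    for m in range(1, m_max + 1):
        # keep only points whose (m+1)-th coordinate exists
        n_pts = n - m * tau
        pts = np.stack([x[k * tau : k * tau + n_pts] for k in range(m)], axis=1)
        nxt = x[m * tau : m * tau + n_pts]
        tree = cKDTree(pts)
        dist, idx = tree.query(pts, k=2)
        d_m, nn = dist[:, 1], idx[:, 1]
        extra = np.abs(nxt - nxt[nn])
        # the 1e-8*r_a floor keeps exact twins (d_m at float-noise scale, as in
        # perfectly periodic signals) from tripping the ratio criterion
        false = (extra > np.maximum(rtol * d_m, 1e-8 * r_a)) | (
            np.hypot(d_m, extra) > atol * r_a
        )
        fracs[m - 1] = false.mean()

    below = np.nonzero(fracs <= threshold)[0]
    if below.size:
        m_sel = int(below[0] + 1)
    else:
        m_sel = m_max
        warnings.warn(
            f"FNN fraction never fell below {threshold:g}; returning m_max={m_max}",
            stacklevel=2,
        )
    return fracs, m_sel


def delay_embed(ts: TimeSeries, params: EmbeddingParams) -> EmbeddedTrajectory:
    """Time-delay embedding: point i = (x[i], x[i+tau], ..., x[i+(m-1)tau])."""
    m, tau = params.m, params.tau
    n = ts.values.size
    n_pts = n - (m - 1) * tau
    if n_pts < 1:
        raise ValueError(
            f"series too short to embed: need N > {(m - 1) * tau}, got {n}"
        )
    pts = np.stack([ts.values[k * tau : k * tau + n_pts] for k in range(m)], axis=1)
    return EmbeddedTrajectory(pts, m=m, tau=tau)


def _drop_outliers(vals: np.ndarray) -> np.ndarray:
    """Discard values beyond 1.5 IQR from the quartiles (kept if IQR is 0)."""
    q1, q3 = np.percentile(vals, [25, 75])
    iqr = q3 - q1
    keep = (vals >= q1 - 1.5 * iqr) & (vals <= q3 + 1.5 * iqr)
    return vals[keep]


def pool_params(
    per_series: list[EmbeddingParams],
    tau_stat: str = "median",
) -> EmbeddingParams:
    """Pool per-series (m, tau) estimates into one pair for the recurrence maps.

    After discarding 1.5x-IQR outliers, m is pooled by maximum (an embedding
    sufficient for every series) and tau by the rounded median (or mean with
    ``tau_stat='mean'``).
    """
    if not per_series:
        raise ValueError("cannot pool an empty parameter list")
    if tau_stat not in ("median", "mean"):
        raise ValueError("tau_stat must be 'median' or 'mean'")
    ms = _drop_outliers(np.array([p.m for p in per_series], dtype=float))
    taus = _drop_outliers(np.array([p.tau for p in per_series], dtype=float))
    stat = np.median if tau_stat == "median" else np.mean
    return EmbeddingParams(m=int(np.max(ms)), tau=int(round(float(stat(taus)))))
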