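"""Cross-recurrence quantification of a coupled series pair.

A cross-recurrence plot (CRP) between two delay-embedded trajectories marks
every time pair (i, j) at which trajectory A's state lies within a Euclidean
radius of trajectory B's state.  Its line structures quantify the coupling:

* diagonal lines — stretches where the two systems evolve in parallel;
  their recurrent-point fraction is %determinism (DET),
* vertical lines — stretches where one state holds near a single state of
  the other (laminar, intermittent episodes); their fraction is %laminarity
  (LAM),
* the Shannon entropy of the line-length distribution indexes the
  complexity of that structure.

The radius is not fixed a priori: it is calibrated per epoch so the overall
recurrence rate hits a target (2.5% by default), which makes the radius
itself a measure — a weakly recurrent pair needs a larger radius to reach
the same rate.

The :class:`CrossRecurrence` model / :class:`CrossRecurrenceResults` pair is
the main entry point; the module-level functions expose each step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .core import TimeSeries
from .embedding import EmbeddedTrajectory, EmbeddingParams, delay_embed

__all__ = [
    "RecurrenceMatrix",
    "LineHistogram",
    "CRQAResult",
    "RadiusCalibration",
    "EpochTooShortError",
    "cross_recurrence_matrix",
    "recurrence_rate",
    "calibrate_radius",
    "line_histograms",
    "crqa_measures",
    "crqa_epoch",
    "CrossRecurrence",
    "CrossRecurrenceResults",
]


class EpochTooShortError(ValueError):
    """Raised when an epoch has too few samples to embed or normalize."""


@dataclass(frozen=True)
class RecurrenceMatrix:
    """Binary cross-recurrence structure plus the radius that produced it."""

    R: np.ndarray
    radius: float
    norm: str = "euclidean"

    def __post_init__(self) -> None:
        r = np.asarray(self.R)
        if r.ndim != 2:
            raise ValueError("R must be a 2-D matrix")
        if r.dtype != bool:
            vals = np.unique(r)
            if not np.all(np.isin(vals, (0, 1))):
                raise ValueError("R entries must be binary")
            r = r.astype(bool)
        object.__setattr__(self, "R", r)

    @property
    def shape(self) -> tuple[int, int]:
        return self.R.shape

    def n_recurrent(self) -> int:
        return int(self.R.sum())


@dataclass(frozen=True)
class LineHistogram:
    """Counts of maximal 1-runs by length, along diagonals or columns."""

    direction: str  # "diagonal" | "vertical"
    counts: np.ndarray  # counts[l] = number of maximal runs of length l
    min_len: int

    def __post_init__(self) -> None:
        if self.direction not in ("diagonal", "vertical"):
            raise ValueError("direction must be 'diagonal' or 'vertical'")
        if self.min_len < 1:
            raise ValueError("min_len must be >= 1")
        c = np.asarray(self.counts, dtype=np.int64)
        if c.ndim != 1 or (c.size and c[0] != 0) or np.any(c < 0):
            raise ValueError("counts must be a 1-D non-negative array with counts[0]=0")
        object.__setattr__(self, "counts", c)

    def total_points(self) -> int:
        """Sum of l*H(l) over all lengths — the recurrent points covered."""
        return int(np.arange(self.counts.size) @ self.counts)


@dataclass(frozen=True)
class RadiusCalibration:
    """Outcome of the fixed-recurrence-rate radius search."""

    radius: float
    achieved_rr: float
    converged: bool


@dataclass(frozen=True)
class CRQAResult:
    """The measure bundle for one epoch.

    Fractions (rr, det, lam) lie in [0, 1]; mean line lengths are in samples;
    entropies are in nats unless computed with ``bits=True``.  Degenerate
    cases use documented sentinels: with no qualifying lines, DET/LAM, the
    mean lines and the entropies are 0.
    """

    rr: float
    det: float
    lam: float
    mean_diag: float
    mean_vert: float
    ent_diag: float
    ent_vert: float
    radius: float
    epoch_label: str = ""

    def as_dict(self) -> dict:
        return {
            "rr": self.rr,
            "det": self.det,
            "lam": self.lam,
            "mean_diag": self.mean_diag,
            "mean_vert": self.mean_vert,
            "ent_diag": self.ent_diag,
            "ent_vert": self.ent_vert,
            "radius": self.radius,
            "epoch_label": self.epoch_label,
        }


def _check_pair(a: EmbeddedTrajectory, b: EmbeddedTrajectory) -> None:
    if a.m != b.m or a.tau != b.tau:
        raise ValueError(
            f"embedding parameters differ: (m={a.m}, tau={a.tau}) vs (m={b.m}, tau={b.tau})"
        )


def cross_recurrence_matrix(
    a: EmbeddedTrajectory, b: EmbeddedTrajectory, radius: float
) -> RecurrenceMatrix:
    """R[i, j] = 1 iff ||a_i - b_j||_2 <= radius (inclusive threshold)."""
    _check_pair(a, b)
    if radius < 0:
        raise ValueError("radius must be non-negative")
    d = cdist(a.points, b.points)
    return RecurrenceMatrix(d <= radius, radius=radius)


def recurrence_rate(rm: RecurrenceMatrix) -> float:
    """Fraction of recurrent entries: sum(R) / (n_rows * n_cols)."""
    if rm.R.size == 0:
        raise ValueError("empty recurrence matrix")
    return float(rm.R.mean())


def _calibrate_on_distances(
    d: np.ndarray, target_rr: float, r0: float, tol: float
) -> RadiusCalibration:
    def rr(r: float) -> float:
        return float((d <= r).mean())

    # bracket the target by geometric expansion/contraction from r0
    lo = hi = float(r0)
    if rr(hi) < target_rr:
        while rr(hi) < target_rr:
            hi *= 2.0
            if hi > 1e12:
                break
        lo = hi / 2.0
    else:
        while rr(lo) >= target_rr and lo > 1e-12:
            lo /= 2.0
    # bisection on the bracket
    best_r, best_rr = hi, rr(hi)
    if abs(rr(lo) - target_rr) < abs(best_rr - target_rr):
        best_r, best_rr = lo, rr(lo)
    while abs(best_rr - target_rr) > tol and hi - lo > 1e-9:
        mid = 0.5 * (lo + hi)
        rr_mid = rr(mid)
        if abs(rr_mid - target_rr) < abs(best_rr - target_rr):
            best_r, best_rr = mid, rr_mid
        if rr_mid < target_rr:
            lo = mid
        else:
            hi = mid
    return RadiusCalibration(best_r, best_rr, abs(best_rr - target_rr) <= tol)


def calibrate_radius(
    a: EmbeddedTrajectory,
    b: EmbeddedTrajectory,
    target_rr: float = 0.025,
    r0: float = 0.01,
    tol: float = 0.001,
) -> RadiusCalibration:
    """Find the radius at which the recurrence rate hits ``target_rr``.

    Starting from ``r0`` (0.01 by default), the radius is expanded (or
    shrunk) geometrically until the target rate is bracketed, then bisected
    until the achieved rate is within ``tol`` of the target or the bracket
    width falls below 1e-9.  RR is non-decreasing in the radius (set
    inclusion), so the search is monotone.  When the target is unattainable
    with the available distance resolution, the nearest achievable rate is
    returned with ``converged=False``.
    """
    _check_pair(a, b)
    if not (0 < target_rr < 1):
        raise ValueError("target_rr must lie in (0, 1)")
    if r0 <= 0:
        raise ValueError("starting radius must be positive")
    d = cdist(a.points, b.points)
    return _calibrate_on_distances(d, target_rr, r0, tol)


def _run_lengths(segments: list[np.ndarray]) -> np.ndarray:
    """Lengths of maximal 1-runs across a list of binary 1-D arrays."""
    if not segments:
        return np.zeros(0, dtype=np.int64)
    # join with zero separators so runs cannot bridge segments
    joined = np.zeros(sum(s.size + 1 for s in segments) + 1, dtype=np.int8)
    pos = 1
    for s in segments:
        joined[pos : pos + s.size] = s
        pos += s.size + 1
    d = np.diff(joined)
    starts = np.nonzero(d == 1)[0]
    ends = np.nonzero(d == -1)[0]
    return ends - starts


def line_histograms(
    rm: RecurrenceMatrix, direction: str, min_len: int = 2
) -> LineHistogram:
    """Histogram of maximal run lengths along diagonals or columns.

    Runs touching the matrix border are counted at their observed length.
    The histogram stores every length >= 1; ``min_len`` (the d_min / v_min of
    the downstream measures, default 2) travels with it.
    """
    r = rm.R.astype(np.int8)
    n_rows, n_cols = r.shape
    if direction == "diagonal":
        segs = [np.diagonal(r, k) for k in range(-(n_rows - 1), n_cols)]
    elif direction == "vertical":
        segs = [r[:, j] for j in range(n_cols)]
    else:
        raise ValueError("direction must be 'diagonal' or 'vertical'")
    lengths = _run_lengths(segs)
    max_l = max(n_rows, n_cols)
    counts = np.bincount(lengths, minlength=max_l + 1)
    return LineHistogram(direction, counts, min_len)


def _line_stats(h: LineHistogram, bits: bool) -> tuple[float, float, float]:
    """(weight, mean length, entropy) of lines with length >= min_len."""
    ln = np.arange(h.counts.size)
    sel = ln >= h.min_len
    c = h.counts[sel]
    n_lines = c.sum()
    if n_lines == 0:
        return 0.0, 0.0, 0.0
    weight = float(ln[sel] @ c)
    mean_len = weight / n_lines
    p = c[c > 0] / n_lines
    ent = float(-(p @ np.log(p)))
    if bits:
        ent /= math.log(2.0)
    return weight, float(mean_len), ent


def crqa_measures(
    rm: RecurrenceMatrix,
    h_diag: LineHistogram,
    h_vert: LineHistogram,
    epoch_label: str = "",
    bits: bool = False,
) -> CRQAResult:
    """Compute RR, DET, LAM, mean line lengths and line entropies.

    DET = sum_{l>=d_min} l*H_D(l) / sum R_ij and LAM analogously from the
    vertical histogram; mean lines and Shannon entropies are taken over the
    same l >= min_len distributions (natural log by default, ``bits=True``
    for bits).  The histograms are validated against the matrix via the
    conservation identity sum_l l*H(l) = sum R_ij.
    """
    if h_diag.direction != "diagonal" or h_vert.direction != "vertical":
        raise ValueError("histogram directions do not match their roles")
    total = rm.n_recurrent()
    for h in (h_diag, h_vert):
        if h.total_points() != total:
            raise ValueError(
                f"{h.direction} histogram covers {h.total_points()} points but the "
                f"matrix has {total} recurrent points; histogram/matrix mismatch"
            )
    w_d, mean_d, ent_d = _line_stats(h_diag, bits)
    w_v, mean_v, ent_v = _line_stats(h_vert, bits)
    det = w_d / total if total else 0.0
    lam = w_v / total if total else 0.0
    return CRQAResult(
        rr=recurrence_rate(rm),
        det=det,
        lam=lam,
        mean_diag=mean_d,
        mean_vert=mean_v,
        ent_diag=ent_d,
        ent_vert=ent_v,
        radius=rm.radius,
        epoch_label=epoch_label,
    )


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        raise EpochTooShortError("cannot z-score a constant epoch")
    return (x - x.mean()) / sd


class CrossRecurrence:
    """Cross-recurrence model of a CoM/platform (or any coupled) series pair.

    Built from two equal-rate scalar series; ``fit()`` z-scores both (so the
    radius is amplitude-free), delay-embeds them, calibrates the radius to
    the target recurrence rate, and returns a
    :class:`CrossRecurrenceResults` with all line-structure measures.

    Parameters
    ----------
    endog, exog : TimeSeries or array-like
        The two signals (by convention the CoM is `endog` — rows of the
        recurrence matrix — and the platform `exog`).  The longer one is
        truncated to the shorter before embedding.
    embedding : EmbeddingParams
        Dimension and delay; defaults m=6, tau=25.
    target_rr : float
        Calibration target for the recurrence rate (default 0.025).
    normalize : bool
        z-score both series before embedding (default True).
    d_min, v_min : int
        Minimum diagonal / vertical line lengths (both default 2).
    """

    def __init__(
        self,
        endog,
        exog,
        embedding: EmbeddingParams | None = None,
        target_rr: float = 0.025,
        normalize: bool = True,
        d_min: int = 2,
        v_min: int = 2,
        r0: float = 0.01,
        rr_tol: float = 0.001,
        label: str = "",
    ) -> None:
        a = endog.values if isinstance(endog, TimeSeries) else np.asarray(endog, float)
        b = exog.values if isinstance(exog, TimeSeries) else np.asarray(exog, float)
        if (
            isinstance(endog, TimeSeries)
            and isinstance(exog, TimeSeries)
            and endog.fs != exog.fs
        ):
            raise ValueError("the two series must share a sampling rate")
        n = min(a.size, b.size)
        self.endog, self.exog = a[:n], b[:n]
        self.embedding = embedding or EmbeddingParams()
        self.target_rr = target_rr
        self.normalize = normalize
        self.d_min, self.v_min = d_min, v_min
        self.r0, self.rr_tol = r0, rr_tol
        self.label = label
        need = (self.embedding.m - 1) * self.embedding.tau + 1
        if n < need:
            raise EpochTooShortError(
                f"epoch of {n} samples is too short for m={self.embedding.m}, "
                f"tau={self.embedding.tau} (needs >= {need})"
            )

    @classmethod
    def from_dataframe(
        cls,
        df,
        endog_col: str = "com_cm",
        exog_col: str = "platform_cm",
        **kwargs,
    ) -> "CrossRecurrence":
        return cls(df[endog_col].to_numpy(), df[exog_col].to_numpy(), **kwargs)

    def fit(self, bits: bool = False) -> "CrossRecurrenceResults":
        a = _zscore(self.endog) if self.normalize else self.endog
        b = _zscore(self.exog) if self.normalize else self.exog
        emb_a = delay_embed(TimeSeries(a), self.embedding)
        emb_b = delay_embed(TimeSeries(b), self.embedding)
        d = cdist(emb_a.points, emb_b.points)
        cal = _calibrate_on_distances(d, self.target_rr, self.r0, self.rr_tol)
        rm = RecurrenceMatrix(d <= cal.radius, radius=cal.radius)
        h_d = line_histograms(rm, "diagonal", self.d_min)
        h_v = line_histograms(rm, "vertical", self.v_min)
        measures = crqa_measures(rm, h_d, h_v, epoch_label=self.label, bits=bits)
        return CrossRecurrenceResults(self, measures, rm, h_d, h_v, cal)


class CrossRecurrenceResults:
    """Fitted cross-recurrence measures, with the matrix and calibration."""

    def __init__(
        self,
        model: CrossRecurrence,
        measures: CRQAResult,
        matrix: RecurrenceMatrix,
        hist_diag: LineHistogram,
        hist_vert: LineHistogram,
        calibration: RadiusCalibration,
    ) -> None:
        self.model = model
        self.measures = measures
        self.matrix = matrix
        self.hist_diag = hist_diag
        self.hist_vert = hist_vert
        self.calibration = calibration

    def __getattr__(self, name):
        try:
            return getattr(self.__dict__["measures"], name)
        except (KeyError, AttributeError):
            raise AttributeError(name) from None

    def summary(self) -> str:
        m = self.measures
        emb = self.model.embedding
        lines = [
            "Cross-Recurrence Quantification Results",
            "=" * 45,
            f"{'epoch':<28}{m.epoch_label or '-':>17}",
            f"{'points (N x N)':<28}{self.matrix.shape[0]:>8} x {self.matrix.shape[1]}",
            f"{'embedding (m, tau)':<28}{f'({emb.m}, {emb.tau})':>17}",
            f"{'radius (z-units)':<28}{m.radius:>17.4f}",
            f"{'recurrence rate':<28}{m.rr:>16.2%}",
            f"{'%determinism (DET)':<28}{m.det:>16.2%}",
            f"{'%laminarity (LAM)':<28}{m.lam:>16.2%}",
            f"{'mean diagonal line':<28}{m.mean_diag:>17.2f}",
            f"{'mean vertical line':<28}{m.mean_vert:>17.2f}",
            f"{'diag line entropy (nats)':<28}{m.ent_diag:>17.3f}",
            f"{'vert line entropy (nats)':<28}{m.ent_vert:>17.3f}",
            f"{'calibration converged':<28}{str(self.calibration.converged):>17}",
            "=" * 45,
        ]
        return "\n".join(lines)

    def save_pbm(self, path) -> None:
        """Export the recurrence plot as a plain-text PBM (P1) bitmap."""
        r = self.matrix.R.astype(np.uint8)
        with open(path, "w") as fh:
            fh.write(f"P1\n{r.shape[1]} {r.shape[0]}\n")
            for row in r[::-1]:  # PBM is top-to-bottom; plot time upward
                fh.write(" ".join(map(str, row)) + "\n")

    def plot(self, ax=None):
        """Draw the recurrence plot (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 5))
        ax.imshow(self.matrix.R, origin="lower", cmap="Greys", interpolation="none")
        ax.set_xlabel("platform state index")
        ax.set_ylabel("CoM state index")
        ax.set_title(self.measures.epoch_label or "cross-recurrence plot")
        return ax


def crqa_epoch(
    com: TimeSeries,
    platform: TimeSeries,
    params: EmbeddingParams | None = None,
    target_rr: float = 0.025,
    epoch_label: str = "",
    **kwargs,
) -> CRQAResult:
    """One-call pipeline for an epoch: normalize, embed, calibrate, measure.

    Raises :class:`EpochTooShortError` for epochs too short to embed; callers
    looping over epochs should catch it and log the skip.
    """
    if com.n != platform.n:
        raise ValueError("epoch signals must have equal length")
    model = CrossRecurrence(
        com, platform, embedding=params, target_rr=target_rr, label=epoch_label, **kwargs
    )
    return model.fit().measures
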