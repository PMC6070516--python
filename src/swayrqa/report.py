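"""Aggregation across trials and the frequency-condition repeated-measures ANOVA.

Epoch-level cRQA measures are averaged per subject x condition (the paradigm
has 11 moving conditions: six ascending, five descending steps), giving a
complete within-subject table per measure.  A classical one-way
repeated-measures ANOVA then tests the platform-frequency effect, with
df = (k-1, (k-1)(n-1)).  Sphericity corrections are off by default (a
Greenhouse-Geisser option exists).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import Protocol, default_protocol

__all__ = [
    "ConditionTable",
    "RMAnovaResult",
    "condition_order",
    "aggregate_trials",
    "rm_anova",
    "FrequencyEffect",
    "FrequencyEffectResults",
    "MEASURES",
]

#: Epoch-level measures carried through aggregation and testing.
MEASURES = ("rr", "det", "lam", "mean_diag", "mean_vert", "ent_diag", "ent_vert", "radius")


@dataclass(frozen=True)
class ConditionTable:
    """Subject x condition matrix of one measure's trial-averaged values."""

    values: pd.DataFrame  # index: subject, columns: condition labels (ordered)
    measure: str = ""
    n_trials: pd.DataFrame | None = None  # contributing-trial counts per cell

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            bad = [
                (s, c)
                for s in self.values.index
                for c in self.values.columns
                if pd.isna(self.values.loc[s, c])
            ]
            raise ValueError(f"condition table incomplete; missing cells: {bad[:5]}")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_conditions(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class RMAnovaResult:
    """One-way within-subject F test: F(df1, df2) and its p value."""

    F: float
    df1: int
    df2: int
    p: float
    degenerate: bool = False  # zero error variance -> F reported infinite

    def __str__(self) -> str:
        tag = " [degenerate: zero error variance]" if self.degenerate else ""
        return f"F({self.df1}, {self.df2}) = {self.F:.3f}, p = {self.p:.4g}{tag}"


def condition_order(protocol: Protocol | None = None) -> list[str]:
    """The fixed condition ordering: 0.2 up ... 1.2, 1.0 down ... 0.2 down."""
    protocol = protocol or default_protocol()
    return [e.label for e in protocol.moving_epochs()]


def aggregate_trials(
    results: pd.DataFrame,
    measure: str,
    protocol: Protocol | None = None,
) -> ConditionTable:
    """Average a measure across trials into a subject x condition table.

    ``results`` is the tidy epoch-level frame with columns ``subject``,
    ``trial``, ``epoch_label`` and the measure columns.  Every subject must
    contribute at least one trial to every condition; a missing cell is
    reported by name.
    """
    required = {"subject", "trial", "epoch_label", measure}
    missing = required - set(results.columns)
    if missing:
        raise ValueError(f"results frame lacks columns: {sorted(missing)}")
    order = condition_order(protocol)
    sub = results[results["epoch_label"].isin(order)]
    means = sub.pivot_table(index="subject", columns="epoch_label", values=measure,
                            aggfunc="mean")
    counts = sub.pivot_table(index="subject", columns="epoch_label", values=measure,
                             aggfunc="count")
    for lab in order:
        if lab not in means.columns:
            means[lab] = np.nan
            counts[lab] = 0
    means = means[order]
    counts = counts[order].fillna(0).astype(int)
    return ConditionTable(means, measure=measure, n_trials=counts)


def _ss_decomposition(x: np.ndarray) -> tuple[float, float]:
    """(SS_condition, SS_error) of the one-way within-subject decomposition."""
    grand = x.mean()
    ss_cond = x.shape[0] * np.sum((x.mean(axis=0) - grand) ** 2)
    ss_subj = x.shape[1] * np.sum((x.mean(axis=1) - grand) ** 2)
    ss_tot = np.sum((x - grand) ** 2)
    return float(ss_cond), float(ss_tot - ss_cond - ss_subj)


def rm_anova(table: ConditionTable, correction: str = "none") -> RMAnovaResult:
    """One-way repeated-measures ANOVA for the condition effect.

    Uses the classical decomposition (fitted via statsmodels' ``AnovaRM``):
    F = MS_condition / MS_error with df = (k-1, (k-1)(n-1)).
    ``correction='gg'`` applies the Greenhouse-Geisser epsilon to the degrees
    of freedom of the p value (F itself is unchanged).  A table with zero
    error variance yields an infinite F with the ``degenerate`` flag set.
    """
    x = table.values.to_numpy(dtype=float)
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 subjects and 2 conditions")
    if correction not in ("none", "gg"):
        raise ValueError("correction must be 'none' or 'gg'")
    df1, df2 = k - 1, (k - 1) * (n - 1)

    ss_cond, ss_err = _ss_decomposition(x)
    if ss_err <= 1e-12 * max(ss_cond, 1.0):
        return RMAnovaResult(np.inf, df1, df2, 0.0, degenerate=True)

    from statsmodels.stats.anova import AnovaRM

    long = table.values.stack().rename("value").reset_index()
    long.columns = ["subject", "condition", "value"]
    fit = AnovaRM(long, depvar="value", subject="subject", within=["condition"]).fit()
    row = fit.anova_table.iloc[0]
    f_val = float(row["F Value"])
    p = float(row["Pr > F"])

    if correction == "gg":
        from scipy import stats

        eps = _gg_epsilon(x)
        p = float(stats.f.sf(f_val, eps * df1, eps * df2))
    return RMAnovaResult(f_val, df1, df2, p)


def _gg_epsilon(x: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from the condition covariance matrix."""
    k = x.shape[1]
    s = np.cov(x, rowvar=False)
    mean_diag = np.trace(s) / k
    mean_all = s.mean()
    num = (k * (mean_diag - mean_all)) ** 2
    den = (k - 1) * (np.sum(s**2) - 2 * k * np.sum(s.mean(axis=1) ** 2) + k**2 * mean_all**2)
    return float(np.clip(num / den, 1.0 / (k - 1), 1.0)) if den > 0 else 1.0


class FrequencyEffect:
    """Repeated-measures model for the platform-frequency effect on a measure.

    statsmodels-style wrapper: built from the tidy epoch-level results frame
    (or a ready :class:`ConditionTable`); ``fit()`` aggregates across trials
    and runs the within-subject ANOVA for each requested measure.
    """

    def __init__(
        self,
        results: pd.DataFrame,
        measures: tuple[str, ...] = MEASURES,
        protocol: Protocol | None = None,
    ) -> None:
        self.results = results
        self.measures = measures
        self.protocol = protocol

    def fit(self, correction: str = "none") -> "FrequencyEffectResults":
        tables = {m: aggregate_trials(self.results, m, self.protocol) for m in self.measures}
        tests = {m: rm_anova(t, correction=correction) for m, t in tables.items()}
        return FrequencyEffectResults(tables, tests)


class FrequencyEffectResults:
    """Per-measure condition tables and their F tests."""

    def __init__(self, tables: dict, tests: dict) -> None:
        self.tables = tables
        self.tests = tests

    def summary(self) -> str:
        lines = [
            "Platform-frequency effect (one-way repeated-measures ANOVA)",
            "=" * 62,
            f"{'measure':<12}{'F':>12}{'df':>12}{'p':>14}",
            "-" * 62,
        ]
        for m, t in self.tests.items():
            f_str = "inf" if np.isinf(t.F) else f"{t.F:.2f}"
            lines.append(f"{m:<12}{f_str:>12}{f'({t.df1}, {t.df2})':>12}{t.p:>14.4g}")
        lines.append("=" * 62)
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "measure": list(self.tests),
                "F": [t.F for t in self.tests.values()],
                "df1": [t.df1 for t in self.tests.values()],
                "df2": [t.df2 for t in self.tests.values()],
                "p": [t.p for t in self.tests.values()],
                "degenerate": [t.degenerate for t in self.tests.values()],
            }
        )
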