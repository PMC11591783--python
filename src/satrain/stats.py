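"""Validation statistics for SA induction and feature comparisons.

The central check is whether the experimental conditions shifted the
distribution of low vs. high SA trials: an omnibus Pearson chi-square on
the condition x {low, high} contingency table, followed by Yates-corrected
2x2 chi-squares for every condition pair.  Feature-level comparisons use
the Mann-Whitney U test (independent samples, e.g. HRV features of low-
vs high-SA trials) and the Wilcoxon signed-rank test (paired samples,
e.g. per-subject EEG band power under the two SA states).

The contingency statistics are computed from their defining formulas;
scipy provides the reference distributions and the rank tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DataError

__all__ = [
    "ContingencyTable",
    "TestResult",
    "chi_square_omnibus",
    "chi_square_yates",
    "pairwise_condition_tests",
    "mann_whitney_u",
    "wilcoxon_signed_rank",
    "validate_sa_induction",
]


@dataclass(frozen=True)
class TestResult:
    """Outcome of a single hypothesis test."""

    statistic: float
    df: float | None
    p_value: float
    method: str
    correction: bool = False
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "statistic": float(self.statistic),
            "df": None if self.df is None else float(self.df),
            "p_value": float(self.p_value),
            "method": self.method,
            "correction": bool(self.correction),
        }
        d.update({k: (float(v) if np.isscalar(v) else v) for k, v in self.extras.items()})
        return d


@dataclass(frozen=True)
class ContingencyTable:
    """Low/high SA counts per experimental condition (k x 2)."""

    conditions: tuple[str, ...]
    low: tuple[int, ...]
    high: tuple[int, ...]

    def __post_init__(self) -> None:
        if not (len(self.conditions) == len(self.low) == len(self.high)):
            raise DataError("conditions, low and high must have equal length")
        if any(c < 0 for c in self.low) or any(c < 0 for c in self.high):
            raise DataError("counts must be non-negative")

    @classmethod
    def from_counts(cls, counts: Mapping[str, tuple[int, int]]) -> "ContingencyTable":
        """Build from ``{condition: (n_low, n_high)}``."""
        conds = tuple(counts)
        return cls(conds,
                   tuple(int(counts[c][0]) for c in conds),
                   tuple(int(counts[c][1]) for c in conds))

    @classmethod
    def from_labels(cls, labels: pd.DataFrame,
                    condition_col: str = "condition",
                    label_col: str = "sa_label") -> "ContingencyTable":
        """Tally low/high SA labels per condition from a labeled trial table."""
        if condition_col not in labels or label_col not in labels:
            raise DataError(
                f"labels table needs columns {condition_col!r} and {label_col!r}")
        conds = tuple(dict.fromkeys(labels[condition_col]))
        low, high = [], []
        for c in conds:
            sub = labels.loc[labels[condition_col] == c, label_col]
            low.append(int((sub == "low").sum()))
            high.append(int((sub == "high").sum()))
        return cls(conds, tuple(low), tuple(high))

    def counts(self) -> np.ndarray:
        """k x 2 array, columns (low, high)."""
        return np.column_stack([self.low, self.high]).astype(float)

    def row_totals(self) -> np.ndarray:
        return np.asarray(self.low) + np.asarray(self.high)

    @property
    def total(self) -> int:
        return int(self.row_totals().sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"condition": self.conditions, "low_sa": self.low, "high_sa": self.high})


def chi_square_omnibus(table: ContingencyTable) -> TestResult:
    """Pearson chi-square of independence on the k x 2 SA table.

    No continuity correction; df = k - 1.
    """
    obs = table.counts()
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    n = obs.sum()
    if np.any(row == 0) or np.any(col == 0) or n == 0:
        raise DataError("chi-square requires positive marginal totals")
    expected = row @ col / n
    stat = float(((obs - expected) ** 2 / expected).sum())
    df = obs.shape[0] - 1
    p = float(sps.chi2.sf(stat, df))
    return TestResult(stat, df, p, method="pearson-chi2")


def chi_square_yates(a: int, b: int, c: int, d: int) -> TestResult:
    """Yates continuity-corrected chi-square for a 2x2 table [[a, b], [c, d]].

    statistic = n * (max(|ad - bc| - n/2, 0))^2 / ((a+b)(c+d)(a+c)(b+d)),
    clamped at zero when the correction exceeds |ad - bc|.
    """
    for v in (a, b, c, d):
        if v < 0:
            raise DataError("2x2 counts must be non-negative")
    n = a + b + c + d
    margins = [(a + b), (c + d), (a + c), (b + d)]
    if any(m == 0 for m in margins):
        raise DataError("chi-square requires positive marginal totals")
    num = n * max(abs(a * d - b * c) - n / 2.0, 0.0) ** 2
    den = float(np.prod([float(m) for m in margins]))
    stat = num / den
    p = float(sps.chi2.sf(stat, 1))
    return TestResult(stat, 1, p, method="yates-chi2", correction=True)


def pairwise_condition_tests(table: ContingencyTable,
                             bonferroni: bool = True
                             ) -> dict[tuple[str, str], TestResult]:
    """Yates 2x2 tests for every pair of conditions.

    Raw p-values are reported; a Bonferroni-adjusted p (times the number
    of pairs, capped at 1) is attached under ``extras['p_bonferroni']``
    when requested.
    """
    idx = {c: i for i, c in enumerate(table.conditions)}
    pairs = list(combinations(table.conditions, 2))
    out: dict[tuple[str, str], TestResult] = {}
    for c1, c2 in pairs:
        i, j = idx[c1], idx[c2]
        res = chi_square_yates(table.low[i], table.high[i],
                               table.low[j], table.high[j])
        if bonferroni:
            res = TestResult(res.statistic, res.df, res.p_value, res.method,
                             res.correction,
                             {"p_bonferroni": min(1.0, res.p_value * len(pairs))})
        out[(c1, c2)] = res
    return out


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sided Mann-Whitney U test (midranks; ties allowed).

    Exact null distribution for small tie-free samples (both n <= 20),
    otherwise the normal approximation with continuity and tie correction.
    The reported statistic is U for ``x``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise DataError("mann_whitney_u requires two nonempty samples")
    has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    method = "exact" if (max(x.size, y.size) <= 20 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return TestResult(float(res.statistic), None, float(res.pvalue),
                      method=f"mann-whitney-{method}")


def wilcoxon_signed_rank(paired_diffs: Sequence[float]) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped; |d| are midranked; the statistic is
    min(W+, W-).  Exact p for n <= 25 tie-free data, otherwise the normal
    approximation with tie correction.
    """
    d = np.asarray(paired_diffs, dtype=float)
    d = d[d != 0]
    if d.size < 5:
        raise DataError("wilcoxon_signed_rank needs >= 5 nonzero differences")
    has_ties = np.unique(np.abs(d)).size < d.size
    method = "exact" if (d.size <= 25 and not has_ties) else "approx"
    res = sps.wilcoxon(d, alternative="two-sided", method=method)
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    return TestResult(float(min(w_plus, w_minus)), None, float(res.pvalue),
                      method=f"wilcoxon-{method}",
                      extras={"w_plus": w_plus, "w_minus": w_minus, "n": d.size})


def validate_sa_induction(labels: pd.DataFrame | ContingencyTable,
                          bonferroni: bool = True) -> dict:
    """Omnibus + pairwise chi-square report for SA induction.

    Accepts either a labeled trial table (``condition`` / ``sa_label``
    columns) or a ready-made :class:`ContingencyTable`.  Returns a JSON-
    serialisable report; ``report['text']`` holds a human-readable summary.
    """
    table = (labels if isinstance(labels, ContingencyTable)
             else ContingencyTable.from_labels(labels))
    omnibus = chi_square_omnibus(table)
    pairwise = pairwise_condition_tests(table, bonferroni=bonferroni)
    lines = [
        "SA induction validation",
        "  counts: " + ", ".join(
            f"{c}: {lo}/{hi} (low/high)"
            for c, lo, hi in zip(table.conditions, table.low, table.high)),
        f"  omnibus chi2 = {omnibus.statistic:.3f}, df = {omnibus.df:.0f}, "
        f"p = {omnibus.p_value:.3g}",
    ]
    for (c1, c2), r in pairwise.items():
        lines.append(f"  {c1} vs {c2}: chi2 = {r.statistic:.2f}, p = {r.p_value:.3g}")
    return {
        "table": {c: [int(lo), int(hi)] for c, lo, hi
                  in zip(table.conditions, table.low, table.high)},
        "omnibus": omnibus.to_dict(),
        "pairwise": {f"{c1}-{c2}": r.to_dict() for (c1, c2), r in pairwise.items()},
        "text": "\n".join(lines),
    }
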