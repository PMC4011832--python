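"""Set-level statistics: Fisher exact, hypergeometric overlap, Welch t
from summaries, Spearman correlation, and annotation-enrichment wrappers.

The Fisher test is computed by explicit summation over the conditional
hypergeometric distribution (two-sided by the minimum-likelihood rule),
so that an independent enumeration oracle can cross-check it; the
overlap test is an upper-tail inclusive hypergeometric evaluated in log
space.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

from .core_model import AssayPanel, Role
from .copy_number_calling import CallMatrix

__all__ = [
    "ContingencyTable2x2",
    "OverlapSpec",
    "SummaryStats",
    "fisher_exact_2x2",
    "hypergeom_overlap",
    "welch_from_summary",
    "spearman",
    "annotation_enrichment",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts with rows = annotation in/out, columns = expressed/not."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def margins(self) -> tuple[int, int, int, int]:
        return (self.a + self.b, self.c + self.d, self.a + self.c, self.b + self.d)

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


@dataclass(frozen=True)
class OverlapSpec:
    """Overlap of two sets inside a finite universe."""

    universe: int
    set_a: int
    set_b: int
    overlap: int

    def __post_init__(self) -> None:
        lo = max(0, self.set_a + self.set_b - self.universe)
        hi = min(self.set_a, self.set_b)
        if not lo <= self.overlap <= hi:
            raise ValueError(
                f"overlap {self.overlap} infeasible for sizes "
                f"({self.universe}, {self.set_a}, {self.set_b})")


@dataclass(frozen=True)
class SummaryStats:
    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be nonnegative")
        if self.n < 2:
            raise ValueError("n must be >= 2")


def fisher_exact_2x2(
    table: ContingencyTable2x2 | list | np.ndarray,
    alternative: str = "two_sided_min_likelihood",
) -> tuple[float, float]:
    """Fisher exact test on a 2×2 table: returns ``(p, odds_ratio)``.

    With margins fixed, the top-left count follows a hypergeometric
    distribution.  The two-sided p sums the point probabilities of all
    tables no more likely than the observed one (minimum-likelihood
    rule); one-sided alternatives sum the corresponding tail.  The odds
    ratio is ``ad/bc`` (infinite when ``bc = 0`` with ``ad > 0``; NaN
    when both products vanish).
    """
    if not isinstance(table, ContingencyTable2x2):
        (a, b), (c, d) = np.asarray(table, dtype=int)
        table = ContingencyTable2x2(int(a), int(b), int(c), int(d))
    a, b, c, d = table.a, table.b, table.c, table.d
    n = a + b + c + d
    row1, col1 = a + b, a + c
    lo = max(0, row1 + col1 - n)
    hi = min(row1, col1)
    support = np.arange(lo, hi + 1)
    logp = stats.hypergeom.logpmf(support, n, col1, row1)
    obs_logp = logp[a - lo]
    if alternative == "two_sided_min_likelihood":
        take = logp <= obs_logp + 1e-7  # tolerate fp noise at equal likelihood
    elif alternative == "greater":
        take = support >= a
    elif alternative == "less":
        take = support <= a
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    p = float(np.exp(logsumexp(logp[take])))
    p = min(p, 1.0)
    ad, bc = a * d, b * c
    if bc == 0:
        odds = math.inf if ad > 0 else math.nan
    else:
        odds = ad / bc
    return p, odds


def hypergeom_overlap(spec: OverlapSpec) -> float:
    """Upper-tail inclusive overlap p-value: ``P(X >= overlap)`` for
    ``X ~ Hypergeometric(universe, set_a, set_b)``, by stable log-space
    summation."""
    n_, k_, m_, x = spec.universe, spec.set_a, spec.set_b, spec.overlap
    hi = min(k_, m_)
    support = np.arange(x, hi + 1)
    if support.size == 0:
        return 1.0
    logp = stats.hypergeom.logpmf(support, n_, k_, m_)
    return float(min(1.0, np.exp(logsumexp(logp))))


def welch_from_summary(
    g1: SummaryStats, g2: SummaryStats
) -> tuple[float, float, float]:
    """Welch unequal-variance t-test from group summaries.

    Returns ``(t, df, p_two_tailed)`` with Welch–Satterthwaite degrees
    of freedom.  Two zero-variance groups with equal means give
    ``t = 0, p = 1``.
    """
    v1, v2 = g1.sd ** 2 / g1.n, g2.sd ** 2 / g2.n
    se2 = v1 + v2
    if se2 == 0:
        if g1.mean == g2.mean:
            return 0.0, float(g1.n + g2.n - 2), 1.0
        raise ValueError("zero variance in both groups with unequal means")
    t = (g1.mean - g2.mean) / math.sqrt(se2)
    df = se2 ** 2 / (v1 ** 2 / (g1.n - 1) + v2 ** 2 / (g2.n - 1))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return float(t), float(df), min(p, 1.0)


def _rank_avg(v: np.ndarray) -> np.ndarray:
    return stats.rankdata(v, method="average")


def spearman(x, y, exact_max_n: int = 9) -> tuple[float, float]:
    """Spearman rank correlation with average ranks on ties.

    For ``n <= exact_max_n`` (and no ties) the p-value is computed by
    exact enumeration of all rank orderings; otherwise by the usual
    t-approximation.  Constant input flags an undefined correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: correlation undefined")
    rx, ry = _rank_avg(x), _rank_avg(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    has_ties = len(np.unique(x)) < n or len(np.unique(y)) < n
    if n <= exact_max_n and not has_ties:
        ry_c = ry - ry.mean()
        rx_c = rx - rx.mean()
        denom = math.sqrt((rx_c ** 2).sum() * (ry_c ** 2).sum())
        count = total = 0
        for perm in itertools.permutations(rx_c):
            r = float(np.dot(perm, ry_c)) / denom
            total += 1
            if abs(r) >= abs(rho) - 1e-12:
                count += 1
        return rho, count / total
    if abs(rho) >= 1.0:
        return rho, 0.0
    t = rho * math.sqrt((n - 2) / (1 - rho ** 2))
    return rho, 2.0 * float(stats.t.sf(abs(t), n - 2))


#: expressed / non-expressed split of the 52 potentially non-functional
#: ORs — the unique integer pair consistent with the reported group
#: percentages (11.3% of 273 expressed, 25% of 82 non-expressed)
NONFUNCTIONAL_SPLIT = (31, 21)


def deorphanized_contingency(
    copies_mean,
    n_or_total: int = 355,
    n_expressed_total: int = 273,
    cutoff: float = 5.0,
) -> ContingencyTable2x2:
    """Expressed × deorphanized table from per-OR mean copy numbers.

    Calls each deorphanized receptor expressed when its mean copies
    exceed the cutoff, then crosses the calls with the cohort totals.
    Rows are expressed / not, columns deorphanized / not.
    """
    copies_mean = np.asarray(copies_mean, dtype=float)
    n_deorph = len(copies_mean)
    a = int((copies_mean > cutoff).sum())
    c = n_deorph - a
    b = n_expressed_total - a
    d = (n_or_total - n_expressed_total) - c
    return ContingencyTable2x2(a, b, c, d)


def nonfunctional_contingency(
    split: tuple[int, int] = NONFUNCTIONAL_SPLIT,
    n_or_total: int = 355,
    n_expressed_total: int = 273,
) -> ContingencyTable2x2:
    """Expressed × potentially-non-functional table from the fixed split."""
    a, c = split
    b = n_expressed_total - a
    d = (n_or_total - n_expressed_total) - c
    return ContingencyTable2x2(a, b, c, d)


def annotation_enrichment(
    calls: CallMatrix,
    panel: AssayPanel,
    annotation: str,
    copies: pd.DataFrame | None = None,
) -> dict:
    """Enrichment of a panel annotation in the expressed OR set.

    Builds the (annotated in/out) × (expressed/not) table from per-OR
    overall calls, tests it with the two-sided Fisher exact test, and —
    when a copies table is given — compares mean copy numbers between
    annotated and unannotated ORs with a Welch t-test.
    """
    flags = {}
    for a in panel.assays:
        if a.role is not Role.OR_TARGET:
            continue
        if not hasattr(a, annotation):
            raise KeyError(f"annotation {annotation!r} absent from panel")
        flags[a.assay_id] = bool(getattr(a, annotation))
    ors = [o for o in calls.expressed.columns if o in flags]
    if not any(flags[o] for o in ors):
        raise ValueError(f"annotation {annotation!r} has no members among called ORs")
    expressed = calls.overall_expressed()
    a_ = sum(1 for o in ors if flags[o] and expressed[o])
    b_ = sum(1 for o in ors if not flags[o] and expressed[o])
    c_ = sum(1 for o in ors if flags[o] and not expressed[o])
    d_ = sum(1 for o in ors if not flags[o] and not expressed[o])
    # rows = expressed / not, columns = annotated / not (printed layout)
    table = ContingencyTable2x2(a_, b_, c_, d_)
    p, odds = fisher_exact_2x2(table)
    out = {
        "annotation": annotation,
        "table": table,
        "fisher_p": p,
        "odds_ratio": odds,
        "pct_expressed_annotated": 100.0 * a_ / (a_ + b_) if a_ + b_ else 0.0,
        "pct_nonexpressed_annotated": 100.0 * c_ / (c_ + d_) if c_ + d_ else 0.0,
    }
    if copies is not None:
        grp1 = copies.loc[:, [o for o in ors if flags[o]]].mean(axis=0)
        grp2 = copies.loc[:, [o for o in ors if not flags[o]]].mean(axis=0)
        s1 = SummaryStats(float(grp1.mean()), float(grp1.std(ddof=1)), len(grp1))
        s2 = SummaryStats(float(grp2.mean()), float(grp2.std(ddof=1)), len(grp2))
        t, df, pw = welch_from_summary(s1, s2)
        out["copy_comparison"] = {
            "annotated": s1, "others": s2, "t": t, "df": df, "p": pw}
    return out
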