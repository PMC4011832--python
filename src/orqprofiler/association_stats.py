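"""Per-gene and global association of expression with donor covariates.

Continuous covariates (age) score each gene with a Pearson correlation;
binary covariates (sex, current-vs-never smoking) with a moderated
two-sample t in which a small exchangeability constant ``s0`` (a
percentile of the gene-wise standard errors) stabilizes the
denominator.  False-discovery rates come from covariate-label
permutations; a global test compares the observed sum of squared
per-gene scores against its permutation null.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "AssociationResult",
    "GlobalTestResult",
    "gene_scores",
    "sam_fdr",
    "global_association",
    "log2_expression",
]

EXHAUSTIVE_LIMIT = 10_000


@dataclass
class AssociationResult:
    scores: pd.Series       # raw per-gene scores (r or moderated t)
    q_values: pd.Series
    direction: pd.Series    # "up" / "down"
    significant: pd.Series  # boolean at q < q_threshold
    q_threshold: float
    n_permutations: int
    exhaustive: bool
    seed: int | None


@dataclass
class GlobalTestResult:
    statistic: float        # T = sum of squared per-gene scores
    p_value: float
    n_permutations: int
    exhaustive: bool
    seed: int | None


def log2_expression(copies: pd.DataFrame, pseudocount: float = 0.5) -> pd.DataFrame:
    """log2(copies + pseudocount): the working scale for association."""
    return np.log2(copies + pseudocount)


def _pearson_scores(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson r of each column of x against y; zero-variance genes -> 0."""
    xc = x - x.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt((xc ** 2).sum(axis=0))
    sy = np.sqrt((yc ** 2).sum())
    denom = sx * sy
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc * yc[:, None]).sum(axis=0) / denom
    return np.where(denom > 0, r, 0.0)


def _t_scores(x: np.ndarray, groups: np.ndarray, s0: float) -> np.ndarray:
    """Moderated two-sample t with pooled variance per gene.

    ``groups`` is boolean (True = group 1).  Zero-variance genes with
    equal means score 0.
    """
    g1, g2 = x[groups], x[~groups]
    n1, n2 = len(g1), len(g2)
    m1, m2 = g1.mean(axis=0), g2.mean(axis=0)
    ss = ((g1 - m1) ** 2).sum(axis=0) + ((g2 - m2) ** 2).sum(axis=0)
    sp = np.sqrt(ss / (n1 + n2 - 2) * (1 / n1 + 1 / n2))
    denom = sp + s0
    with np.errstate(invalid="ignore", divide="ignore"):
        t = (m1 - m2) / denom
    return np.where(denom > 0, t, 0.0)


def _prepare(expr: pd.DataFrame, covariate: pd.Series):
    cov = covariate.reindex(expr.index)
    keep = cov.notna()
    expr = expr.loc[keep]
    cov = cov.loc[keep]
    if len(expr) < 3:
        raise ValueError("need at least 3 complete samples")
    x = expr.to_numpy(dtype=float)
    if pd.api.types.is_numeric_dtype(cov) and cov.nunique() > 2:
        y = cov.to_numpy(dtype=float)
        if np.ptp(y) == 0:
            raise ValueError("constant covariate")
        return expr.columns, x, y, "continuous"
    levels = sorted(cov.unique())
    if len(levels) != 2:
        raise ValueError(f"binary covariate must have exactly 2 levels, got {levels}")
    groups = (cov == levels[-1]).to_numpy()
    if groups.sum() < 3 or (~groups).sum() < 3:
        raise ValueError("need >= 3 samples per class for a binary covariate")
    return expr.columns, x, groups, "binary"


def _s0_from_data(x: np.ndarray, groups: np.ndarray, percentile: float) -> float:
    g1, g2 = x[groups], x[~groups]
    n1, n2 = len(g1), len(g2)
    ss = ((g1 - g1.mean(axis=0)) ** 2).sum(axis=0) + ((g2 - g2.mean(axis=0)) ** 2).sum(axis=0)
    sp = np.sqrt(ss / (n1 + n2 - 2) * (1 / n1 + 1 / n2))
    return float(np.percentile(sp, percentile))


def gene_scores(
    expr: pd.DataFrame,
    covariate: pd.Series,
    s0: float | None = None,
    s0_percentile: float = 50.0,
) -> pd.Series:
    """Per-gene association scores.

    Continuous covariates yield Pearson r; binary covariates a moderated
    t (``s0`` defaults to the median gene-wise standard error).
    """
    genes, x, y, kind = _prepare(expr, covariate)
    if kind == "continuous":
        return pd.Series(_pearson_scores(x, y), index=genes)
    if s0 is None:
        s0 = _s0_from_data(x, y, s0_percentile)
    return pd.Series(_t_scores(x, y, s0), index=genes)


def _permutations(y, kind: str, B: int, rng: np.random.Generator):
    """Yield permuted covariate vectors; exhaustive when the space is small.

    For binary covariates the space is the set of distinct group
    assignments (combinations); for continuous it is the full set of
    orderings.
    """
    n = len(y)
    if kind == "binary":
        k = int(y.sum())
        total = math.comb(n, k)
        if total <= EXHAUSTIVE_LIMIT:
            perms = []
            for idx in itertools.combinations(range(n), k):
                g = np.zeros(n, dtype=bool)
                g[list(idx)] = True
                perms.append(g)
            return perms, True
        return [rng.permutation(y) for _ in range(B)], False
    total = math.factorial(n)
    if total <= EXHAUSTIVE_LIMIT:
        return [np.asarray(p, dtype=float) for p in itertools.permutations(y)], True
    return [rng.permutation(y) for _ in range(B)], False


def sam_fdr(
    expr: pd.DataFrame,
    covariate: pd.Series,
    B: int = 1000,
    seed: int | None = None,
    q_threshold: float = 0.05,
    s0: float | None = None,
    s0_percentile: float = 50.0,
) -> AssociationResult:
    """Permutation FDR over per-gene association scores.

    The observed scores are ranked by absolute value; for each gene the
    q-value is the median (over permutations) count of null scores at or
    above its absolute score, divided by the number of observed scores
    at or above it, capped at 1 and made monotone non-decreasing with
    decreasing |score|.
    """
    if B < 100:
        raise ValueError("B < 100 gives an unstable FDR estimate")
    genes, x, y, kind = _prepare(expr, covariate)
    rng = np.random.default_rng(seed)
    if kind == "binary" and s0 is None:
        s0 = _s0_from_data(x, y, s0_percentile)

    def score_fn(yy):
        if kind == "continuous":
            return _pearson_scores(x, yy)
        return _t_scores(x, yy, s0)

    obs = score_fn(y)
    abs_obs = np.abs(obs)
    perms, exhaustive = _permutations(y, kind, B, rng)
    # null counts: for each gene, #null |scores| >= |obs_g| per permutation
    order = np.argsort(-abs_obs, kind="stable")
    sorted_abs = abs_obs[order]
    counts = np.empty((len(perms), len(obs)))
    for i, yy in enumerate(perms):
        null_abs = np.sort(np.abs(score_fn(yy)))
        # number of null scores >= threshold t = len - searchsorted_left(t)
        counts[i] = len(null_abs) - np.searchsorted(null_abs, sorted_abs, side="left")
    med_null = np.median(counts, axis=0)
    rank = np.arange(1, len(obs) + 1)  # observed scores >= threshold, in sorted order
    q_sorted = np.minimum(med_null / rank, 1.0)
    q_sorted = np.maximum.accumulate(q_sorted)  # monotone in decreasing |score|
    q = np.empty_like(q_sorted)
    q[order] = q_sorted

    scores = pd.Series(obs, index=genes)
    qv = pd.Series(q, index=genes)
    return AssociationResult(
        scores=scores,
        q_values=qv,
        direction=pd.Series(np.where(obs >= 0, "up", "down"), index=genes),
        significant=qv < q_threshold,
        q_threshold=q_threshold,
        n_permutations=len(perms),
        exhaustive=exhaustive,
        seed=seed,
    )


def global_association(
    expr: pd.DataFrame,
    covariate: pd.Series,
    B: int = 10_000,
    seed: int | None = None,
    s0: float | None = None,
    s0_percentile: float = 50.0,
) -> GlobalTestResult:
    """Global permutation test on T = sum of squared per-gene scores.

    Sampled mode uses the add-one convention ``p = (1 + #{T* >= T_obs})
    / (B + 1)``; exhaustive mode (permutation space <= 10,000) returns
    the exact enumerated fraction.
    """
    genes, x, y, kind = _prepare(expr, covariate)
    rng = np.random.default_rng(seed)
    if kind == "binary" and s0 is None:
        s0 = _s0_from_data(x, y, s0_percentile)

    def t_stat(yy):
        s = _pearson_scores(x, yy) if kind == "continuous" else _t_scores(x, yy, s0)
        return float((s ** 2).sum())

    t_obs = t_stat(y)
    perms, exhaustive = _permutations(y, kind, B, rng)
    n_ge = sum(1 for yy in perms if t_stat(yy) >= t_obs - 1e-12)
    if exhaustive:
        p = n_ge / len(perms)
    else:
        p = (1 + n_ge) / (len(perms) + 1)
    return GlobalTestResult(t_obs, p, len(perms), exhaustive, seed)
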