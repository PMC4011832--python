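"""Relative quantification and two-stage normalization of Cq data.

Cq values are first rescaled to relative quantities (RQ) against a fixed
calibrator cycle, with undetermined wells substituted at 40 cycles.  A
first, *technical* normalization divides by the geometric mean of stably
expressed endogenous reference genes (selected by gene-stability
ranking); a second, *biological* normalization divides by the geometric
mean of six olfactory-epithelium-specific reference genes, absorbing the
variable neuronal content of the dissected mucosa.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_model import CqMatrix

__all__ = [
    "RQTable",
    "StabilityRanking",
    "NormalizationFactors",
    "NRQTable",
    "cq_to_rq",
    "genorm_stability",
    "normalization_factor",
    "normalize_two_stage",
    "DEFAULT_CALIBRATOR_CQ",
    "DEFAULT_TECH_REFS",
    "DEFAULT_BIO_REFS",
]

DEFAULT_CALIBRATOR_CQ = 32.7
DEFAULT_UNDETERMINED_SUBSTITUTE = 40.0

#: stable endogenous trio selected by the stability ranking on the cohort
DEFAULT_TECH_REFS = ("CASC3", "PSMC4", "CDKN1B")
#: olfactory-epithelium-specific reference genes
DEFAULT_BIO_REFS = ("CNGA2", "GNAL", "ADCY3", "RIC8B", "RTP1", "OBP2A2B")


@dataclass
class RQTable:
    """Sample × assay relative quantities: RQ = E^(calibrator − Cq)."""

    values: pd.DataFrame
    calibrator_cq: float
    efficiency: float
    undetermined_substitute: float
    was_undetermined: pd.DataFrame = None  # boolean mask of substituted cells


@dataclass
class StabilityRanking:
    """Gene-stability (M) ranking with pairwise-variation V(n/n+1)."""

    m_values: pd.Series          # M on the full candidate set
    exclusion_order: list[str]   # least stable first
    ranking: list[str]           # most stable first
    v_values: dict               # n -> V(n/n+1)
    recommended_n: int
    v_threshold: float


@dataclass
class NormalizationFactors:
    nf_tech: pd.Series
    nf_bio: pd.Series
    tech_refs: list[str]
    bio_refs: list[str]


@dataclass
class NRQTable:
    """Normalized relative quantities after both stages."""

    values: pd.DataFrame
    factors: NormalizationFactors
    calibrator_cq: float
    efficiency: float
    undetermined_substitute: float
    was_undetermined: pd.DataFrame = None


def cq_to_rq(
    cq: CqMatrix,
    calibrator_cq: float = DEFAULT_CALIBRATOR_CQ,
    efficiency: float = 2.0,
    undetermined_substitute: float = DEFAULT_UNDETERMINED_SUBSTITUTE,
) -> RQTable:
    """Transform Cq into relative quantities.

    UNDETERMINED wells are substituted at ``undetermined_substitute``
    cycles (default 40) before the exponential transform, so every RQ is
    strictly positive.
    """
    if efficiency <= 1:
        raise ValueError("amplification efficiency must exceed 1")
    if calibrator_cq <= 0:
        raise ValueError("calibrator_cq must be positive")
    mask = cq.values.isna()
    filled = cq.values.fillna(undetermined_substitute)
    rq = efficiency ** (calibrator_cq - filled)
    return RQTable(rq, calibrator_cq, efficiency, undetermined_substitute, mask)


def recompute_calibrator(cq: CqMatrix, or_assays: list[str],
                         undetermined_substitute: float = DEFAULT_UNDETERMINED_SUBSTITUTE) -> float:
    """Dataset-specific calibrator: mean OR Cq after the 40-substitution."""
    vals = cq.values.loc[:, or_assays].fillna(undetermined_substitute)
    return float(vals.to_numpy().mean())


def genorm_stability(
    quantities: pd.DataFrame,
    v_threshold: float = 0.15,
) -> StabilityRanking:
    """Rank candidate reference genes by expression stability.

    For genes *j*, *k* the pairwise variation ``V_jk`` is the standard
    deviation across samples of ``log2(q_j/q_k)``; the stability measure
    ``M_j`` is the mean of ``V_jk`` over all other candidates.  Genes
    are excluded iteratively (highest M first, ties broken by column
    order) until two remain.  ``V(n/n+1)`` compares normalization
    factors built from the *n* and *n+1* most stable genes; the
    recommended count is the smallest *n* with ``V < v_threshold``.

    NaN cells (undetermined reference wells) are ignored pairwise.
    """
    genes = list(quantities.columns)
    if len(genes) < 3:
        raise ValueError("stability ranking needs >= 3 candidate genes")
    if len(quantities) < 2:
        raise ValueError("stability ranking needs >= 2 samples")
    q = quantities.to_numpy(dtype=float)
    if np.nanmin(q) <= 0:
        raise ValueError("quantities must be strictly positive")
    logq = np.log2(q)

    def m_values(cols: list[int]) -> np.ndarray:
        sub = logq[:, cols]
        k = len(cols)
        m = np.empty(k)
        for i in range(k):
            vs = []
            for j in range(k):
                if i == j:
                    continue
                diff = sub[:, i] - sub[:, j]
                diff = diff[np.isfinite(diff)]
                if diff.size < 2:
                    raise ValueError("insufficient paired observations for stability")
                vs.append(diff.std(ddof=1))
            m[i] = np.mean(vs)
        return m

    all_cols = list(range(len(genes)))
    full_m = pd.Series(m_values(all_cols), index=genes)

    remaining = all_cols.copy()
    exclusion: list[str] = []
    while len(remaining) > 2:
        m = m_values(remaining)
        worst = int(np.argmax(m))  # argmax takes the first on ties = column order
        exclusion.append(genes[remaining[worst]])
        remaining.pop(worst)
    ranking = [genes[c] for c in remaining] + exclusion[::-1]

    v_values: dict[int, float] = {}
    k = len(genes)
    col_of = {g: i for i, g in enumerate(genes)}
    for n in range(2, k):
        top_n = [col_of[g] for g in ranking[:n]]
        top_n1 = [col_of[g] for g in ranking[:n + 1]]
        nf_n = np.nanmean(logq[:, top_n], axis=1)
        nf_n1 = np.nanmean(logq[:, top_n1], axis=1)
        diff = nf_n - nf_n1
        diff = diff[np.isfinite(diff)]
        v_values[n] = float(diff.std(ddof=1))
    recommended = next((n for n, v in sorted(v_values.items()) if v < v_threshold), k)
    return StabilityRanking(full_m, exclusion, ranking, v_values, recommended, v_threshold)


def normalization_factor(quantities: pd.DataFrame, reference_genes: list[str]) -> pd.Series:
    """Per-sample geometric mean of the listed reference-gene quantities."""
    refs = list(reference_genes)
    if not refs:
        raise ValueError("reference gene list must be nonempty")
    missing = [g for g in refs if g not in quantities.columns]
    if missing:
        raise KeyError(f"reference genes absent from quantities: {missing}")
    sub = quantities.loc[:, refs].to_numpy(dtype=float)
    if np.nanmin(sub) <= 0:
        raise ValueError("reference quantities must be strictly positive")
    return pd.Series(np.exp(np.nanmean(np.log(sub), axis=1)), index=quantities.index)


def normalize_two_stage(
    cq: CqMatrix,
    tech_refs: list[str],
    bio_refs: list[str],
    calibrator_cq: float = DEFAULT_CALIBRATOR_CQ,
    efficiency: float = 2.0,
    undetermined_substitute: float = DEFAULT_UNDETERMINED_SUBSTITUTE,
) -> tuple[NRQTable, NormalizationFactors]:
    """Two-stage normalization of a Cq matrix.

    Stage 1 divides RQ by the geometric mean of the technical reference
    assays; stage 2 divides the result by the geometric mean of the
    (already technically normalized) biological reference assays.  The
    two factors are therefore orthogonal: a global per-sample Cq shift
    cancels in stage 1, and a shift confined to OR + OE-reference genes
    cancels in stage 2.
    """
    for name, refs in (("tech_refs", tech_refs), ("bio_refs", bio_refs)):
        missing = [g for g in refs if g not in cq.values.columns]
        if missing:
            raise KeyError(f"{name} absent from Cq matrix: {missing}")
    rq = cq_to_rq(cq, calibrator_cq, efficiency, undetermined_substitute)
    nf_tech = normalization_factor(rq.values, list(tech_refs))
    q1 = rq.values.div(nf_tech, axis=0)
    nf_bio = normalization_factor(q1, list(bio_refs))
    nrq = q1.div(nf_bio, axis=0)
    factors = NormalizationFactors(nf_tech, nf_bio, list(tech_refs), list(bio_refs))
    return (
        NRQTable(nrq, factors, calibrator_cq, efficiency,
                 undetermined_substitute, rq.was_undetermined),
        factors,
    )
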