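"""Copy-number rescaling, expression calling and repertoire summaries.

Normalized relative quantities are mapped onto an approximate
copies-per-20-ng-RNA scale through a single exponential anchor
(``copies = anchor_copies * 2^(anchor_cq - effective_cq)``).  Three
anchor modes exist: the plasmid pool (~3000 molecules/reaction), the
genomic-DNA card (mass-derived haploid copies) and a configured anchor
pinned so that the 5-copy expression cutoff corresponds to Cq 35.3.
The naive physical anchors land within roughly an order of magnitude of
the configured scale; the configured mode is the default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_model import AssayPanel, CqMatrix, OrClass, Role
from .normalization import NRQTable

__all__ = [
    "CalibrationModel",
    "CopyTable",
    "CallMatrix",
    "TissueRatioTable",
    "fit_calibration",
    "estimate_copies",
    "call_expression",
    "repertoire_summary",
    "class_composition",
    "tissue_ratio",
    "DEFAULT_COPY_CUTOFF",
    "CUTOFF_CQ",
]

DEFAULT_COPY_CUTOFF = 5.0
CUTOFF_CQ = 35.3  # Cq corresponding to the 5-copy cutoff
HAPLOID_GENOME_NG = 0.0033  # mass of one haploid human genome


@dataclass
class CalibrationModel:
    """Exponential Cq→copies anchor (halving per added cycle)."""

    anchor_copies: float
    anchor_cq: float
    source: str  # plasmid | gdna | configured

    def __post_init__(self) -> None:
        if self.anchor_copies <= 0:
            raise ValueError("anchor_copies must be positive")

    def copies_at(self, cq) -> float:
        return self.anchor_copies * 2.0 ** (self.anchor_cq - np.asarray(cq, dtype=float))

    def cq_at(self, copies: float) -> float:
        return self.anchor_cq - np.log2(copies / self.anchor_copies)

    @property
    def copies_at_cutoff_cq(self) -> float:
        """Diagnostic: copies at the 35.3-cycle cutoff Cq."""
        return float(self.copies_at(CUTOFF_CQ))


@dataclass
class CopyTable:
    values: pd.DataFrame   # sample × OR copies per 20 ng RNA
    calibration: CalibrationModel

    def per_or_mean(self) -> pd.Series:
        return self.values.mean(axis=0)

    def per_or_sd(self) -> pd.Series:
        return self.values.std(axis=0, ddof=1)


@dataclass
class CallMatrix:
    expressed: pd.DataFrame  # boolean sample × OR
    cutoff: float
    masked: list[str]
    per_or_mean_copies: pd.Series = None

    @property
    def n_expressing(self) -> pd.Series:
        """Expressing-individual count per OR (column sums)."""
        return self.expressed.sum(axis=0).astype(int)

    @property
    def n_expressed_per_sample(self) -> pd.Series:
        return self.expressed.sum(axis=1).astype(int)

    def overall_expressed(self) -> pd.Series:
        """Per-OR call from the across-sample mean copy number."""
        if self.per_or_mean_copies is None:
            raise ValueError("per-OR mean copies unavailable")
        return self.per_or_mean_copies > self.cutoff


@dataclass
class TissueRatioTable:
    ratios: pd.Series
    enriched: pd.Series
    threshold: float
    n_missing: int


def fit_calibration(
    plasmid_card: CqMatrix | None = None,
    gdna_card: CqMatrix | None = None,
    pool_members: list[str] | None = None,
    intronless_assays: list[str] | None = None,
    mode: str = "configured",
    anchor_copies: float | None = None,
    anchor_cq: float | None = None,
    plasmid_molecules: float = 3000.0,
    gdna_mass_ng: float = 150.0 / 48.0,
    cutoff_copies: float = DEFAULT_COPY_CUTOFF,
) -> CalibrationModel:
    """Fit the Cq→copies anchor.

    ``mode`` selects the anchor source:

    * ``"plasmid"`` — ~3000 plasmid molecules at the mean specific Cq of
      the pool members;
    * ``"gdna"`` — haploid genome copies per reaction mass
      (``gdna_mass_ng / 0.0033``) at the mean intronless Cq;
    * ``"configured"`` — explicit ``(anchor_copies, anchor_cq)``, or by
      default the anchor pinned so ``cutoff_copies`` maps to Cq 35.3.
    """
    if mode == "plasmid":
        if plasmid_card is None or not pool_members:
            raise ValueError("plasmid mode needs a plasmid card and pool members")
        cqs = plasmid_card.values.iloc[0].reindex(pool_members).dropna()
        if cqs.empty:
            raise ValueError("no detected pool members on the plasmid card")
        return CalibrationModel(plasmid_molecules, float(cqs.mean()), "plasmid")
    if mode == "gdna":
        if gdna_card is None:
            raise ValueError("gdna mode needs a gdna card")
        row = gdna_card.values.iloc[0]
        if intronless_assays is not None:
            row = row.reindex(intronless_assays)
        vals = row.dropna()
        if vals.empty:
            raise ValueError("no detected assays on the gdna card")
        return CalibrationModel(gdna_mass_ng / HAPLOID_GENOME_NG, float(vals.mean()), "gdna")
    if mode == "configured":
        if anchor_copies is not None and anchor_cq is not None:
            return CalibrationModel(float(anchor_copies), float(anchor_cq), "configured")
        # pin the anchor so cutoff_copies copies sit exactly at the cutoff Cq
        return CalibrationModel(float(cutoff_copies), CUTOFF_CQ, "configured")
    raise ValueError(f"unknown calibration mode {mode!r}")


def estimate_copies(nrq: NRQTable, calibration: CalibrationModel,
                    or_assays: list[str] | None = None) -> CopyTable:
    """Copies per 20 ng RNA from normalized relative quantities.

    The normalization-adjusted cycle is ``effective_cq = calibrator_cq −
    log2(NRQ)``; copies halve per added cycle from the anchor.
    """
    values = nrq.values if or_assays is None else nrq.values.loc[:, or_assays]
    effective_cq = nrq.calibrator_cq - np.log2(values)
    copies = calibration.anchor_copies * 2.0 ** (calibration.anchor_cq - effective_cq)
    return CopyTable(copies, calibration)


def call_expression(
    copies: CopyTable | pd.DataFrame,
    cutoff: float = DEFAULT_COPY_CUTOFF,
    masked: list[str] | None = None,
) -> CallMatrix:
    """Boolean expression calls at a strict ``copies > cutoff`` rule.

    Masked (QC-excluded) assays are dropped from the call matrix and
    reported separately.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    values = copies.values if isinstance(copies, CopyTable) else copies
    masked = [m for m in (masked or []) if m in values.columns]
    kept = values.drop(columns=masked)
    return CallMatrix(
        expressed=kept > cutoff,
        cutoff=cutoff,
        masked=masked,
        per_or_mean_copies=kept.mean(axis=0),
    )


def repertoire_summary(calls: CallMatrix, sex: pd.Series | None = None) -> dict:
    """Per-sample expressed counts and OR frequency classes.

    Frequency classes over *n* individuals: expressed in all; expressed
    in a majority (at least ``ceil(n/2)`` but not all); rarely expressed
    (fewer than ``ceil(n/2)``).
    """
    if calls.expressed.shape[0] < 1:
        raise ValueError("need at least one sample")
    n = calls.expressed.shape[0]
    half = int(np.ceil(n / 2))
    n_expr = calls.n_expressing
    classes = pd.Series(
        np.where(n_expr == n, "all",
                 np.where(n_expr >= half, "majority", "rare")),
        index=n_expr.index,
    )
    out = {
        "n_samples": n,
        "per_sample_counts": calls.n_expressed_per_sample,
        "frequency_class": classes,
        "class_sizes": {
            "all": int((classes == "all").sum()),
            "majority": int((classes == "majority").sum()),
            "rare": int((classes == "rare").sum()),
        },
        "mean_count": float(calls.n_expressed_per_sample.mean()),
        "sd_count": float(calls.n_expressed_per_sample.std(ddof=1)) if n > 1 else np.nan,
    }
    if sex is not None:
        counts = calls.n_expressed_per_sample
        by_sex = {}
        for s in ("F", "M"):
            sel = counts[sex.reindex(counts.index) == s]
            if len(sel):
                by_sex[s] = {
                    "mean": float(sel.mean()),
                    "sd": float(sel.std(ddof=1)) if len(sel) > 1 else np.nan,
                    "n": int(len(sel)),
                }
        out["by_sex"] = by_sex
    return out


def frequency_classes_from_counts(n_expressing: pd.Series, n_individuals: int) -> dict:
    """Class sizes straight from expressing-individual counts."""
    half = int(np.ceil(n_individuals / 2))
    return {
        "all": int((n_expressing == n_individuals).sum()),
        "majority": int(((n_expressing >= half) & (n_expressing < n_individuals)).sum()),
        "rare": int((n_expressing < half).sum()),
    }


def class_composition(calls: CallMatrix, panel: AssayPanel) -> dict:
    """Class I share among tested vs expressed OR genes."""
    class_of = {a.assay_id: a.or_class for a in panel.assays
                if a.role is Role.OR_TARGET}
    tested = [a for a in calls.expressed.columns if a in class_of]
    expressed = [a for a in tested if calls.overall_expressed().get(a, False)]
    n_tested_i = sum(1 for a in tested if class_of[a] is OrClass.CLASS_I)
    n_expr_i = sum(1 for a in expressed if class_of[a] is OrClass.CLASS_I)
    return {
        "n_tested": len(tested),
        "n_tested_class_I": n_tested_i,
        "pct_tested_class_I": 100.0 * n_tested_i / len(tested) if tested else 0.0,
        "n_expressed": len(expressed),
        "n_expressed_class_I": n_expr_i,
        "pct_expressed_class_I": 100.0 * n_expr_i / len(expressed) if expressed else 0.0,
    }


def tissue_ratio(
    whom_quantities: pd.DataFrame,
    it_quantities: pd.Series,
    enrich_threshold: float = 2.0,
) -> TissueRatioTable:
    """Per-OR ratio of mean WHOM quantity to the inferior-turbinate value.

    Both inputs must be normalized with the technical factor only (the
    biological factor is undefined for respiratory mucosa).  Enrichment
    is inclusive at the threshold (ratio >= 2).
    """
    whom_mean = whom_quantities.mean(axis=0)
    common = whom_mean.index.intersection(it_quantities.index)
    n_missing = len(whom_mean.index.union(it_quantities.index)) - len(common)
    it = it_quantities.reindex(common)
    ratios = whom_mean.reindex(common) / it
    if (it <= 0).any():
        raise ValueError("inferior-turbinate quantities must be positive")
    return TissueRatioTable(ratios, ratios >= enrich_threshold, enrich_threshold, n_missing)
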