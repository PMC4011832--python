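"""Pre-analysis quality control.

Four checks run before any quantification: RT-minus ports summarize
residual genomic-DNA contamination, the genomic-DNA card screens assay
efficacy (and excludes grossly anomalous assays), the plasmid-pool card
classifies assay specificity, and shared samples across runs quantify
run-to-run agreement.  Cq values above 35 cycles are treated as
unreliable throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_model import AssayPanel, CqMatrix, Role

__all__ = [
    "DETECT_THRESHOLD",
    "ContaminationReport",
    "AssayScreenReport",
    "SpecificityReport",
    "InterRunReport",
    "assess_rt_minus",
    "screen_gdna_assays",
    "assess_plasmid_specificity",
    "interrun_calibrate",
]

DETECT_THRESHOLD = 35.0


@dataclass
class ContaminationReport:
    per_sample: pd.DataFrame  # fraction_clean, n_detected, mean_detected_cq, sd_detected_cq, clean
    detect_threshold: float
    clean_bound: float

    @property
    def verdict(self) -> bool:
        return bool(self.per_sample["clean"].all())


@dataclass
class AssayScreenReport:
    per_assay: pd.DataFrame  # gdna_cq, status
    center: float
    spread: float
    k_sd: float

    @property
    def excluded(self) -> list[str]:
        # anomalous-low assays propagate downstream as masked
        return list(self.per_assay.index[self.per_assay["status"] == "anomalous_low"])


@dataclass
class SpecificityReport:
    per_assay: pd.DataFrame  # class, delta_cq, partner
    specific_mean: float

    def class_counts(self) -> dict[str, int]:
        return self.per_assay["class"].value_counts().to_dict()


@dataclass
class InterRunReport:
    pairwise: pd.DataFrame   # run_a, run_b, role_group, slope, intercept, r_squared, n
    offsets: dict            # run -> additive Cq offset vs reference run
    reference_run: str
    detect_threshold: float


def assess_rt_minus(
    rtminus: CqMatrix,
    detect_threshold: float = DETECT_THRESHOLD,
    clean_bound: float = 0.85,
) -> ContaminationReport:
    """Summarize residual genomic-DNA signal on RT-minus ports.

    A well counts as clean when it is UNDETERMINED or its Cq exceeds the
    detection threshold; a sample's verdict is clean when the clean
    fraction reaches ``clean_bound``.
    """
    if rtminus.values.size == 0:
        raise ValueError("empty RT-minus matrix")
    rows = []
    for sample in rtminus.samples:
        v = rtminus.values.loc[sample].to_numpy()
        detected = np.isfinite(v) & (v <= detect_threshold)
        n_det = int(detected.sum())
        frac_clean = 1.0 - n_det / v.size
        rows.append({
            "sample_id": sample,
            "fraction_clean": frac_clean,
            "n_detected": n_det,
            "mean_detected_cq": float(v[detected].mean()) if n_det else np.nan,
            "sd_detected_cq": float(v[detected].std(ddof=1)) if n_det > 1 else np.nan,
            "clean": frac_clean >= clean_bound,
        })
    per_sample = pd.DataFrame(rows).set_index("sample_id")
    return ContaminationReport(per_sample, detect_threshold, clean_bound)


def screen_gdna_assays(
    gdna: CqMatrix,
    panel: AssayPanel,
    k_sd: float = 3.0,
) -> AssayScreenReport:
    """Screen assays against the genomic-DNA card.

    Intronless assays should amplify near the card-wide center (every
    genome carries one target copy per haploid equivalent); an assay
    more than ``k_sd`` robust SDs below the center is anomalous and
    excluded downstream.  Intron-spanning assays are expected to stay
    undetermined; detection is reported but tolerated.
    """
    if len(gdna.samples) != 1:
        raise ValueError("gdna card must contain exactly one pseudo-sample")
    row = gdna.values.iloc[0]
    intronless = [a.assay_id for a in panel.assays
                  if not a.intron_spanning and a.assay_id in row.index]
    vals = row.loc[intronless].dropna()
    if vals.empty:
        raise ValueError("no numeric gdna Cq values to screen against")
    center = float(np.median(vals))
    spread = float(1.4826 * np.median(np.abs(vals - center)))
    if spread == 0.0:
        spread = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
    cut = center - k_sd * spread
    statuses = {}
    for a in panel.assays:
        if a.assay_id not in row.index:
            continue
        cq = row[a.assay_id]
        if a.intron_spanning:
            statuses[a.assay_id] = (
                "expected_undetermined_ok" if np.isnan(cq) else "unexpected_detected")
        elif np.isnan(cq):
            statuses[a.assay_id] = "unexpected_undetermined"
        elif spread > 0 and cq < cut:
            statuses[a.assay_id] = "anomalous_low"
        else:
            statuses[a.assay_id] = "ok"
    per_assay = pd.DataFrame({
        "gdna_cq": row.reindex(list(statuses)),
        "status": pd.Series(statuses),
    })
    return AssayScreenReport(per_assay, center, spread, k_sd)


def assess_plasmid_specificity(
    plasmid: CqMatrix,
    pool_members: list[str],
    indistinct_delta: float = 3.0,
    negligible_delta: float = 6.0,
) -> SpecificityReport:
    """Classify assays by their response to the plasmid pool.

    Pool members are *specific*; a non-member with signal is
    *indistinguishable* when within ``indistinct_delta`` cycles of the
    specific mean, *negligible_cross* when at least ``negligible_delta``
    cycles above it, otherwise *intermediate*; silent assays carry no
    signal.
    """
    if not pool_members:
        raise ValueError("pool_members must be nonempty")
    if len(plasmid.samples) != 1:
        raise ValueError("plasmid card must contain exactly one pseudo-sample")
    row = plasmid.values.iloc[0]
    member_cq = row.reindex(pool_members)
    if member_cq.isna().any():
        import warnings
        missing = list(member_cq.index[member_cq.isna()])
        warnings.warn(f"pool members with no signal excluded from specific mean: {missing}")
    specific_mean = float(member_cq.dropna().mean())
    classes, deltas = {}, {}
    for aid in row.index:
        cq = row[aid]
        if aid in pool_members:
            classes[aid] = "specific"
            deltas[aid] = cq - specific_mean if np.isfinite(cq) else np.nan
        elif np.isnan(cq):
            classes[aid] = "silent"
            deltas[aid] = np.nan
        else:
            d = cq - specific_mean
            deltas[aid] = d
            if d <= indistinct_delta:
                classes[aid] = "indistinguishable"
            elif d >= negligible_delta:
                classes[aid] = "negligible_cross"
            else:
                classes[aid] = "intermediate"
    per_assay = pd.DataFrame({"class": pd.Series(classes), "delta_cq": pd.Series(deltas)})
    return SpecificityReport(per_assay, specific_mean)


def interrun_calibrate(
    runs: CqMatrix,
    shared_sample_ids: list[str],
    panel: AssayPanel | None = None,
    detect_threshold: float = DETECT_THRESHOLD,
) -> InterRunReport:
    """Quantify run-to-run agreement on a shared sample.

    ``runs`` holds one row per (shared sample, run) with distinct run
    labels.  For every run pair, run-B Cq is regressed on run-A Cq over
    assays detected (< threshold) in both, with r² reported per assay
    role group when a panel is given.  Per-run additive offsets (mean
    paired difference vs the first run) are returned for optional
    application before normalization.
    """
    sub = runs.subset_samples(shared_sample_ids)
    run_labels = list(dict.fromkeys(sub.run_id))
    if len(run_labels) < 2:
        raise ValueError("shared sample must be measured in >= 2 runs")
    by_run = {r: sub.values[sub.run_id == r].mean(axis=0) for r in run_labels}

    role_of = None
    if panel is not None:
        role_of = {a.assay_id: a.role.value for a in panel.assays}

    rows = []
    ref = run_labels[0]
    offsets = {ref: 0.0}
    for i, ra in enumerate(run_labels):
        for rb in run_labels[i + 1:]:
            a, b = by_run[ra], by_run[rb]
            ok = a.notna() & b.notna() & (a < detect_threshold) & (b < detect_threshold)
            groups = {"all": ok}
            if role_of is not None:
                for role in ("or_target", "endogenous_ref", "oe_ref"):
                    groups[role] = ok & pd.Series(
                        [role_of.get(c) == role for c in a.index], index=a.index)
            for gname, gmask in groups.items():
                x, y = a[gmask].to_numpy(), b[gmask].to_numpy()
                if x.size < 3:
                    if gname == "all":
                        raise ValueError(
                            f"<3 shared detected assays between {ra} and {rb}")
                    continue
                slope, intercept = np.polyfit(x, y, 1)
                r = np.corrcoef(x, y)[0, 1]
                rows.append({
                    "run_a": ra, "run_b": rb, "role_group": gname,
                    "slope": float(slope), "intercept": float(intercept),
                    "r_squared": float(r * r), "n": int(x.size),
                })
            if ra == ref:
                both = a.notna() & b.notna() & (a < detect_threshold) & (b < detect_threshold)
                offsets[rb] = float((b[both] - a[both]).mean())
    return InterRunReport(pd.DataFrame(rows), offsets, ref, detect_threshold)


def apply_run_offsets(cq: CqMatrix, offsets: dict) -> CqMatrix:
    """Subtract per-run additive offsets from every sample's Cq."""
    values = cq.values.copy()
    for sample in cq.samples:
        off = offsets.get(cq.run_id[sample], 0.0)
        values.loc[sample] = values.loc[sample] - off
    return CqMatrix(values, cq.run_id.copy(), cq.condition.copy())
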