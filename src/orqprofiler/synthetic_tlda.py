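"""Synthetic TLDA cohorts, calibration cards and RT-minus ports.

The generative model mirrors the structure the downstream normalization
assumes: every gene of a sample shares a technical loading shift, while
OR targets and olfactory-epithelium reference genes additionally share a
neuron-fraction shift (olfactory tissue is patchy, so the neuronal
content varies between donors).  Covariate effects can be planted on
named genes for power/recovery studies, and the full latent state is
returned as ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_model import AssayPanel, CqMatrix, Role, load_default_panel

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "generate_cohort",
    "generate_gdna_card",
    "generate_plasmid_card",
    "generate_rt_minus",
]

# Per-gene (mean, sd) Cq of the endogenous reference assays, matching the
# printed cohort summaries.
DEFAULT_ENDOGENOUS_PARAMS: dict[str, tuple[float, float]] = {
    "UBC": (17.1, 0.7),
    "GAPDH": (17.6, 0.5),
    "PPIA": (18.0, 0.6),
    "CDKN1B": (20.0, 0.6),
    "CASC3": (20.4, 0.6),
    "PSMC4": (21.5, 0.7),
    "POLR2A": (21.7, 0.6),
    "YWHAZ": (22.1, 0.8),
    "RPL30": (22.6, 0.9),
    "MRPL19": (22.8, 3.6),
    "TBP": (24.0, 0.6),
}

# Only the endpoints of the OE-reference Cq range are printed; the four
# intermediate genes are spaced evenly between them.
DEFAULT_OE_PARAMS: dict[str, tuple[float, float]] = {
    "ADCY3": (21.3, 0.8),
    "CNGA2": (23.16, 0.86),
    "GNAL": (25.02, 0.92),
    "RIC8B": (26.88, 0.98),
    "RTP1": (28.74, 1.04),
    "OBP2A2B": (30.6, 1.1),
}

SMOKING_STATES = ("never", "current", "past", "unknown")
# cohort-table frequencies: 12 never, 8 current, 2 past, 4 unknown of 26
SMOKING_PROBS = (12 / 26, 8 / 26, 2 / 26, 4 / 26)


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic cohort generator.

    Defaults reproduce the printed distributional summaries: OR Cq range
    25.8-39.8, ~62 +/- 29 undetermined OR wells per sample, gDNA card at
    24.5 +/- 0.8, plasmid pool at 25.4 +/- 1.1 with negligible
    cross-reaction at 32.5 +/- 1.8, RT-minus detections at 34.1 +/- 1.1
    in ~10% of wells.
    """

    n_samples: int = 26
    calibrator_cq: float = 32.7
    max_cycles: float = 40.0
    endogenous_ref_params: dict = field(
        default_factory=lambda: dict(DEFAULT_ENDOGENOUS_PARAMS))
    oe_ref_params: dict = field(default_factory=lambda: dict(DEFAULT_OE_PARAMS))
    or_cq_range: tuple[float, float] = (25.8, 39.8)
    or_noise_sd: float = 0.5
    or_dropout_rate: float = 0.16
    neuron_fraction_sd: float = 1.0
    technical_loading_sd: float = 0.3
    run_offsets: dict = field(default_factory=lambda: {"run1": 0.0, "run2": 0.0, "run3": 0.0})
    age_effect_genes: list = field(default_factory=list)   # (gene, slope cycles/year)
    binary_effect_genes: list = field(default_factory=list)  # (gene, covariate, delta)
    age_range: tuple[float, float] = (39.0, 81.0)
    expressed_cq_threshold: float = 35.3
    gdna_cq_params: tuple[float, float] = (24.5, 0.8)
    plasmid_specific_params: tuple[float, float] = (25.4, 1.1)
    plasmid_cross_params: tuple[float, float] = (32.5, 1.8)
    plasmid_indistinct_params: tuple[float, float] = (25.0, 0.8)
    rtminus_detect_rate: float = 0.10
    rtminus_cq_params: tuple[float, float] = (34.1, 1.1)

    def __post_init__(self) -> None:
        for name in ("or_noise_sd", "neuron_fraction_sd", "technical_loading_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        lo, hi = self.or_cq_range
        if not lo < hi:
            raise ValueError("or_cq_range must satisfy low < high")
        if not 0 <= self.or_dropout_rate <= 1:
            raise ValueError("or_dropout_rate must be a probability")


@dataclass
class GroundTruth:
    """Latent state behind a generated cohort, for recovery tests."""

    sample_factors: pd.DataFrame   # neuron_shift, technical_loading, run_id + covariates
    gene_baselines: pd.Series      # true baseline Cq per assay
    true_cq: pd.DataFrame          # noiseless-dropout true Cq per cell
    true_expressed: pd.DataFrame   # boolean, OR assays only
    planted_age_effects: dict
    planted_binary_effects: list


def _ref_assay_map(panel: AssayPanel) -> dict[str, str]:
    """gene symbol -> assay_id for reference/control assays."""
    return {a.gene_symbol: a.assay_id for a in panel.assays
            if a.role is not Role.OR_TARGET}


def generate_cohort(
    config: GeneratorConfig,
    seed: int,
    panel: AssayPanel | None = None,
) -> tuple[CqMatrix, pd.DataFrame, GroundTruth]:
    """Simulate a WHOM cohort on the given panel.

    Per cell: ``Cq = baseline + covariate effects + technical_loading +
    neuron_shift (OR and OE-reference genes) + run_offset + noise``; a
    cell becomes UNDETERMINED when its Cq exceeds ``max_cycles`` or an
    independent dropout fires (OR targets only).
    """
    if config.n_samples < 2:
        raise ValueError("need at least 2 samples (association stages undefined)")
    panel = panel or load_default_panel()
    rng = np.random.default_rng(seed)

    samples = [f"S{i + 1:02d}" for i in range(config.n_samples)]
    n = config.n_samples

    ages = np.round(rng.uniform(*config.age_range, size=n), 0)
    sexes = np.array(["F", "M"] * ((n + 1) // 2))[:n]
    smoking = rng.choice(SMOKING_STATES, size=n, p=SMOKING_PROBS)
    run_names = sorted(config.run_offsets) or ["run1"]
    run_ids = np.array([run_names[i % len(run_names)] for i in range(n)])

    tech = rng.normal(0.0, config.technical_loading_sd, size=n)
    neuron = rng.normal(0.0, config.neuron_fraction_sd, size=n)

    assay_ids = panel.assay_ids
    baselines = {}
    noise_sds = {}
    neuron_linked = {}
    ref_params = {**config.endogenous_ref_params,
                  **{"GAPDH": config.endogenous_ref_params.get(
                      "GAPDH", DEFAULT_ENDOGENOUS_PARAMS["GAPDH"])}}
    for a in panel.assays:
        if a.role is Role.OR_TARGET:
            baselines[a.assay_id] = rng.uniform(*config.or_cq_range)
            noise_sds[a.assay_id] = config.or_noise_sd
            neuron_linked[a.assay_id] = True
        elif a.role is Role.OE_REF:
            mu, sd = config.oe_ref_params.get(a.gene_symbol, (26.0, 0.9))
            baselines[a.assay_id] = mu
            noise_sds[a.assay_id] = sd
            neuron_linked[a.assay_id] = True
        else:
            mu, sd = ref_params.get(a.gene_symbol, (20.0, 0.6))
            baselines[a.assay_id] = mu
            noise_sds[a.assay_id] = sd
            neuron_linked[a.assay_id] = False

    gene_to_assay = panel.gene_to_assay()
    age_fx = {}
    for gene, slope in config.age_effect_genes:
        age_fx[gene_to_assay.get(gene, gene)] = float(slope)
    bin_fx = []
    for gene, covariate, delta in config.binary_effect_genes:
        bin_fx.append((gene_to_assay.get(gene, gene), covariate, float(delta)))

    base = np.array([baselines[a] for a in assay_ids])
    sds = np.array([noise_sds[a] for a in assay_ids])
    linked = np.array([neuron_linked[a] for a in assay_ids])
    offsets = np.array([config.run_offsets.get(r, 0.0) for r in run_ids])

    true_cq = np.tile(base, (n, 1))
    true_cq += tech[:, None]
    true_cq += np.where(linked[None, :], neuron[:, None], 0.0)
    true_cq += offsets[:, None]
    age_centered = ages - ages.mean()
    for aid, slope in age_fx.items():
        j = assay_ids.index(aid)
        true_cq[:, j] += slope * age_centered
    for aid, covariate, delta in bin_fx:
        j = assay_ids.index(aid)
        if covariate == "sex":
            mask = sexes == "M"
        elif covariate == "smoking":
            mask = smoking == "current"
        else:
            raise ValueError(f"unknown covariate {covariate!r}")
        true_cq[:, j] += np.where(mask, delta, 0.0)

    noise = rng.normal(0.0, 1.0, size=true_cq.shape) * sds[None, :]
    observed = true_cq + noise

    is_or = np.array([panel[a].role is Role.OR_TARGET for a in assay_ids])
    dropout = rng.random(observed.shape) < config.or_dropout_rate
    undet = (observed > config.max_cycles) | (dropout & is_or[None, :])
    observed = np.where(undet, np.nan, np.clip(observed, 1e-6, config.max_cycles))

    values = pd.DataFrame(observed, index=samples, columns=assay_ids)
    cq = CqMatrix(values,
                  pd.Series(run_ids, index=samples),
                  pd.Series("whom", index=samples))

    sample_table = pd.DataFrame({
        "age": ages, "sex": sexes, "smoking": smoking, "run_id": run_ids,
    }, index=samples)

    or_ids = [a for a, flag in zip(assay_ids, is_or) if flag]
    truth = GroundTruth(
        sample_factors=pd.DataFrame({
            "neuron_shift": neuron, "technical_loading": tech, "run_id": run_ids,
            "age": ages, "sex": sexes, "smoking": smoking,
        }, index=samples),
        gene_baselines=pd.Series(base, index=assay_ids),
        true_cq=pd.DataFrame(true_cq, index=samples, columns=assay_ids),
        true_expressed=pd.DataFrame(
            true_cq[:, is_or] < config.expressed_cq_threshold,
            index=samples, columns=or_ids),
        planted_age_effects=dict(age_fx),
        planted_binary_effects=list(bin_fx),
    )
    return cq, sample_table, truth


def generate_gdna_card(
    config: GeneratorConfig,
    seed: int,
    panel: AssayPanel | None = None,
    anomaly: tuple[str, float] | None = None,
) -> CqMatrix:
    """One pseudo-sample run on pooled genomic DNA.

    Intronless assays amplify at ``gdna_cq_params``; intron-spanning
    assays stay UNDETERMINED.  ``anomaly=(assay_id, cq)`` plants a
    mis-behaving assay at a fixed Cq.
    """
    panel = panel or load_default_panel()
    rng = np.random.default_rng(seed)
    mu, sd = config.gdna_cq_params
    vals = {}
    for a in panel.assays:
        vals[a.assay_id] = np.nan if a.intron_spanning else rng.normal(mu, sd)
    if anomaly is not None:
        aid, cqv = anomaly
        if aid not in panel:
            raise KeyError(f"anomaly assay {aid!r} not in panel")
        vals[aid] = float(cqv)
    values = pd.DataFrame([vals], index=["gdna_pool"]).loc[:, panel.assay_ids]
    return CqMatrix(values,
                    pd.Series({"gdna_pool": "gdna_run"}),
                    pd.Series({"gdna_pool": "gdna"}))


def generate_plasmid_card(
    pool_members: list[str],
    config: GeneratorConfig,
    seed: int,
    panel: AssayPanel | None = None,
    cross_reactors: list[str] | None = None,
    indistinct_partners: list[str] | None = None,
) -> CqMatrix:
    """One pseudo-sample run on a pool of OR coding plasmids.

    Pooled targets amplify at the specific level, declared negligible
    cross-reactors ~7 cycles later, declared indistinguishable partners
    at the specific level, and everything else stays UNDETERMINED.
    """
    panel = panel or load_default_panel()
    for m in pool_members:
        if m not in panel:
            raise KeyError(f"pool member {m!r} not in panel")
    rng = np.random.default_rng(seed)
    cross = set(cross_reactors or [])
    indist = set(indistinct_partners or [])
    vals = {}
    for a in panel.assays:
        if a.assay_id in pool_members:
            vals[a.assay_id] = rng.normal(*config.plasmid_specific_params)
        elif a.assay_id in indist:
            vals[a.assay_id] = rng.normal(*config.plasmid_indistinct_params)
        elif a.assay_id in cross:
            vals[a.assay_id] = rng.normal(*config.plasmid_cross_params)
        else:
            vals[a.assay_id] = np.nan
    values = pd.DataFrame([vals], index=["plasmid_pool"]).loc[:, panel.assay_ids]
    values = values.clip(upper=config.max_cycles)
    return CqMatrix(values,
                    pd.Series({"plasmid_pool": "plasmid_run"}),
                    pd.Series({"plasmid_pool": "plasmid"}))


def generate_rt_minus(
    config: GeneratorConfig,
    seed: int,
    panel: AssayPanel | None = None,
    sample_id: str = "rtminus_1",
) -> CqMatrix:
    """A reverse-transcriptase-free port: sporadic low-level detection."""
    panel = panel or load_default_panel()
    rng = np.random.default_rng(seed)
    mu, sd = config.rtminus_cq_params
    detected = rng.random(len(panel)) < config.rtminus_detect_rate
    cqs = rng.normal(mu, sd, size=len(panel))
    vals = np.where(detected, np.clip(cqs, 1e-6, config.max_cycles), np.nan)
    values = pd.DataFrame([vals], index=[sample_id], columns=panel.assay_ids)
    return CqMatrix(values,
                    pd.Series({sample_id: "rtminus_run"}),
                    pd.Series({sample_id: "rt_minus"}))
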