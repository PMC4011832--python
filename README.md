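# orqprofiler

Olfactory-receptor expression profiling from TaqMan Low Density Array
(TLDA) qRT-PCR data. The package covers the full analysis path for a
384-assay card (356 OR targets, 10 endogenous reference genes, 6
olfactory-epithelium-specific reference genes, GAPDH control) run on a
cohort of whole-human-olfactory-mucosa samples:

- **core_model** — domain types (`CqMatrix`, `AssayPanel`, ...), lossless
  wide/long Cq I/O with an explicit UNDETERMINED sentinel, and packaged
  fixtures (default panel, 26-donor cohort metadata, the 47-receptor
  deorphanized table).
- **synthetic_tlda** — a seeded generator for cohorts, genomic-DNA and
  plasmid calibration cards and RT-minus ports, with latent
  technical-loading and neuron-fraction factors and plantable covariate
  effects (full ground truth returned for recovery tests).
- **qc_calibration** — RT-minus contamination summaries, genomic-DNA
  assay screening (anomalously low assays are excluded downstream),
  plasmid specificity classification, and inter-run calibration.
- **normalization** — relative quantities `E^(calibrator − Cq)` with the
  40-cycle substitution for undetermined wells, gene-stability ranking
  (M values, pairwise variation V(n/n+1)) for reference selection, and
  the two-stage normalization: endogenous (technical) factor followed by
  the olfactory-epithelium (biological) factor. NRQ is exactly invariant
  to per-sample global Cq shifts and to joint OR + OE-reference shifts.
- **copy_number_calling** — Cq→copies-per-20-ng-RNA anchoring (plasmid,
  genomic-DNA or configured mode; the default pins 5 copies to Cq 35.3),
  strict >5-copy expression calls, repertoire summaries (frequency
  classes, per-sex counts), class I/II composition, WHOM/inferior-
  turbinate enrichment ratios.
- **association_stats** — per-gene Pearson (age) or moderated-t
  (sex/smoking) scores, permutation FDR q-values with exhaustive
  enumeration for small designs, and the global sum-of-squared-scores
  permutation test.
- **enrichment_compare** — Fisher exact 2×2 (minimum-likelihood
  two-sided rule via explicit hypergeometric summation), upper-tail
  hypergeometric overlap, Welch t from summary statistics, Spearman
  correlation (exact for small n), and annotation-enrichment wrappers.
- **cli** — a `PipelineConfig`-driven orchestration of
  qc → normalize → call → associate → enrich with config-hash-stamped,
  byte-deterministic output bundles.

## CLI

Stages run from a single YAML config; a `generator:` block replaces file
inputs with a synthetic cohort:

```yaml
# cfg.yaml
generator:
  n_samples: 26
output_dir: orq_out
n_permutations: 1000
seed: 7
```

```bash
orqprofiler run --config cfg.yaml --seed 7
orqprofiler qc --config cfg.yaml          # individual stage views
orqprofiler --help
```

For real data, set `cq_path` (wide or long CSV/TSV; "Undetermined",
"NA" and empty cells are undetermined), optional `panel_path` and
`samples_path` instead of the generator block. Outputs (NRQ,
normalization factors, copies, calls, association and enrichment
tables, JSON summaries) are written under `output_dir`, each stamped
with the config hash and seed; identical (config, seed) runs are
byte-identical.

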