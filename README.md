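# myelomap

Single-cell multiome (RNA + ATAC) analysis toolkit for plasma-cell
malignancies. It covers the full arc of a myeloma multiome study:

- **QC and contaminant removal** — per-cell count/feature/mitochondrial
  filters, then iterative removal of clusters whose marker-gene
  (SDC1/CD138 analog) percentile cell is silent.
- **Joint clustering** — per-modality log-CP10K normalization, PCA, and
  SNN/Leiden clustering on a fused RNA+ATAC graph (equal or
  WNN-style cell-specific modality weights).
- **Expression-based CNV inference** — inferCNV-style smoothed
  log-ratio profiles against a diploid reference cluster, arm-level
  gain/amp/loss calls, clone assignment, and per-patient imputation of
  translocations (marker overexpression) and hyperdiploidy.
- **Cluster–phenotype association** — per-patient cluster proportions
  tested across disease stages (rank-sum, pairwise contrasts, BH).
- **Differential expression / accessibility** — Wilcoxon rank-sum with
  an exact small-sample path, fold-change and FDR cutoffs, ATAC
  gene-activity aggregation, and signature intersection with Fisher
  overlap tests.
- **TF regulation** — TF→target database cross-referencing, filtering
  to a genomic region of interest, and promoter ChIP-peak percentile
  ranking.
- **Synthetic cohorts** — a generator that plants all of the above
  structure (populations, clones, events, regulatory program) with
  per-cell ground truth, used by the benchmark suite.

Everything is deterministic: a fixed config and seed reproduce
byte-identical TSV outputs.

## Quickstart

Run the whole pipeline on a simulated cohort:

```python
from myelomap import run_pipeline

result = run_pipeline({}, outdir="out", seed=0)
```

which prints per-stage progress and leaves 15 TSVs in `out/`. On the
default 12-patient cohort this takes about 15 seconds and recovers the
planted structure:

```text
cells after QC + contaminant removal: 4231
joint clusters: 6
top stage-associated cluster: 4
rare-cell recall in top cluster:  1.00
rare-cell purity of top cluster:  0.99
imputed translocations: P04 -> CCND1, P11 -> NSD2
hyperdiploid patients: ['P03']
TF candidates on the event arm: ['PBX1', 'USF1']
best promoter ChIP peak percentile: top 4.0%
```

(Verbatim output of `python examples/02_full_pipeline.py`; all calls
match the generator's planted truth.)

Or from the command line:

```bash
myelomap simulate --out cohort/ --seed 0        # write a synthetic cohort
myelomap run --in cohort/ --out results/ --seed 0
myelomap run --config my_config.yaml --out results/
```

The config file is YAML overlaying the defaults in
`myelomap.pipeline.DEFAULT_CONFIG`, e.g.:

```yaml
cluster:
  resolution: 0.8
  fusion: wnn
cnv:
  window: 51
```

## Examples

Narrative scripts in `examples/`:

1. `01_simulate_cohort.py` — generate a cohort and inspect its planted
   ground truth.
2. `02_full_pipeline.py` — run the full pipeline and compare results to
   the truth.
3. `03_step_by_step.py` — drive every stage manually through the
   library API.

## Testing and reproduction

```bash
pytest -q                     # full suite, incl. acceptance criteria
python scripts/acceptance.py --seed 0 --out acceptance.json
```

`scripts/acceptance.py` recomputes the headline benchmark numbers
(oracle agreement of the statistical primitives, contaminant-removal
sensitivity/specificity, planted-DE recovery and permutation-null
calibration, CNV dosage/clone recovery, stage-association power and
type-I rate, end-to-end recovery, rerun determinism) from scratch and
writes them as JSON.

## Methods

See [docs/methods.md](docs/methods.md) for the statistical model behind
each stage, parameter defaults and their rationale, and the known
attenuation effects of the log-CP10K transform on fold-change and CNV
amplitude estimates.
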