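# lrxtalk

Ligand–receptor crosstalk screening between tumor cells and macrophages from
coupled single-cell and bulk transcriptomes.

The package implements a reusable pipeline for:

- **Synthetic cohorts** (`lrxtalk.synthetic_data`) — coupled single-cell,
  bulk and survival cohorts with planted marker genes, concordant
  ligand–receptor differential expression, copula-planted Spearman
  correlations and prognostic gene effects, plus a ground-truth manifest so
  every downstream stage is testable by parameter recovery.
- **I/O** (`lrxtalk.io_core`) — 10x-style MTX triplet and dense TSV count
  matrices, ligand–receptor pair tables, bulk expression matrices, survival
  tables; typed validation errors throughout.
- **Preprocessing and annotation** (`lrxtalk.preprocess_annotate`) —
  library-size log-normalization, highly-variable-gene selection, PCA
  embedding, k-means clustering and marker-score cell-type annotation, with
  composition summaries and macrophage subclustering.
- **Hurdle differential expression** (`lrxtalk.hurdle_de`) — a two-part
  (detection + continuous) likelihood-ratio test per gene with
  Benjamini–Hochberg correction and up/down direction calls.
- **Ligand–receptor screening** (`lrxtalk.lr_screen`) — concordant autocrine
  pair selection, cross-population paracrine pair selection, bulk Spearman
  coexpression filtering (signed rho > 0.3 by default, `--abs-rho` optional)
  and crosstalk-network/hub construction.
- **Gene-set scoring** (`lrxtalk.signatures`) — module z-scores, pathway
  contrasts (Welch test with BH correction), M1/M2 and pro-/anti-inflammatory
  polarization coordinates, permutation-null interaction scores and
  hypergeometric over-representation.
- **Survival and risk modeling** (`lrxtalk.survival_ml`) — Kaplan–Meier
  curves, log-rank tests, per-gene median-split prognostic screening, and a
  stage-label (I–II vs III–IV) gradient-boosted risk classifier with a
  stratified 2:1 split and external-cohort validation.

## CLI

Stages chain through TSV files (counts as an MTX triplet):

```bash
lrxtalk simulate --config sim.yaml --out simdir
lrxtalk annotate --counts simdir/counts --markers markers.tsv --out ann.tsv
lrxtalk de --counts simdir/counts --groups simdir/annotation.tsv \
    --contrast tumor_cells:epithelial --out de_tumor.tsv
lrxtalk screen --de-tumor de_tumor.tsv --de-mac de_mac.tsv \
    --pairs lr_pairs.tsv --bulk simdir/bulk.tsv --out pairs.tsv
lrxtalk score --counts simdir/counts --groups simdir/annotation.tsv \
    --contrast tumor_cells:epithelial --sets hallmark.gmt --out pathways.tsv
lrxtalk survival --bulk simdir/bulk.tsv --surv simdir/survival.tsv \
    --genes genes.txt --out prognostic.tsv
lrxtalk model train --bulk bulk.tsv --surv surv.tsv --genes genes.txt --out model.pkl
lrxtalk model validate --model model.pkl --bulk bulk_ext.tsv --surv surv_ext.tsv
```

`lrxtalk screen` also writes a hub table (`*.hubs.tsv`) and a GraphML export
of the crosstalk network next to the pair table.

A `sim.yaml` looks like:

```yaml
n_genes: 800
populations:
  - {name: tumor_cells, n_cells: 200, sample_type: tumor}
  - {name: epithelial, n_cells: 200, sample_type: normal}
n_de_lr_pairs_up: 10
n_de_lr_pairs_down: 10
de_fc: 4.0
n_bulk_samples: 500
planted_rho: 0.5
seed: 11
```

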