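# ipmndsp

Analysis pipeline for targeted digital spatial RNA profiling of pancreatic
cyst (IPMN) epithelium. Intraductal papillary mucinous neoplasms harbor a
mosaic of epithelial subtypes — pancreaticobiliary (PB), intestinal (INT)
and gastric foveolar (GF) — each occurring with low- or high-grade dysplasia
(LGD / HGD). GeoMx-style segmented profiling measures each pathologist-drawn
epithelial area of interest (AOI) as one expression sample through a panel of
barcoded probes (several probes per gene plus negative-control probes with
no transcript target). This package implements the complete downstream
analysis from the exported probe-count matrix: quality control, probe
collapsing, normalization, differential-expression signatures, gene-set
enrichment, and a permutation-calibrated coexpression network — together
with a synthetic probe-count generator so every stage can be benchmarked
against planted ground truth.

It is aimed at computational biologists analyzing segmented spatial
transcriptomics of heterogeneous lesions, and at anyone who wants a tested,
reusable reference implementation of this analysis design.

## Methods at a glance

- **QC.** Per AOI, the signal-to-noise ROC AUC (snAUC) separates gene-probe
  counts from negative-probe counts (equivalently, the Mann–Whitney U
  statistic over all probe pairs, ties counted ½). The limit of detection
  (LOD) is the 90th percentile of that AOI's negative-probe counts; a count
  below the LOD is undetectable. AOIs are kept when total counts
  > 100,000 and snAUC > 0.65; gene probes undetected in > 80% of AOIs are
  dropped; surviving probes collapse to one value per gene by geometric
  mean; genes detected in ≥ 20% of AOIs are retained.
- **Normalization.** Per AOI: subtract the geometric mean of negative-probe
  counts (background), scale to counts per million, quantile-normalize
  across AOIs, then log₂(x + 1).
- **Differential expression.** Per-gene two-group OLS on log₂ expression
  with empirical-Bayes variance moderation (the scaled-F hierarchical model
  with moment-matched prior df and scale; cross-checked against limma's
  eBayes). Significance: |log₂FC| > 1 and BH-adjusted P < 0.05.
  Subtype-specific signatures are intersections of the pairwise contrasts
  (PB vs GF, PB vs INT, INT vs GF); the pooled HGD-vs-LGD contrast defines
  the high-grade signature.
- **Enrichment.** Preranked GSEA on log₂FC-ranked lists (weighted
  Kolmogorov–Smirnov running sum, weight exponent 1; random-gene-set null,
  enumerated exhaustively on small universes) and upper-tail hypergeometric
  over-representation for gene clusters.
- **Network.** Spearman correlation of all genes; a pooled permutation null
  (each permutation independently shuffles each gene's values across AOIs);
  empirical p-values converted to Storey q-values; edges require
  |ρ| ≥ 0.7 and q < 0.01 with weight ρ⁴; Leiden communities at
  resolution 0.5; clusters with < 10 genes flagged as underpowered.

## Worked example

```python
from ipmndsp import (SimulationConfig, default_design, simulate_dataset,
                     Contrast, fit_contrast, call_de, build_network,
                     leiden_communities)
from ipmndsp.qc import run_qc
from ipmndsp.normalize import normalize_pipeline

config = SimulationConfig(subtype_design=default_design(3, 3), n_genes=600, seed=7)
pcm, annotation, truth = simulate_dataset(config)
expr, pcm_f, records, lods = run_qc(pcm)
log = normalize_pipeline(expr, pcm_f)["log"]
hgd = fit_contrast(log, annotation.subset(log.aoi_ids),
                   Contrast("HGD_vs_LGD", {"grade": "HGD"}, {"grade": "LGD"}))
up, down = call_de(hgd)
net = build_network(log, n_perm=1000, seed=7)
labels = leiden_communities(net, seed=7)
```

prints, via the obvious f-strings:

```
simulated 2891 probes x 50 AOIs
QC: 39/50 AOIs pass, 458/600 genes detected
HGD vs LGD: 29 up, 2 down; 29/29 planted genes recovered
network: 195 genes, 1903 edges, 10 communities
```

Eleven low-signal AOIs fail the count/snAUC gates, about a quarter of the
genes sit below the per-AOI detection limit, the moderated contrast recovers
every planted high-grade gene that survived detection filtering (with two
borderline extra calls), and the coexpression network isolates the planted
modules among its communities.

The same analysis is scriptable from the shell:

```bash
ipmndsp simulate --out data --seed 7 --n-genes 600 --n-slides 3
ipmndsp qc --counts data/probe_counts.tsv --manifest data/probe_manifest.tsv --out qc_out
ipmndsp run-all --config pipeline.yaml
```

where `pipeline.yaml` holds the `PipelineConfig` fields (every threshold
defaults to the analysis values listed above).

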