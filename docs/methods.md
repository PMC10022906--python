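# Methods

This note documents the statistical procedures the package implements, the
choices made where the design was genuinely open, what the synthetic-data
generator does and does not emulate, and known limitations.

## Quality control

Each AOI is scored by two statistics computed from its own probe counts:

- **snAUC** — the area under the ROC curve treating gene-probe counts as
  positives and negative-probe counts as negatives. It is computed as the
  Mann–Whitney U statistic divided by the number of (gene, negative) probe
  pairs, ties contributing ½, so it is invariant under any strictly
  monotone transform of the counts.
- **LOD** — the 90th percentile of the AOI's negative-probe counts, using
  linear interpolation between order statistics (the "type 7" quantile
  convention). The percentile convention is not dictated by the analysis
  design; type 7 was chosen because it is the default of both NumPy and R
  and is therefore the easiest to verify independently. A count strictly
  below the LOD is undetectable; equality counts as detected.

The LOD is computed **per AOI** rather than globally: background level
scales with library size, so a single pooled threshold would over-call
detection in shallow AOIs and under-call it in deep ones.

Filter boundaries follow the stated wording exactly: "greater than"
criteria are strict (an AOI with snAUC exactly 0.65, or a probe undetected
in exactly 80% of AOIs, is *not* removed for that criterion alone), and
"at least" criteria are inclusive (a gene detected in exactly 20% of AOIs
is retained).

Probe collapsing takes the geometric mean of a gene's surviving probes
after replacing zeros with 1 — the standard digital-counting convention,
which prevents a single dropout probe from zeroing the gene. The per-probe
multiplicative biases the generator plants make the geometric mean the
natural estimator being tested.

## Normalization

The chain is fixed: background subtraction → library scaling → quantile
normalization → log transform.

1. Background per AOI is the geometric mean of its negative-probe counts
   (zeros replaced by 1); subtracted values are floored at 0.
2. Library scaling divides each AOI column by its total and multiplies by
   10⁶ (counts per million).
3. Quantile normalization is the classic rank-mean algorithm: sort each
   column, average across columns at each rank, map the averages back by
   each column's original ordering. Ties receive the mean of the rank means
   over the tied span, so tied inputs stay tied and the operation is
   idempotent.
4. log₂(x + 1), so 0 maps to 0 and fold changes are natively in log₂
   units.

Library scaling before quantile normalization follows the stated order of
the analysis; since quantile normalization equalizes the full distribution
anyway, the scaling step mainly protects the background-subtracted values
from gross library effects in the rank structure.

## Differential expression

Each gene is fitted by OLS for a two-group contrast on log₂ expression.
Gene-level residual variances are moderated under the standard hierarchical
model s²_g ~ s₀² F(d_g, d₀): the prior degrees of freedom d₀ and prior
variance s₀² are estimated by moment matching the mean and variance of
log s²_g to the digamma/trigamma moments of the log-F distribution
(trigamma inversion by Newton iteration). The moderated t is the fold
change over the shrunken standard error with d_g + d₀ degrees of freedom.
When the log-variances are underdispersed relative to pure chi-square
sampling noise, d₀ is infinite and every gene is shrunk to the plain mean
of the variances. The test suite verifies the implementation against
limma's `eBayes` to numerical precision.

Design choices:

- **No random effect for slide/patient.** AOIs are treated as independent
  observations. This is a known simplification: AOIs within a slide share
  a patient and section, and the resulting p-values are anti-conservative
  to the extent of that intra-slide correlation.
- **BH within each contrast separately** (per-analysis families), matching
  per-contrast reporting.
- **Internal DE calls use strict |log₂FC| > 1**; external gene-set
  curation (`build_external_gene_sets`) uses the inclusive ≥ 1 threshold,
  mirroring how the two rules are stated for each use.
- The pooled HGD-vs-LGD contrast does not adjust for subtype; the subgroup
  contrasts (PB-HGD, PB-LGD, INT-HGD, INT-LGD, all six pairs) provide the
  subtype-stratified view instead. Subgroups combine the *slide's
  predominant* subtype with the AOI grade, so GF AOIs on PB-predominant
  slides contribute to PB-LGD.

## Gene-set enrichment

Preranked GSEA ranks genes by log₂ fold change (descending; ties broken by
gene symbol for determinism) and scores each set by the weighted
Kolmogorov–Smirnov running sum with weight exponent 1: hits increment
proportionally to |statistic|, misses decrement uniformly, and the ES is
the deviation of maximal magnitude (a positive peak wins an exact ± tie).
The null distribution draws random same-size gene subsets of the ranked
universe — preranked-mode semantics, since sample permutation is
unavailable for a preranked list. When the number of distinct subsets is at
most `n_perm` the null is enumerated exhaustively (and the p-value is the
exact fraction); otherwise subsets are sampled with a seeded generator and
the p-value uses the (1 + extreme)/(1 + n) smoothing, which is slightly
conservative. NES divides ES by the mean |null ES| of matching sign.
Defaults `min_size=5`, `max_size=500` bound testable sets; genes absent
from the measured universe are dropped from each set before testing — the
reality of a targeted panel covering ~10% of protein-coding genes.

Cluster over-representation uses the upper-tail hypergeometric probability
P(X ≥ k) within a configurable universe; the default universe is all
filtered genes. Using network genes instead would shrink the universe and
inflate significance, which is why the choice is exposed rather than fixed.

## Coexpression network

The Spearman matrix is computed on average-ranked values per gene;
constant genes get undefined (NaN) correlations and cannot form edges.

The permutation null independently permutes each gene's values across
AOIs, which destroys all pairwise association while preserving every
gene's marginal (including tie structure from low counts). All permuted
|ρ| values pool into one global null, matching the single-null design.
Computing every pairwise correlation for every permutation is quadratic in
genes, so each permutation permutes a small random gene subset and
contributes an equal share of pairs, capping the pooled null at
`max_null_size` (default 10⁶) values; the p-value resolution 1/10⁶ is far
below the q < 0.01 edge rule. Gene and AOI orderings are canonicalized
inside the null so network construction is invariant to input row/column
order.

Empirical p-values use the (1 + #{null ≥ obs})/(1 + #null) estimator
(super-uniform under the null). q-values use the Storey positive-FDR
estimator with π₀ from the fraction of p-values above λ = 0.5, with the
usual monotonicity enforcement.

Edges require |ρ| ≥ 0.7 **and** q < 0.01; q-values are computed over all
pairs, then both thresholds are applied. Edge weights are ρ⁴, which
sharpens the contrast between strong and borderline correlations in the
community search. Leiden clustering runs on the weighted graph with the
resolution-parameterized modularity quality (resolution 0.5, 10
iterations, seeded). Clusters with fewer than 10 genes are flagged as
underpowered for enrichment rather than deleted from node attributes.

## Exploration

PCA treats AOIs as observations with genes centered and, by default,
scaled to unit variance (scaling is configurable; the analysis design does
not state it, and unit variance keeps high-abundance genes from dominating
a targeted panel). Hierarchical clustering uses Euclidean distance with
the ward.D2 criterion — distances are *not* squared before the
Lance–Williams update — which is exactly SciPy's `ward` linkage; the test
suite validates the merge heights against a brute-force recursion. Heatmap
views z-score each gene across AOIs first; constant genes map to z = 0
with a warning. The high/low-risk view cuts the AOI dendrogram (built on
the HGD-vs-LGD signature genes) into k = 2 groups.

## Synthetic-data generator

The generator emulates the count structure the analysis assumes:

- **Cohort.** 12 slides (6 PB-predominant, 6 INT-predominant), 98 AOIs
  (50 HGD / 48 LGD), with GF epithelium always low grade — requesting a
  GF-HGD AOI is rejected by name. 8584 gene probes over 1829 genes (a
  mixed 4/5 probes-per-gene layout) and 75 negative probes.
- **Counts.** Negative binomial (gamma–Poisson) with gene-specific log₂
  baseline ~ N(4.0, 2.0), shared dispersion 0.1, a fixed lognormal
  multiplicative bias per probe (sd 0.25), and a background level of 2³
  for negative probes. Per-AOI library targets are log-uniform on
  (60k, 1M) with HGD and INT AOIs biased toward larger libraries,
  reproducing the correlation of sequencing yield with cellular density
  that normalization must remove. These defaults were calibrated once to
  the loosely stated cohort medians (~84% of AOIs passing QC, roughly half
  of probes above background, ~70% of genes retained, median library in
  the hundreds of thousands).
- **Planted truth.** Subtype-specific genes (default 25 per subtype,
  +2 log₂ in their subtype), high-grade genes (default 30, +2 log₂ in HGD
  AOIs), and coexpression modules (default 40/30/20 genes, loading 1.5 on
  a per-AOI latent factor). Signature memberships are disjoint; module
  members are drawn from the remaining background. All memberships are
  recorded in a `SyntheticTruth` ledger.
- **Reproducibility.** A single root seed spawns independent child streams
  per stage; identical configs are bit-for-bit reproducible.

What the generator does **not** emulate: spatial autocorrelation between
neighboring AOIs, patient-level random effects, probe-specific sequence
biases that vary by AOI, segmentation artifacts, or any image-derived
signal. Passing recovery tests therefore demonstrates that the chain
correctly handles overdispersed counts, probe bias, background, and
library confounding — not that it is robust to every failure mode of real
tissue profiling.

Performance benchmarks in the test suite use a well-expressed variant of
the generator (baseline 2⁶, sd 1.5, libraries 300k–900k) so that planted
genes sit above the detection limit and the statistic under test — rather
than the detection filter — determines the outcome. Problem sizes follow
the benchmark definitions (500 genes / 20 planted at 10 vs 10 AOIs for DE;
3 × 25 planted subtype genes at 90 AOIs for signatures; 900 background
genes at 60–78 AOIs with 1,000-permutation nulls for the network checks).

## Numerical choices

- Quantile-normalization ties: mean of rank means over the tied span.
- Geometric means: zeros replaced by 1 before logging.
- GSEA ES ties: positive deviation wins within 1e-12.
- Trigamma inversion: Newton iteration, 50-step cap, relative tolerance
  1e-8; variance moderation falls back to infinite prior df when the
  observed log-variance spread is below chi-square sampling noise.
- Zero-variance genes never divide by zero: shrinkage gives them the
  pooled variance.
- All output tables are written with a fixed float format so identical
  runs are byte-identical.

## Limitations

- AOI independence (no mixed model) overstates effective sample size for
  contrasts that span few slides.
- The pooled permutation null is global, not per-pair; pairs with unusual
  marginals (heavy ties) are calibrated only on average. The sub-sampled
  pooling bounds memory but means the extreme null tail beyond the cap's
  resolution is unexplored.
- GSEA's random-gene-set null ignores inter-gene correlation, as
  preranked mode always does; enrichment p-values are optimistic for sets
  of co-regulated genes.
- The high/low-risk clustering is a descriptive view of the HGD signature,
  not a validated classifier.
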