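"""Probe-level quality control, filtering, and probe-to-gene collapsing.

QC follows the standard chain for targeted digital spatial profiling:

1. Per AOI, a signal-to-noise ROC AUC (snAUC) separating gene-probe counts
   from negative-probe counts, and a limit of detection (LOD) set to the
   90th percentile of the negative-probe counts. A count strictly below the
   LOD is undetectable; equality counts as detected.
2. AOIs are retained when total counts exceed 100,000 and snAUC exceeds
   0.65 (both strict).
3. Gene probes undetected in more than 80% of AOIs are removed (negative
   probes are exempt), then surviving probes are collapsed to one value per
   gene by geometric mean (zeros replaced by 1 first).
4. Genes detected above the per-AOI LOD in at least 20% of AOIs are kept.

The LOD is computed per AOI from that AOI's own negative probes, because
background level varies with library size. The percentile uses linear
interpolation between order statistics (the common "type 7" convention).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .containers import (
    AOIQCRecord,
    GeneExpressionMatrix,
    ProbeCountMatrix,
    ValidationError,
)

LOD_PERCENTILE = 90.0


def compute_snauc(gene_probe_counts, negative_probe_counts) -> float:
    """ROC AUC of gene-probe counts (positives) vs negative probes (negatives).

    Equals the Mann-Whitney U statistic divided by the number of
    (gene, negative) pairs, with ties contributing 1/2.
    """
    gene = np.asarray(gene_probe_counts, dtype=float)
    neg = np.asarray(negative_probe_counts, dtype=float)
    if gene.size == 0:
        raise ValidationError("no gene-probe counts supplied (positive class empty)")
    if neg.size == 0:
        raise ValidationError("no negative-probe counts supplied (negative class empty)")
    u = stats.mannwhitneyu(gene, neg, alternative="two-sided", method="asymptotic").statistic
    return float(u) / (gene.size * neg.size)


def compute_lod(negative_probe_counts, percentile: float = LOD_PERCENTILE) -> float:
    """Limit of detection: the 90th percentile of negative-probe counts."""
    neg = np.asarray(negative_probe_counts, dtype=float)
    if neg.size == 0:
        raise ValidationError("cannot compute LOD from an empty negative-probe vector")
    return float(np.percentile(neg, percentile))  # linear / type-7 interpolation


def is_detected(count, lod) -> bool:
    """A count is detected iff it is not strictly below the LOD."""
    return np.asarray(count) >= lod


def aoi_lods(matrix: ProbeCountMatrix) -> pd.Series:
    """Per-AOI LOD from each AOI's own negative probes."""
    neg = matrix.negative_probe_counts
    if neg.shape[0] == 0:
        raise ValidationError("matrix has no negative probes; cannot compute LODs")
    return pd.Series(np.percentile(neg.values, LOD_PERCENTILE, axis=0), index=matrix.aoi_ids)


def qc_records(matrix: ProbeCountMatrix, min_counts: int = 100_000, min_snauc: float = 0.65):
    """Compute one :class:`AOIQCRecord` per AOI (no filtering applied)."""
    gene_counts = matrix.gene_probe_counts
    neg_counts = matrix.negative_probe_counts
    lods = aoi_lods(matrix)
    records = []
    for aoi in matrix.aoi_ids:
        total = int(matrix.counts[aoi].sum())
        snauc = compute_snauc(gene_counts[aoi].values, neg_counts[aoi].values)
        lod = float(lods[aoi])
        pct = float(100.0 * np.mean(gene_counts[aoi].values >= lod))
        reasons = []
        if total <= min_counts:
            reasons.append("low counts")
        if snauc <= min_snauc:
            reasons.append("low snAUC")
        records.append(AOIQCRecord(str(aoi), total, snauc, lod, pct, not reasons, reasons))
    return records


def filter_aois(
    matrix: ProbeCountMatrix, min_counts: int = 100_000, min_snauc: float = 0.65
):
    """Retain AOIs with total counts > ``min_counts`` and snAUC > ``min_snauc``.

    Both criteria are strict. Returns the column-subset matrix and the full
    list of QC records (including the removed AOIs with their reasons).
    """
    records = qc_records(matrix, min_counts=min_counts, min_snauc=min_snauc)
    keep = [r.aoi_id for r in records if r.passed]
    if not keep:
        raise ValidationError("no AOIs pass QC")
    return matrix.subset_aois(keep), records


def filter_probes(matrix: ProbeCountMatrix, max_undetected_frac: float = 0.80) -> ProbeCountMatrix:
    """Remove gene probes undetected in more than ``max_undetected_frac`` of AOIs.

    Detection is judged per AOI against that AOI's LOD. Negative probes are
    never removed. The boundary is strict: a probe undetected in exactly 80%
    of AOIs is retained.
    """
    lods = aoi_lods(matrix)
    undetected = matrix.counts.values < lods.values[None, :]
    frac = undetected.mean(axis=1)
    keep = (frac <= max_undetected_frac) | matrix.is_negative.values
    return matrix.subset_probes(matrix.counts.index[keep])


def collapse_probes(matrix: ProbeCountMatrix, zero_replacement: float = 1.0) -> GeneExpressionMatrix:
    """Geometric-mean collapse of surviving probes to one value per gene.

    Zeros are replaced by ``zero_replacement`` before taking logs, the
    standard digital-counting convention, so a single dropout probe cannot
    annihilate a gene's value.
    """
    gene_counts = matrix.gene_probe_counts
    genes = matrix.manifest.loc[gene_counts.index, "gene"]
    logged = np.log(np.maximum(gene_counts.values, zero_replacement))
    logged_df = pd.DataFrame(logged, index=genes.values, columns=gene_counts.columns)
    collapsed = np.exp(logged_df.groupby(level=0, sort=True).mean())
    return GeneExpressionMatrix(collapsed, stage="collapsed_raw")


def filter_genes(
    expr: GeneExpressionMatrix, lods: pd.Series, min_detected_frac: float = 0.20
) -> GeneExpressionMatrix:
    """Retain genes detected (>= per-AOI LOD) in at least ``min_detected_frac`` of AOIs."""
    lods = lods.loc[expr.aoi_ids]
    detected = expr.values.values >= lods.values[None, :]
    frac = detected.mean(axis=1)
    keep = frac >= min_detected_frac
    if not keep.any():
        raise ValidationError("no genes pass the detection filter")
    return GeneExpressionMatrix(expr.values.loc[keep], stage=expr.stage)


def run_qc(
    matrix: ProbeCountMatrix,
    min_counts: int = 100_000,
    min_snauc: float = 0.65,
    max_undetected_frac: float = 0.80,
    min_detected_frac: float = 0.20,
):
    """Full QC chain: AOI filter -> probe filter -> collapse -> gene filter.

    Returns ``(expr, filtered_matrix, records, lods)`` where ``expr`` is the
    collapsed, gene-filtered raw expression matrix and ``lods`` the per-AOI
    LODs of the retained AOIs.
    """
    filtered, records = filter_aois(matrix, min_counts=min_counts, min_snauc=min_snauc)
    filtered = filter_probes(filtered, max_undetected_frac=max_undetected_frac)
    collapsed = collapse_probes(filtered)
    lods = aoi_lods(filtered)
    expr = filter_genes(collapsed, lods, min_detected_frac=min_detected_frac)
    return expr, filtered, records, lods
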