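"""Normalization chain for collapsed gene counts.

Fixed order: background subtraction (geometric mean of each AOI's negative
probes), library-size scaling to counts per million, quantile
normalization, and finally log2(x + 1) for modeling. Each step returns a
new :class:`GeneExpressionMatrix` with the corresponding stage tag.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import GeneExpressionMatrix, ProbeCountMatrix, ValidationError


def background_levels(matrix: ProbeCountMatrix, zero_replacement: float = 1.0) -> pd.Series:
    """Per-AOI background: geometric mean of negative-probe counts."""
    neg = matrix.negative_probe_counts
    if neg.shape[0] == 0:
        raise ValidationError("no negative probes available for background estimation")
    logged = np.log(np.maximum(neg.values, zero_replacement))
    return pd.Series(np.exp(logged.mean(axis=0)), index=matrix.aoi_ids)


def subtract_background(expr: GeneExpressionMatrix, matrix: ProbeCountMatrix) -> GeneExpressionMatrix:
    """Subtract each AOI's background level, flooring at zero."""
    bg = background_levels(matrix).loc[expr.aoi_ids]
    values = np.maximum(expr.values.values - bg.values[None, :], 0.0)
    out = pd.DataFrame(values, index=expr.genes, columns=expr.aoi_ids)
    return GeneExpressionMatrix(out, stage="background_subtracted")


def scale_library(expr: GeneExpressionMatrix) -> GeneExpressionMatrix:
    """Scale each AOI column to counts per million."""
    totals = expr.values.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValidationError(f"AOI '{zero.index[0]}' has an all-zero column; cannot scale")
    values = expr.values.values / totals.values[None, :] * 1e6
    out = pd.DataFrame(values, index=expr.genes, columns=expr.aoi_ids)
    return GeneExpressionMatrix(out, stage="scaled")


def quantile_normalize(expr: GeneExpressionMatrix) -> GeneExpressionMatrix:
    """Classic quantile normalization across AOI columns.

    Each column is sorted, values are averaged across columns at each rank,
    and the rank means are mapped back by each column's original ordering.
    Ties within a column receive the mean of the rank means over the tied
    span, so tied values stay tied.
    """
    if expr.values.shape[1] < 2:
        raise ValidationError("quantile normalization requires at least 2 AOIs")
    vals = expr.values.values.astype(float)
    n, m = vals.shape
    rank_means = np.sort(vals, axis=0).mean(axis=1)
    out = np.empty_like(vals)
    for j in range(m):
        order = np.argsort(vals[:, j], kind="mergesort")
        sorted_col = vals[order, j]
        # average rank means over runs of tied values
        _, inverse = np.unique(sorted_col, return_inverse=True)
        sums = np.bincount(inverse, weights=rank_means)
        counts = np.bincount(inverse)
        out[order, j] = (sums / counts)[inverse]
    df = pd.DataFrame(out, index=expr.genes, columns=expr.aoi_ids)
    return GeneExpressionMatrix(df, stage="quantile_normalized")


def log_transform(expr: GeneExpressionMatrix, pseudocount: float = 1.0) -> GeneExpressionMatrix:
    """log2(value + pseudocount); with the default pseudocount, 0 maps to 0."""
    if (expr.values.values < 0).any():
        raise ValidationError("log transform requires non-negative input")
    out = np.log2(expr.values + pseudocount)
    return GeneExpressionMatrix(out, stage="log")


def normalize_pipeline(
    expr: GeneExpressionMatrix, matrix: ProbeCountMatrix, pseudocount: float = 1.0
):
    """Run subtract -> scale -> quantile -> log; returns every stage.

    The returned dict maps stage tag to matrix, with "log" being the input
    for all downstream modeling.
    """
    stages = {}
    stages["background_subtracted"] = subtract_background(expr, matrix)
    stages["scaled"] = scale_library(stages["background_subtracted"])
    stages["quantile_normalized"] = quantile_normalize(stages["scaled"])
    stages["log"] = log_transform(stages["quantile_normalized"], pseudocount=pseudocount)
    return stages
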