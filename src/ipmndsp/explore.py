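"""Unsupervised views: PCA of AOIs and ward.D2 hierarchical clustering.

PCA treats AOIs as observations and genes as features, centered and (by
default) scaled to unit variance per gene. Hierarchical clustering uses
Euclidean distance with the ward.D2 criterion (distances are not squared
before the Lance-Williams update), matching the convention of R's
``hclust(method="ward.D2")``; SciPy's ``ward`` linkage implements exactly
this form. For heatmap-style views rows are z-scored per gene first.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from sklearn.decomposition import PCA

from .containers import GeneExpressionMatrix, ValidationError


def pca_aois(expr: GeneExpressionMatrix, n_components: int | None = None, scale: bool = True):
    """PCA of AOIs on (centered, optionally unit-variance) genes.

    Returns ``(scores, loadings, explained_variance_ratio)``: scores are
    AOIs x components, loadings genes x components, and the variance
    fractions are non-increasing and sum to <= 1.
    """
    x = expr.values.T.values.astype(float)  # AOIs x genes
    n_aois, n_genes = x.shape
    if n_aois < 2 or n_genes < 2:
        raise ValidationError("PCA requires at least 2 AOIs and 2 genes")
    x = x - x.mean(axis=0)
    if scale:
        sd = x.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0  # constant genes contribute nothing after centering
        x = x / sd
    max_comp = min(n_aois - 1, n_genes)
    k = max_comp if n_components is None else min(n_components, max_comp)
    model = PCA(n_components=k, svd_solver="full")
    scores = model.fit_transform(x)
    comp_names = [f"PC{i + 1}" for i in range(k)]
    scores_df = pd.DataFrame(scores, index=expr.aoi_ids, columns=comp_names)
    loadings_df = pd.DataFrame(model.components_.T, index=expr.genes, columns=comp_names)
    # variance fractions relative to the total variance of the input
    total_var = model.explained_variance_.sum() / model.explained_variance_ratio_.sum()
    ratio = model.explained_variance_ / total_var
    return scores_df, loadings_df, ratio


def zscore_rows(values: pd.DataFrame) -> pd.DataFrame:
    """Per-row z-score; constant rows map to 0 with a warning."""
    mean = values.mean(axis=1)
    sd = values.std(axis=1, ddof=0)
    constant = sd == 0
    if constant.any():
        warnings.warn(f"{int(constant.sum())} constant row(s) set to z = 0")
        sd = sd.mask(constant, 1.0)
    return values.sub(mean, axis=0).div(sd, axis=0)


def hierarchical_cluster(values: pd.DataFrame, axis: str = "rows", zscore: bool = False):
    """ward.D2 agglomerative clustering of rows or columns.

    Returns ``(linkage_matrix, item_labels, leaf_order)``. When ``zscore``
    is set, rows are z-scored before clustering (the heatmap convention);
    this applies to whichever axis is clustered through the shared matrix.
    """
    if axis not in ("rows", "columns"):
        raise ValidationError("axis must be 'rows' or 'columns'")
    data = zscore_rows(values) if zscore else values
    mat = data.values if axis == "rows" else data.values.T
    labels = list(data.index if axis == "rows" else data.columns)
    if mat.shape[0] < 2:
        raise ValidationError("clustering requires at least 2 items")
    linkage = hierarchy.linkage(mat, method="ward")
    order = [labels[i] for i in hierarchy.leaves_list(linkage)]
    return linkage, labels, order


def cut_clusters(linkage: np.ndarray, labels, k: int) -> pd.Series:
    """Cut the dendrogram into exactly ``k`` groups (1 <= k <= n items)."""
    n = len(labels)
    if not (1 <= k <= n):
        raise ValidationError(f"k must be in [1, {n}], got {k}")
    assignments = hierarchy.cut_tree(linkage, n_clusters=k).ravel() + 1
    return pd.Series(assignments, index=pd.Index(labels))


def to_newick(linkage: np.ndarray, labels) -> str:
    """Serialize a linkage tree as a Newick-style nested string."""
    tree = hierarchy.to_tree(linkage)

    def render(node) -> str:
        if node.is_leaf():
            return str(labels[node.id])
        left, right = render(node.left), render(node.right)
        return f"({left},{right}):{node.dist:.6g}"

    return render(tree) + ";"
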