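"""Permutation-calibrated Spearman coexpression network with Leiden communities.

The network is built from the pairwise Spearman correlation matrix of all
genes. Statistical calibration uses a pooled permutation null: each
permutation shuffles every gene's values independently across AOIs (which
destroys all pairwise association while preserving each gene's marginal
distribution), and the resulting |rho| values are pooled into one global
null distribution. Per-pair empirical p-values are converted to q-values
with a positive-FDR estimator (pi0 from the fraction of p-values above
lambda = 0.5). Edges require |rho| >= 0.7 and q < 0.01; edge weights are
rho^4, sharpening the contrast between strong and borderline correlations.
Communities come from Leiden clustering at resolution 0.5 on the weighted
graph, and clusters with fewer than 10 genes are flagged as underpowered.

Computing every pairwise correlation for every permutation is quadratic in
genes, so the pooled null caps its total size (default one million values):
each permutation permutes a small random subset of genes and contributes an
equal share of null correlations. The cap is configurable and the p-value
resolution (1 / null size) stays far below the q < 0.01 edge threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import igraph
import leidenalg
import numpy as np
import pandas as pd

from .containers import AOIAnnotation, GeneExpressionMatrix, ValidationError


def _rank_rows(values: np.ndarray) -> np.ndarray:
    """Average ranks along each row (ties share the mean rank)."""
    from scipy.stats import rankdata

    return rankdata(values, axis=1, method="average")


def spearman_matrix(expr: GeneExpressionMatrix) -> pd.DataFrame:
    """Pairwise Spearman correlation of genes across AOIs.

    Constant genes have undefined correlation; their rows/columns are NaN
    (excluded from edge calling) and a warning is emitted.
    """
    values = expr.values.values
    if values.shape[1] < 3:
        raise ValidationError("Spearman matrix requires at least 3 AOIs")
    constant = values.std(axis=1) == 0
    if constant.any():
        warnings.warn(f"{int(constant.sum())} constant gene(s); correlations set to NaN")
    ranks = _rank_rows(values)
    with np.errstate(invalid="ignore"):
        rho = np.corrcoef(ranks)
    rho[constant, :] = np.nan
    rho[:, constant] = np.nan
    np.fill_diagonal(rho, 1.0)
    return pd.DataFrame(rho, index=expr.genes, columns=expr.genes)


def permutation_null(
    expr: GeneExpressionMatrix,
    n_perm: int = 10_000,
    seed: int = 0,
    max_null_size: int = 1_000_000,
) -> np.ndarray:
    """Pooled null distribution of |Spearman rho| under independence.

    Each of ``n_perm`` permutations independently shuffles a subset of
    genes across AOIs and contributes ``max_null_size / n_perm`` pairwise
    correlations to the pool. Returns the sorted |rho| values.
    """
    if n_perm < 1000:
        raise ValidationError("n_perm must be at least 1000")
    # canonical gene/AOI ordering so the null (and hence edge calling) is
    # invariant to the row/column order of the input matrix
    canonical = expr.values.sort_index(axis=0).sort_index(axis=1)
    values = canonical.values
    n_genes, n_aois = values.shape
    if n_genes < 2:
        raise ValidationError("need at least 2 genes for a correlation null")
    rng = np.random.default_rng(seed)
    per_perm = max(1, int(np.ceil(max_null_size / n_perm)))
    # smallest subset of genes whose pair count covers the per-permutation share
    q = 2
    while q * (q - 1) // 2 < per_perm and q < n_genes:
        q += 1
    pooled = []
    iu = np.triu_indices(q, k=1)
    for _ in range(n_perm):
        rows = rng.choice(n_genes, size=q, replace=False)
        sub = values[rows]
        perm_sub = np.empty_like(sub)
        for i in range(q):
            perm_sub[i] = sub[i, rng.permutation(n_aois)]
        ranks = _rank_rows(perm_sub)
        with np.errstate(invalid="ignore"):
            rho = np.corrcoef(ranks)
        pair_vals = np.abs(rho[iu])
        ok = np.isfinite(pair_vals)
        pair_vals = pair_vals[ok]
        if pair_vals.size > per_perm:
            pick = rng.choice(pair_vals.size, size=per_perm, replace=False)
            pair_vals = pair_vals[pick]
        pooled.append(pair_vals)
    null = np.sort(np.concatenate(pooled))
    return null


def empirical_pvalues(rho: pd.DataFrame, null: np.ndarray):
    """Per-pair empirical p = (1 + #{null >= |rho|}) / (1 + #null).

    Returns ``(pairs_i, pairs_j, p)`` for the upper-triangle pairs with
    finite correlation.
    """
    if null.size == 0:
        raise ValidationError("null distribution is empty")
    r = rho.values
    iu = np.triu_indices(r.shape[0], k=1)
    obs = np.abs(r[iu])
    finite = np.isfinite(obs)
    i_idx, j_idx, obs = iu[0][finite], iu[1][finite], obs[finite]
    # null is sorted ascending: count of null >= obs via searchsorted
    ge = null.size - np.searchsorted(null, obs, side="left")
    p = (1.0 + ge) / (1.0 + null.size)
    return i_idx, j_idx, p


def storey_qvalues(pvalues: np.ndarray, lambda_: float = 0.5) -> np.ndarray:
    """Positive-FDR q-values with pi0 estimated from p-values above lambda."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    if m == 0:
        return p
    pi0 = np.mean(p > lambda_) / (1.0 - lambda_)
    pi0 = min(max(pi0, 1.0 / m), 1.0)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    q_sorted = pi0 * m * ranked / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def edge_qvalues(rho: pd.DataFrame, null: np.ndarray) -> pd.DataFrame:
    """Tidy per-pair table with rho, empirical p and q (monotone in p)."""
    i_idx, j_idx, p = empirical_pvalues(rho, null)
    q = storey_qvalues(p)
    genes = rho.index.to_numpy()
    return pd.DataFrame(
        {
            "gene_a": genes[i_idx],
            "gene_b": genes[j_idx],
            "rho": rho.values[i_idx, j_idx],
            "pvalue": p,
            "qvalue": q,
        }
    )


@dataclass
class CoexpressionNetwork:
    """Gene coexpression network: nodes, thresholded edges, cluster labels."""

    edges: pd.DataFrame  # gene_a, gene_b, rho, pvalue, qvalue, weight
    nodes: pd.Index
    node_attrs: pd.DataFrame = field(default_factory=pd.DataFrame)
    clusters: pd.Series = field(default_factory=lambda: pd.Series(dtype=int))

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def graph(self) -> igraph.Graph:
        g = igraph.Graph()
        g.add_vertices(len(self.nodes))
        g.vs["name"] = list(self.nodes)
        if len(self.edges):
            index = {g_: i for i, g_ in enumerate(self.nodes)}
            pairs = [
                (index[a], index[b]) for a, b in zip(self.edges["gene_a"], self.edges["gene_b"])
            ]
            g.add_edges(pairs)
            g.es["weight"] = list(self.edges["weight"])
        return g

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        for node in self.nodes:
            attrs = {}
            if len(self.node_attrs) and node in self.node_attrs.index:
                attrs = {
                    k: (v.item() if hasattr(v, "item") else v)
                    for k, v in self.node_attrs.loc[node].items()
                }
            if len(self.clusters) and node in self.clusters.index:
                attrs["cluster"] = int(self.clusters[node])
            g.add_node(node, **attrs)
        for row in self.edges.itertuples(index=False):
            g.add_edge(
                row.gene_a,
                row.gene_b,
                rho=float(row.rho),
                qvalue=float(row.qvalue),
                weight=float(row.weight),
            )
        return g


def build_network(
    expr: GeneExpressionMatrix,
    rho_min: float = 0.7,
    q_max: float = 0.01,
    n_perm: int = 10_000,
    seed: int = 0,
    max_null_size: int = 1_000_000,
) -> CoexpressionNetwork:
    """Spearman matrix -> permutation null -> q-values -> thresholded edges.

    Edges require |rho| >= ``rho_min`` and q < ``q_max``; weights are rho^4.
    Nodes are the genes incident to at least one passing edge.
    """
    rho = spearman_matrix(expr)
    null = permutation_null(expr, n_perm=n_perm, seed=seed, max_null_size=max_null_size)
    pairs = edge_qvalues(rho, null)
    passing = pairs[(pairs["rho"].abs() >= rho_min) & (pairs["qvalue"] < q_max)].copy()
    passing["weight"] = passing["rho"] ** 4
    passing = passing.reset_index(drop=True)
    if len(passing) == 0:
        warnings.warn("no gene pairs pass the edge thresholds; returning an empty network")
        return CoexpressionNetwork(passing, pd.Index([], name="gene"))
    nodes = pd.Index(
        sorted(set(passing["gene_a"]) | set(passing["gene_b"])), name="gene"
    )
    return CoexpressionNetwork(passing, nodes)


def leiden_communities(
    net: CoexpressionNetwork, resolution: float = 0.5, seed: int = 0, n_iterations: int = 10
) -> pd.Series:
    """Leiden partition of the weighted graph (modularity-type quality).

    Returns integer cluster labels indexed by gene; stable for a fixed seed.
    """
    if net.n_nodes == 0:
        raise ValidationError("cannot cluster an empty network")
    g = net.graph()
    partition = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        weights="weight" if net.n_edges else None,
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=n_iterations,
    )
    labels = pd.Series(partition.membership, index=pd.Index(g.vs["name"], name="gene"))
    net.clusters = labels
    return labels


def filter_clusters(labels: pd.Series, min_size: int = 10) -> pd.DataFrame:
    """Flag clusters below ``min_size`` as underpowered (labels are kept).

    Returns a per-gene table with columns ``cluster`` and ``retained``.
    """
    sizes = labels.value_counts()
    retained_ids = set(sizes.index[sizes >= min_size])
    out = pd.DataFrame({"cluster": labels, "retained": labels.isin(retained_ids)})
    if not retained_ids:
        warnings.warn("all clusters fall below the minimum size; none retained")
    return out


def annotate_overlays(
    net: CoexpressionNetwork,
    expr: GeneExpressionMatrix,
    annotation: AOIAnnotation,
    groups: dict,
    external_sets=(),
    hgd_log2fc: pd.Series | None = None,
) -> CoexpressionNetwork:
    """Attach per-node overlay attributes for network visualization export.

    For each named group (a selector over annotation columns, e.g.
    ``{"slide_subtype": "PB", "grade": "HGD"}``) the node attribute is the
    z-score (across network genes) of the mean log expression within that
    group. The HGD-vs-LGD log2 fold change becomes the node-size attribute
    and each external gene set contributes a boolean membership flag.
    """
    from .de import Contrast

    attrs = pd.DataFrame(index=net.nodes)
    for name, selector in groups.items():
        ids = Contrast._select(annotation.table, selector)
        ids = [i for i in ids if i in expr.aoi_ids]
        if not ids:
            raise ValidationError(f"overlay group '{name}' selects no AOIs")
        means = expr.values.loc[net.nodes, ids].mean(axis=1)
        sd = means.std(ddof=0)
        attrs[f"z_{name}"] = (means - means.mean()) / sd if sd > 0 else 0.0
    if hgd_log2fc is not None:
        attrs["log2fc_hgd_vs_lgd"] = hgd_log2fc.reindex(net.nodes)
    for gs in external_sets:
        attrs[f"in_{gs.name}"] = net.nodes.isin(gs.genes)
    net.node_attrs = attrs
    return net
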