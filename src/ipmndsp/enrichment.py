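"""Gene-set enrichment: preranked GSEA and hypergeometric over-representation.

Preranked GSEA scores each gene set with the weighted Kolmogorov-Smirnov
running-sum statistic (weight exponent 1: hit increments proportional to
|rank statistic|, miss decrements uniform) on a list ranked by log2 fold
change. The null is built from random same-size gene subsets of the ranked
universe; when the number of distinct subsets is small enough the null is
enumerated exhaustively, otherwise it is sampled with a seeded generator.
NES divides the observed ES by the mean |null ES| of matching sign, and the
p-value is the fraction of same-sign null scores at least as extreme.

Hypergeometric over-representation gives the upper-tail probability
P(X >= k) of the observed overlap between a gene cluster and an annotation
set within a fixed universe.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GeneSet, ValidationError
from .de import adjust_bh


def enrichment_score(statistics: np.ndarray, hit_mask: np.ndarray):
    """Weighted KS enrichment score for one set on a descending ranking.

    Returns ``(es, peak_index)`` where ``peak_index`` is the position of the
    extreme deviation (used for the leading edge).
    """
    n = statistics.size
    n_hit = int(hit_mask.sum())
    if n_hit == 0 or n_hit == n:
        raise ValidationError("gene set must hit a strict subset of the universe")
    weights = np.abs(statistics) * hit_mask
    total = weights.sum()
    if total == 0:  # all hit statistics are zero: fall back to equal weights
        weights = hit_mask.astype(float)
        total = weights.sum()
    p_hit = np.cumsum(weights) / total
    p_miss = np.cumsum(~hit_mask) / (n - n_hit)
    dev = p_hit - p_miss
    # extreme deviation; on a +/- magnitude tie the positive peak wins
    hi, lo = int(np.argmax(dev)), int(np.argmin(dev))
    if dev[hi] + 1e-12 >= -dev[lo]:
        return float(dev[hi]), hi
    return float(dev[lo]), lo


def _null_subsets(n: int, k: int, n_perm: int, rng: np.random.Generator):
    """Yield index subsets for the null: exhaustive when feasible, else sampled."""
    if comb(n, k) <= n_perm:
        for c in combinations(range(n), k):
            yield np.asarray(c, dtype=int), True
    else:
        for _ in range(n_perm):
            yield rng.choice(n, size=k, replace=False), False


@dataclass
class EnrichmentResult:
    name: str
    es: float
    nes: float
    pvalue: float
    padj: float
    size: int
    leading_edge: tuple


def gsea_preranked(
    ranked: pd.Series,
    sets,
    n_perm: int = 1000,
    min_size: int = 5,
    max_size: int = 500,
    seed: int = 0,
) -> pd.DataFrame:
    """Preranked GSEA over a collection of gene sets.

    Parameters
    ----------
    ranked
        Rank statistic (log2 fold change) indexed by gene symbol; sorted
        descending internally, ties broken by gene symbol for determinism.
    sets
        Iterable of :class:`GeneSet`. Sets whose intersection with the
        universe falls outside ``[min_size, max_size]`` are skipped with a
        warning.
    """
    if n_perm < 100:
        raise ValidationError("n_perm must be at least 100")
    if len(ranked) == 0:
        raise ValidationError("ranked list is empty")
    if ranked.index.has_duplicates:
        raise ValidationError("ranked list has duplicate gene symbols")
    order = np.lexsort((ranked.index.to_numpy(), -ranked.to_numpy()))
    ranked = ranked.iloc[order]
    statistics = ranked.to_numpy(dtype=float)
    universe = ranked.index
    pos = {g: i for i, g in enumerate(universe)}
    n = len(universe)

    rows = []
    rng = np.random.default_rng(seed)
    null_cache: dict = {}
    for gs in sets:
        idx = np.asarray(sorted(pos[g] for g in gs.genes if g in pos), dtype=int)
        k = idx.size
        if k < min_size or k > max_size or k == n:
            warnings.warn(
                f"gene set '{gs.name}' skipped (effective size {k} outside "
                f"[{min_size}, {max_size}] or degenerate)"
            )
            continue
        mask = np.zeros(n, dtype=bool)
        mask[idx] = True
        es, peak = enrichment_score(statistics, mask)
        if k not in null_cache:
            null_es = []
            exhaustive = False
            for subset, exhaustive in _null_subsets(n, k, n_perm, rng):
                m = np.zeros(n, dtype=bool)
                m[subset] = True
                null_es.append(enrichment_score(statistics, m)[0])
            null_cache[k] = (np.asarray(null_es), exhaustive)
        null_es, exhaustive = null_cache[k]
        same_sign = null_es[null_es >= 0] if es >= 0 else null_es[null_es < 0]
        if same_sign.size:
            extreme = int(np.sum(np.abs(same_sign) >= abs(es)))
            if exhaustive:
                pvalue = extreme / same_sign.size
            else:
                pvalue = (1 + extreme) / (1 + same_sign.size)
            mean_mag = float(np.mean(np.abs(same_sign)))
            nes = es / mean_mag if mean_mag > 0 else np.nan
        else:
            pvalue, nes = 1.0 / (1 + null_es.size), np.nan
        if es >= 0:
            leading = tuple(universe[i] for i in idx if i <= peak)
        else:
            leading = tuple(universe[i] for i in idx if i >= peak)
        rows.append(
            {
                "name": gs.name,
                "es": es,
                "nes": nes,
                "pvalue": pvalue,
                "size": k,
                "leading_edge": leading,
            }
        )
    result = pd.DataFrame(rows, columns=["name", "es", "nes", "pvalue", "size", "leading_edge"])
    if len(result):
        result["padj"] = adjust_bh(result["pvalue"].to_numpy())
    else:
        result["padj"] = pd.Series(dtype=float)
    return result.set_index("name")


def hypergeometric_enrich(cluster, annotation_sets, universe) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation of a cluster in each set.

    ``cluster`` must be a subset of ``universe``. For each annotation set,
    successes are the set's genes present in the universe; the p-value is
    P(X >= k) for the observed overlap k when |cluster| genes are drawn
    without replacement. BH adjustment is applied across sets.
    """
    universe = set(universe)
    if not universe:
        raise ValidationError("universe is empty")
    cluster = set(cluster)
    if not cluster <= universe:
        raise ValidationError("cluster must be a subset of the universe")
    n_univ, n_draw = len(universe), len(cluster)
    rows = []
    for gs in annotation_sets:
        members = set(gs.genes) & universe
        k = len(cluster & members)
        if n_draw == 0:
            p = 1.0
        else:
            p = float(stats.hypergeom.sf(k - 1, n_univ, len(members), n_draw))
        rows.append({"name": gs.name, "set_size": len(members), "overlap": k, "pvalue": min(p, 1.0)})
    result = pd.DataFrame(rows, columns=["name", "set_size", "overlap", "pvalue"])
    if len(result):
        result["padj"] = adjust_bh(result["pvalue"].to_numpy())
    else:
        result["padj"] = pd.Series(dtype=float)
    return result.set_index("name")
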