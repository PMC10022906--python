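"""Two-group differential expression with empirical-Bayes variance moderation.

Each gene is fitted by ordinary least squares on log2 expression (a
two-group comparison), and the gene-level residual variances are shrunk
toward a common prior under the standard scaled-inverse-chi-square
hierarchical model: marginally s_g^2 ~ s0^2 * F(d_g, d0). The prior degrees
of freedom d0 and prior variance s0^2 are estimated by moment matching on
log s_g^2 (mean and variance of the log variances against the digamma /
trigamma moments of the log-F distribution). The moderated t statistic is
the fold change over the shrunken standard error, referred to a t
distribution with residual + prior degrees of freedom. This reproduces the
moderated-t construction used throughout microarray-style DE analysis.

AOIs are treated as independent observations; no random effect for slide or
patient is fitted (a documented simplification).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .containers import AOIAnnotation, GeneExpressionMatrix, GeneSet, ValidationError

LFC_THRESHOLD = 1.0
ALPHA = 0.05


@dataclass
class Contrast:
    """A named two-group contrast over AOI annotations.

    ``group_a`` and ``group_b`` map annotation columns to allowed values,
    e.g. ``{"subtype": ["PB"]}``. Fold changes are reported as A minus B in
    log2 units. Selectors must be disjoint and each non-empty on the data.
    """

    name: str
    group_a: dict
    group_b: dict

    @staticmethod
    def _select(table: pd.DataFrame, selector: dict) -> pd.Index:
        mask = pd.Series(True, index=table.index)
        for col, values in selector.items():
            if col not in table.columns:
                raise ValidationError(f"annotation has no column '{col}'")
            allowed = [values] if isinstance(values, str) else list(values)
            mask &= table[col].isin(allowed)
        return table.index[mask]

    def split(self, annotation: AOIAnnotation):
        a = self._select(annotation.table, self.group_a)
        b = self._select(annotation.table, self.group_b)
        if len(a) == 0 or len(b) == 0:
            raise ValidationError(f"contrast '{self.name}': empty group selection")
        if len(a.intersection(b)):
            raise ValidationError(f"contrast '{self.name}': groups overlap")
        return a, b


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton iteration on 1/trigamma)."""
    if x <= 0:
        return math.inf
    if x > 1e7:
        return 1.0 / math.sqrt(x)
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-8 * y:
            break
    return float(y)


def squeeze_variances(s2: np.ndarray, df: float):
    """Moment-match the scaled-F prior and return (d0, s0_sq, posterior s2).

    ``d0 = inf`` means the log variances are underdispersed relative to pure
    chi-square sampling noise, and every gene is shrunk fully to s0^2.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = np.isfinite(s2) & (s2 > 0)
    if ok.sum() < 2:
        raise ValidationError("need at least two positive gene variances for moderation")
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + math.log(df / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if e_var > 0:
        d0 = 2.0 * _trigamma_inverse(e_var)
        s0_sq = math.exp(e_mean + float(special.digamma(d0 / 2.0)) - math.log(d0 / 2.0))
    else:
        # log-variances underdispersed vs pure chi-square noise: infinite
        # prior df, common variance estimated by the plain mean
        d0 = math.inf
        s0_sq = float(np.mean(s2[ok]))
    if math.isinf(d0):
        post = np.full_like(s2, s0_sq)
    else:
        post = (d0 * s0_sq + df * np.where(ok, s2, 0.0)) / (d0 + df)
    return d0, s0_sq, post


def fit_contrast(
    expr: GeneExpressionMatrix, annotation: AOIAnnotation, contrast: Contrast
) -> pd.DataFrame:
    """Moderated two-group DE on log2 expression.

    Returns a DataFrame indexed by gene with columns ``log2fc`` (A minus B),
    ``t`` (moderated), ``pvalue``, ``padj`` (BH within this contrast) and
    ``significant`` (|log2fc| > 1 and padj < 0.05).
    """
    if expr.stage != "log":
        raise ValidationError("fit_contrast expects log-stage expression")
    a_ids, b_ids = contrast.split(annotation)
    a_ids = [i for i in a_ids if i in expr.aoi_ids]
    b_ids = [i for i in b_ids if i in expr.aoi_ids]
    n_a, n_b = len(a_ids), len(b_ids)
    if n_a < 2 or n_b < 2:
        raise ValidationError(
            f"contrast '{contrast.name}': each group needs >=2 AOIs (got {n_a} vs {n_b})"
        )
    xa = expr.values[a_ids].values
    xb = expr.values[b_ids].values
    mean_a, mean_b = xa.mean(axis=1), xb.mean(axis=1)
    lfc = mean_a - mean_b
    df_resid = n_a + n_b - 2
    ss = ((xa - mean_a[:, None]) ** 2).sum(axis=1) + ((xb - mean_b[:, None]) ** 2).sum(axis=1)
    s2 = ss / df_resid
    d0, s0_sq, s2_post = squeeze_variances(s2, df_resid)
    se = np.sqrt(s2_post * (1.0 / n_a + 1.0 / n_b))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, lfc / se, 0.0)
    df_total = df_resid + d0
    if math.isinf(df_total):
        pvalue = 2.0 * stats.norm.sf(np.abs(t))
    else:
        pvalue = 2.0 * stats.t.sf(np.abs(t), df_total)
    padj = adjust_bh(pvalue)
    out = pd.DataFrame(
        {
            "log2fc": lfc,
            "t": t,
            "pvalue": pvalue,
            "padj": padj,
            "significant": (np.abs(lfc) > LFC_THRESHOLD) & (padj < ALPHA),
        },
        index=expr.genes,
    )
    out.attrs["contrast"] = contrast.name
    out.attrs["n_a"] = n_a
    out.attrs["n_b"] = n_b
    out.attrs["prior_df"] = d0
    out.attrs["prior_var"] = s0_sq
    return out


def adjust_bh(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment (monotone, clipped to [0, 1])."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_de(results: pd.DataFrame, lfc: float = LFC_THRESHOLD, alpha: float = ALPHA):
    """Split a DE table into up / down gene sets at strict thresholds."""
    up = set(results.index[(results["log2fc"] > lfc) & (results["padj"] < alpha)])
    down = set(results.index[(results["log2fc"] < -lfc) & (results["padj"] < alpha)])
    return up, down


def build_subtype_signatures(
    pairwise: dict, lfc: float = LFC_THRESHOLD, alpha: float = ALPHA
):
    """Intersect pairwise subtype contrasts into subtype-specific signatures.

    ``pairwise`` maps the ordered pair names ``("PB", "GF")``, ``("PB",
    "INT")`` and ``("INT", "GF")`` to DE tables (log2fc oriented first minus
    second). A gene is X-specific when it is up in X against both other
    subtypes. Returns ``(signatures, provenance)`` where signatures maps
    subtype to a gene set and provenance is a tidy per-gene table for the
    union.
    """
    required = {("PB", "GF"), ("PB", "INT"), ("INT", "GF")}
    if set(pairwise) != required:
        missing = required - set(pairwise)
        raise ValidationError(f"missing pairwise contrasts: {sorted(missing)}")

    def up_in(first: str, second: str) -> set:
        if (first, second) in pairwise:
            up, _ = call_de(pairwise[(first, second)], lfc, alpha)
            return up
        _, down = call_de(pairwise[(second, first)], lfc, alpha)
        return down

    signatures = {
        "PB": up_in("PB", "GF") & up_in("PB", "INT"),
        "GF": up_in("GF", "PB") & up_in("GF", "INT"),
        "INT": up_in("INT", "PB") & up_in("INT", "GF"),
    }
    rows = [
        {"gene": g, "subtype": s} for s in ("PB", "INT", "GF") for g in sorted(signatures[s])
    ]
    provenance = pd.DataFrame(rows, columns=["gene", "subtype"])
    return signatures, provenance


def build_external_gene_sets(
    de_table: pd.DataFrame,
    name: str,
    lfc: float = 1.0,
    alpha: float = 0.05,
    gene_col: str = "gene",
    lfc_col: str = "log2fc",
    padj_col: str = "padj",
):
    """Curate up/down GMT records from an external DE table.

    External curation uses the inclusive threshold |log2fc| >= ``lfc`` with
    padj < ``alpha``. Duplicate symbols collapse to one membership entry.
    """
    for col in (gene_col, lfc_col, padj_col):
        if col not in de_table.columns:
            raise ValidationError(f"external DE table missing column '{col}'")
    sig = de_table[(de_table[lfc_col].abs() >= lfc) & (de_table[padj_col] < alpha)]
    up = tuple(dict.fromkeys(sig.loc[sig[lfc_col] > 0, gene_col]))
    down = tuple(dict.fromkeys(sig.loc[sig[lfc_col] < 0, gene_col]))
    return [
        GeneSet(f"{name}_UP", f"up-regulated in {name}", up),
        GeneSet(f"{name}_DOWN", f"down-regulated in {name}", down),
    ]
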