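"""Synthetic probe-count generator for spatial profiling of cyst epithelium.

The generator emulates the count structure a GeoMx-style targeted panel
produces on segmented epithelial areas of interest (AOIs): several probes
per gene plus a pool of negative-control probes, AOIs nested in slides with
epithelial subtype (PB / INT / GF) and dysplasia grade (LGD / HGD) labels.

Counts follow a negative-binomial (gamma-Poisson) model. Each gene has a
log2 baseline mean; planted subtype-specific and HGD-specific genes add a
fixed log2 effect in the matching AOIs; planted coexpression modules add a
shared per-AOI latent factor scaled by a loading. Each probe of a gene
carries a fixed multiplicative lognormal bias (so geometric-mean collapsing
is the natural estimator), and each AOI has a library-size offset that
scales every probe. HGD and intestinal AOIs draw larger library offsets,
reproducing the correlation of sequencing yield with cellular density that
the normalization chain must remove. Negative probes draw from a background
distribution well below typical gene-probe means.

A :class:`SyntheticTruth` ledger records every planted membership so that
recovery can be scored downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .containers import (
    AOIAnnotation,
    GRADES,
    ProbeCountMatrix,
    SUBTYPES,
    ValidationError,
)

# Study-scale panel geometry: 8584 gene probes over 1829 genes works out to
# 1268 genes with 5 probes and the rest with 4.
_PANEL_GENES = 1829
_PANEL_GENE_PROBES = 8584


def default_design(n_pb_slides: int = 6, n_int_slides: int = 6) -> dict:
    """Cohort design emulating the study: 12 slides, 98 AOIs (50 HGD, 48 LGD).

    PB-predominant slides mix PB-HGD, a little PB-LGD and gastric foveolar
    (GF, uniformly LGD) epithelium; INT-predominant slides mix INT-HGD and
    INT-LGD, with GF regions on two of them.
    """
    design = {}
    for i in range(n_pb_slides):
        slide = f"slide{i + 1:02d}"
        aois = [("PB", "HGD")] * 4 + [("PB", "LGD")] + [("GF", "LGD")] * 3
        if i < 2:  # two slides carry one extra high-grade region
            aois.append(("PB", "HGD"))
        design[slide] = aois
    for i in range(n_int_slides):
        slide = f"slide{i + n_pb_slides + 1:02d}"
        if i < 2:
            aois = [("INT", "HGD")] * 4 + [("INT", "LGD")] * 2 + [("GF", "LGD")] * 2
        else:
            aois = [("INT", "HGD")] * 4 + [("INT", "LGD")] * 4
        design[slide] = aois
    return design


@dataclass
class SimulationConfig:
    """Parameters of the synthetic dataset.

    Effects are in log2 units. ``baseline_log_mean`` is the log2 expected
    count of a typical gene probe at the reference library size;
    ``negative_log_mean`` plays the same role for negative-control probes
    and sits well below it. ``library_size_range`` bounds the per-AOI target
    total count (drawn log-uniformly, with HGD/INT AOIs biased upward).
    """

    subtype_design: Optional[dict] = None  # slide -> list of (subtype, grade)
    n_genes: int = _PANEL_GENES
    probes_per_gene: Optional[int] = None  # None -> mixed 4/5 per panel geometry
    n_negative_probes: int = 75
    baseline_log_mean: float = 4.0
    gene_log_sd: float = 2.0
    negative_log_mean: float = 3.0
    probe_bias_sd: float = 0.25
    dispersion: float = 0.1
    library_size_range: tuple = (60_000, 1_000_000)
    planted_subtype_genes: dict = field(
        default_factory=lambda: {"PB": (25, 2.0), "INT": (25, 2.0), "GF": (25, 2.0)}
    )
    planted_hgd_genes: tuple = (30, 2.0)
    planted_modules: list = field(default_factory=lambda: [(40, 1.5), (30, 1.5), (20, 1.5)])
    seed: int = 0

    def __post_init__(self) -> None:
        if self.subtype_design is None:
            self.subtype_design = default_design()
        if self.n_genes < 1 or self.n_negative_probes < 1:
            raise ValidationError("n_genes and n_negative_probes must be positive")
        if self.probes_per_gene is not None and self.probes_per_gene < 1:
            raise ValidationError("probes_per_gene must be >= 1")
        if self.dispersion <= 0:
            raise ValidationError("dispersion must be > 0")
        lo, hi = self.library_size_range
        if not (0 < lo <= hi):
            raise ValidationError("library_size_range must be positive and ordered")
        for sub, (count, eff) in self.planted_subtype_genes.items():
            if sub not in SUBTYPES:
                raise ValidationError(f"unknown subtype '{sub}' in planted_subtype_genes")
            if count < 0 or not np.isfinite(eff):
                raise ValidationError("planted gene counts must be >=0 with finite effects")
        count, eff = self.planted_hgd_genes
        if count < 0 or not np.isfinite(eff):
            raise ValidationError("planted_hgd_genes must have count >=0 and finite effect")
        for size, loading in self.planted_modules:
            if size < 2 or not np.isfinite(loading):
                raise ValidationError("planted modules need size >=2 and finite loading")
        for slide, aois in self.subtype_design.items():
            for subtype, grade in aois:
                if subtype not in SUBTYPES or grade not in GRADES:
                    raise ValidationError(
                        f"unknown label pair ({subtype}, {grade}) on {slide}"
                    )
                if subtype == "GF" and grade == "HGD":
                    raise ValidationError(
                        f"inconsistent design: label pair (GF, HGD) on {slide}; "
                        "gastric foveolar epithelium is uniformly low grade"
                    )

    # ------------------------------------------------------------------

    def probe_counts_per_gene(self) -> np.ndarray:
        """Number of probes for each gene.

        With the default mixed layout the panel-scale ratio 8584/1829 is
        preserved for any ``n_genes``: a fraction of genes get 5 probes and
        the rest 4.
        """
        if self.probes_per_gene is not None:
            return np.full(self.n_genes, self.probes_per_gene, dtype=int)
        frac5 = _PANEL_GENE_PROBES / _PANEL_GENES - 4.0
        n5 = int(round(self.n_genes * frac5))
        out = np.full(self.n_genes, 4, dtype=int)
        out[:n5] = 5
        return out


@dataclass
class SyntheticTruth:
    """Ground-truth ledger of every planted structure."""

    subtype_genes: dict  # subtype -> tuple of gene symbols
    hgd_genes: tuple
    modules: list  # list of tuples of gene symbols
    module_loadings: list
    library_targets: dict  # aoi_id -> expected total counts
    seed: int

    def planted_union(self) -> set:
        out = set(self.hgd_genes)
        for genes in self.subtype_genes.values():
            out |= set(genes)
        return out

    def to_dict(self) -> dict:
        return {
            "subtype_genes": {k: list(v) for k, v in self.subtype_genes.items()},
            "hgd_genes": list(self.hgd_genes),
            "modules": [list(m) for m in self.modules],
            "module_loadings": [float(x) for x in self.module_loadings],
            "library_targets": {k: float(v) for k, v in self.library_targets.items()},
            "seed": int(self.seed),
        }


def _build_annotation(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for slide in sorted(config.subtype_design):
        aois = config.subtype_design[slide]
        subtypes = [s for s, _ in aois]
        # predominant subtype of the slide, GF never predominates
        counts = {s: subtypes.count(s) for s in ("PB", "INT")}
        slide_subtype = max(counts, key=lambda s: counts[s]) if any(counts.values()) else "GF"
        for i, (subtype, grade) in enumerate(aois):
            rows.append(
                {
                    "aoi_id": f"{slide}_aoi{i + 1:02d}",
                    "slide": slide,
                    "subtype": subtype,
                    "grade": grade,
                    "slide_subtype": slide_subtype,
                }
            )
    table = pd.DataFrame(rows).set_index("aoi_id")
    return table


def simulate_dataset(config: SimulationConfig):
    """Draw one synthetic dataset.

    Returns
    -------
    (ProbeCountMatrix, AOIAnnotation, SyntheticTruth)
        Probe counts with manifest, the AOI design table (including nuclei
        and surface-area covariates correlated with library size), and the
        planted-structure ledger. Identical configs (same seed) reproduce
        identical outputs bit for bit.
    """
    root = np.random.SeedSequence(config.seed)
    ss_design, ss_genes, ss_library, ss_modules, ss_counts, ss_covar = root.spawn(6)
    rng_design = np.random.default_rng(ss_design)
    rng_genes = np.random.default_rng(ss_genes)
    rng_library = np.random.default_rng(ss_library)
    rng_modules = np.random.default_rng(ss_modules)
    rng_counts = np.random.default_rng(ss_counts)
    rng_covar = np.random.default_rng(ss_covar)

    table = _build_annotation(config, rng_design)
    aoi_ids = table.index.to_numpy()
    n_aois = len(aoi_ids)
    genes = np.array([f"G{i + 1:05d}" for i in range(config.n_genes)])

    # --- planted memberships (disjoint between signatures; modules drawn
    # from the remaining background genes)
    perm = rng_genes.permutation(config.n_genes)
    cursor = 0
    subtype_genes = {}
    for subtype in SUBTYPES:
        count, _ = config.planted_subtype_genes.get(subtype, (0, 0.0))
        subtype_genes[subtype] = tuple(genes[perm[cursor : cursor + count]])
        cursor += count
    n_hgd, hgd_eff = config.planted_hgd_genes
    hgd_genes = tuple(genes[perm[cursor : cursor + n_hgd]])
    cursor += n_hgd
    modules = []
    for size, _ in config.planted_modules:
        modules.append(tuple(genes[perm[cursor : cursor + size]]))
        cursor += size
    if cursor > config.n_genes:
        raise ValidationError("more planted genes requested than n_genes")

    # --- gene-level log2 means and per-AOI effect matrix (genes x AOIs)
    gene_mu = config.baseline_log_mean + config.gene_log_sd * rng_genes.standard_normal(
        config.n_genes
    )
    gene_index = pd.Index(genes)
    log2_effect = np.zeros((config.n_genes, n_aois))
    subtype_of = table["subtype"].to_numpy()
    grade_of = table["grade"].to_numpy()
    for subtype in SUBTYPES:
        _, eff = config.planted_subtype_genes.get(subtype, (0, 0.0))
        rows = gene_index.get_indexer(list(subtype_genes[subtype]))
        if len(rows):
            log2_effect[np.ix_(rows, np.flatnonzero(subtype_of == subtype))] += eff
    rows = gene_index.get_indexer(list(hgd_genes))
    if len(rows):
        log2_effect[np.ix_(rows, np.flatnonzero(grade_of == "HGD"))] += hgd_eff
    for (size, loading), members in zip(config.planted_modules, modules):
        z = rng_modules.standard_normal(n_aois)
        rows = gene_index.get_indexer(list(members))
        log2_effect[rows, :] += loading * z[None, :]

    # --- library targets: log-uniform, with HGD and INT AOIs biased upward
    lo, hi = np.log(config.library_size_range[0]), np.log(config.library_size_range[1])
    u = rng_library.uniform(size=n_aois)
    dense = (grade_of == "HGD") | (subtype_of == "INT")
    u = np.where(dense, 0.4 + 0.6 * u, 0.6 * u)
    library_target = np.exp(lo + (hi - lo) * u)

    # --- probe layout and biases
    probes_per_gene = config.probe_counts_per_gene()
    gene_row = np.repeat(np.arange(config.n_genes), probes_per_gene)
    probe_ids = []
    for gi, npr in enumerate(probes_per_gene):
        probe_ids.extend(f"{genes[gi]}_p{k + 1}" for k in range(npr))
    probe_ids.extend(f"NEG_p{k + 1}" for k in range(config.n_negative_probes))
    n_gene_probes = len(gene_row)
    probe_bias = np.exp(config.probe_bias_sd * rng_genes.standard_normal(n_gene_probes))

    # --- expected means per (probe, AOI)
    mean_gene = probe_bias[:, None] * np.exp2(gene_mu[gene_row][:, None] + log2_effect[gene_row, :])
    mean_neg = np.full((config.n_negative_probes, n_aois), np.exp2(config.negative_log_mean))
    mean_all = np.vstack([mean_gene, mean_neg])
    scale = library_target / mean_all.sum(axis=0)
    mean_all *= scale[None, :]

    # --- gamma-Poisson draw (negative binomial with dispersion alpha)
    r = 1.0 / config.dispersion
    lam = rng_counts.gamma(shape=r, scale=mean_all / r)
    counts = rng_counts.poisson(lam)

    counts_df = pd.DataFrame(counts, index=pd.Index(probe_ids, name="probe_id"), columns=aoi_ids)
    manifest = pd.DataFrame(
        {
            "gene": np.concatenate([genes[gene_row], [""] * config.n_negative_probes]),
            "is_negative": np.concatenate(
                [np.zeros(n_gene_probes, bool), np.ones(config.n_negative_probes, bool)]
            ),
        },
        index=counts_df.index,
    )

    # --- covariates correlated with library size (median nuclei ~600/AOI)
    nuclei = np.maximum(
        1,
        np.round(
            library_target / 1000.0 * np.exp(0.3 * rng_covar.standard_normal(n_aois))
        ).astype(int),
    )
    area = np.round(nuclei * np.exp(0.2 * rng_covar.standard_normal(n_aois)) * 250.0, 1)
    table = table.assign(nuclei=nuclei, area=area)

    truth = SyntheticTruth(
        subtype_genes=subtype_genes,
        hgd_genes=hgd_genes,
        modules=modules,
        module_loadings=[loading for _, loading in config.planted_modules],
        library_targets=dict(zip(aoi_ids, library_target)),
        seed=config.seed,
    )
    return ProbeCountMatrix(counts_df, manifest), AOIAnnotation(table), truth
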