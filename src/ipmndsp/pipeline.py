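"""End-to-end orchestration: configuration, stage sequencing, run manifest.

``run_pipeline`` executes qc -> normalize -> de (three subtype contrasts,
the pooled HGD-vs-LGD contrast, and all six pairwise subgroup contrasts)
-> subtype signatures -> preranked GSEA -> coexpression network -> PCA and
risk clustering, writing every product as TSV/GMT/JSON plus a manifest
recording parameters, seeds and per-stage dimensions. Identical config and
inputs yield byte-identical outputs: all randomness flows from explicit
seeds and floats are written with a fixed format.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .containers import AOIAnnotation, GeneExpressionMatrix, ProbeCountMatrix, ValidationError
from .de import Contrast, build_subtype_signatures, call_de, fit_contrast
from .enrichment import gsea_preranked, hypergeometric_enrich
from .explore import cut_clusters, hierarchical_cluster, pca_aois, to_newick
from .io import (
    FLOAT_FORMAT,
    read_annotation,
    read_gmt,
    read_probe_counts,
    write_expression,
    write_gmt,
    write_json,
)
from .containers import GeneSet
from .network import annotate_overlays, build_network, filter_clusters, leiden_communities
from .normalize import normalize_pipeline
from .qc import run_qc


@dataclass
class PipelineConfig:
    """All thresholds and seeds of the analysis, with study defaults."""

    # inputs
    counts_path: str = ""
    manifest_path: str = ""
    annotation_path: str = ""
    gene_sets_path: str = ""  # GMT; optional (GSEA + cluster enrichment skipped if empty)
    output_dir: str = "results"
    # QC
    min_counts: int = 100_000
    min_snauc: float = 0.65
    max_undetected_frac: float = 0.80
    min_detected_frac: float = 0.20
    # DE
    lfc_threshold: float = 1.0
    alpha: float = 0.05
    # GSEA
    gsea_n_perm: int = 1000
    gsea_min_size: int = 5
    gsea_max_size: int = 500
    gsea_seed: int = 0
    # network
    rho_min: float = 0.7
    q_max: float = 0.01
    network_n_perm: int = 10_000
    network_max_null_size: int = 1_000_000
    leiden_resolution: float = 0.5
    min_cluster_size: int = 10
    network_seed: int = 0
    # exploration
    n_risk_clusters: int = 2

    def validate(self) -> None:
        if not (0.0 <= self.min_snauc <= 1.0):
            raise ValidationError(f"min_snauc must be in [0, 1], got {self.min_snauc}")
        for name in ("max_undetected_frac", "min_detected_frac", "alpha", "q_max"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        if not (0.0 <= self.rho_min <= 1.0):
            raise ValidationError(f"rho_min must be in [0, 1], got {self.rho_min}")
        if self.min_counts < 0 or self.lfc_threshold < 0:
            raise ValidationError("min_counts and lfc_threshold must be non-negative")
        if self.gsea_n_perm < 100:
            raise ValidationError("gsea_n_perm must be at least 100")
        if self.network_n_perm < 1000:
            raise ValidationError("network_n_perm must be at least 1000")
        if self.leiden_resolution <= 0 or self.min_cluster_size < 1:
            raise ValidationError("leiden_resolution must be > 0 and min_cluster_size >= 1")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        config = cls(**raw)
        config.validate()
        return config

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


SUBTYPE_CONTRASTS = [
    Contrast("PB_vs_GF", {"subtype": "PB"}, {"subtype": "GF"}),
    Contrast("PB_vs_INT", {"subtype": "PB"}, {"subtype": "INT"}),
    Contrast("INT_vs_GF", {"subtype": "INT"}, {"subtype": "GF"}),
]

GRADE_CONTRAST = Contrast("HGD_vs_LGD", {"grade": "HGD"}, {"grade": "LGD"})

SUBGROUPS = ["PB-HGD", "PB-LGD", "INT-HGD", "INT-LGD"]


def subgroup_contrasts() -> list:
    """The six pairwise contrasts between histopathologic subgroups.

    Subgroups combine the slide's predominant subtype with the AOI grade
    (PB-HGD, PB-LGD, INT-HGD, INT-LGD).
    """
    out = []
    for a, b in itertools.combinations(SUBGROUPS, 2):
        sa, ga = a.split("-")
        sb, gb = b.split("-")
        out.append(
            Contrast(
                f"{a}_vs_{b}".replace("-", ""),
                {"slide_subtype": sa, "grade": ga},
                {"slide_subtype": sb, "grade": gb},
            )
        )
    return out


def _write_de(table: pd.DataFrame, path: Path) -> None:
    out = table.copy()
    out["significant"] = out["significant"].astype(bool)
    with open(path, "w") as fh:
        fh.write(f"# contrast: {table.attrs.get('contrast', '')}\n")
        out.to_csv(fh, sep="\t", index_label="gene", float_format=FLOAT_FORMAT)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns the run manifest (also written).

    Stage failures abort with the stage name prefixed to the error message.
    """
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "parameters": asdict(config),
        "stages": {},
    }

    def stage(name):
        def wrap(fn, *args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"stage '{name}' failed: {exc}") from exc

        return wrap

    # ---- load inputs ----
    pcm = stage("load")(read_probe_counts, config.counts_path, config.manifest_path)
    annotation = stage("load")(read_annotation, config.annotation_path)
    missing = set(pcm.aoi_ids) - set(annotation.aoi_ids)
    if missing:
        raise RuntimeError(f"stage 'load' failed: AOIs missing from annotation: {sorted(missing)[:5]}")
    manifest["stages"]["load"] = {
        "n_probes": int(pcm.counts.shape[0]),
        "n_aois": int(pcm.counts.shape[1]),
        "n_negative_probes": pcm.n_negative_probes,
    }

    # ---- qc ----
    expr_raw, pcm_f, records, lods = stage("qc")(
        run_qc,
        pcm,
        min_counts=config.min_counts,
        min_snauc=config.min_snauc,
        max_undetected_frac=config.max_undetected_frac,
        min_detected_frac=config.min_detected_frac,
    )
    annotation = annotation.subset(expr_raw.aoi_ids)
    write_json({"aois": [r.to_dict() for r in records]}, outdir / "qc_report.json")
    write_expression(expr_raw, outdir / "expression_collapsed_raw.tsv")
    manifest["stages"]["qc"] = {
        "n_aois_in": len(records),
        "n_aois_pass": int(sum(r.passed for r in records)),
        "n_probes_pass": int(pcm_f.counts.shape[0]),
        "n_genes_pass": int(expr_raw.values.shape[0]),
    }

    # ---- normalize ----
    stages_norm = stage("normalize")(normalize_pipeline, expr_raw, pcm_f)
    expr_log = stages_norm["log"]
    write_expression(stages_norm["quantile_normalized"], outdir / "expression_normalized.tsv")
    write_expression(expr_log, outdir / "expression_log.tsv")
    manifest["stages"]["normalize"] = {
        "order": ["background_subtracted", "scaled", "quantile_normalized", "log"],
        "n_genes": int(expr_log.values.shape[0]),
        "n_aois": int(expr_log.values.shape[1]),
    }

    # ---- differential expression ----
    de_tables: dict = {}
    contrasts = SUBTYPE_CONTRASTS + [GRADE_CONTRAST] + subgroup_contrasts()
    for contrast in contrasts:
        de_tables[contrast.name] = stage("de")(fit_contrast, expr_log, annotation, contrast)
        _write_de(de_tables[contrast.name], outdir / f"de_{contrast.name}.tsv")
    manifest["stages"]["de"] = {
        "contrasts": [c.name for c in contrasts],
        "n_significant": {
            name: int(table["significant"].sum()) for name, table in de_tables.items()
        },
    }

    # ---- subtype signatures ----
    pairwise = {
        ("PB", "GF"): de_tables["PB_vs_GF"],
        ("PB", "INT"): de_tables["PB_vs_INT"],
        ("INT", "GF"): de_tables["INT_vs_GF"],
    }
    signatures, provenance = stage("signatures")(
        build_subtype_signatures, pairwise, config.lfc_threshold, config.alpha
    )
    hgd_up, hgd_down = call_de(de_tables["HGD_vs_LGD"], config.lfc_threshold, config.alpha)
    sig_sets = [
        GeneSet(f"{s}_SPECIFIC", f"{s}-specific subtype signature", tuple(sorted(signatures[s])))
        for s in ("PB", "INT", "GF")
    ] + [
        GeneSet("HGD_UP", "up in HGD vs LGD", tuple(sorted(hgd_up))),
        GeneSet("HGD_DOWN", "down in HGD vs LGD", tuple(sorted(hgd_down))),
    ]
    write_gmt(sig_sets, outdir / "signatures.gmt")
    provenance.to_csv(outdir / "subtype_signature_genes.tsv", sep="\t", index=False)
    manifest["stages"]["signatures"] = {
        "n_subtype_union": int(len(set(provenance["gene"]))),
        "per_subtype": {s: int(len(signatures[s])) for s in signatures},
        "n_hgd_up": len(hgd_up),
        "n_hgd_down": len(hgd_down),
    }

    # ---- GSEA ----
    gene_sets = read_gmt(config.gene_sets_path) if config.gene_sets_path else []
    if gene_sets:
        ranked = de_tables["HGD_vs_LGD"]["log2fc"]
        gsea = stage("gsea")(
            gsea_preranked,
            ranked,
            gene_sets,
            n_perm=config.gsea_n_perm,
            min_size=config.gsea_min_size,
            max_size=config.gsea_max_size,
            seed=config.gsea_seed,
        )
        out = gsea.copy()
        out["leading_edge"] = out["leading_edge"].map(lambda genes: ",".join(genes))
        out.to_csv(outdir / "gsea_HGD_vs_LGD.tsv", sep="\t", float_format=FLOAT_FORMAT)
        manifest["stages"]["gsea"] = {
            "n_sets_tested": int(len(gsea)),
            "n_significant": int((gsea["padj"] < config.alpha).sum()),
        }
    else:
        manifest["stages"]["gsea"] = {"skipped": "no gene-set GMT provided"}

    # ---- network ----
    net = stage("network")(
        build_network,
        expr_log,
        rho_min=config.rho_min,
        q_max=config.q_max,
        n_perm=config.network_n_perm,
        seed=config.network_seed,
        max_null_size=config.network_max_null_size,
    )
    cluster_table = pd.DataFrame(columns=["cluster", "retained"])
    if net.n_nodes:
        labels = stage("network")(
            leiden_communities, net, resolution=config.leiden_resolution, seed=config.network_seed
        )
        cluster_table = filter_clusters(labels, min_size=config.min_cluster_size)
        groups = {
            "PB_HGD": {"slide_subtype": "PB", "grade": "HGD"},
            "INT_HGD": {"slide_subtype": "INT", "grade": "HGD"},
        }
        try:
            annotate_overlays(
                net,
                expr_log,
                annotation,
                groups,
                external_sets=gene_sets,
                hgd_log2fc=de_tables["HGD_vs_LGD"]["log2fc"],
            )
        except ValidationError:
            pass  # small designs may lack a subgroup; overlays are optional
        # per-cluster enrichment against provided sets
        if gene_sets:
            universe = set(expr_log.genes)
            enrich_rows = []
            retained = cluster_table[cluster_table["retained"]]
            for cid in sorted(retained["cluster"].unique()):
                members = set(retained.index[retained["cluster"] == cid])
                res = hypergeometric_enrich(members, gene_sets, universe)
                res = res.assign(cluster=int(cid))
                enrich_rows.append(res.reset_index())
            if enrich_rows:
                pd.concat(enrich_rows, ignore_index=True).to_csv(
                    outdir / "cluster_enrichment.tsv",
                    sep="\t",
                    index=False,
                    float_format=FLOAT_FORMAT,
                )
    net.edges.to_csv(outdir / "network_edges.tsv", sep="\t", index=False, float_format=FLOAT_FORMAT)
    cluster_table.to_csv(outdir / "network_clusters.tsv", sep="\t", index_label="gene")
    if net.n_nodes:
        import networkx as nx

        nx.write_graphml(net.to_networkx(), outdir / "network.graphml")
    manifest["stages"]["network"] = {
        "n_nodes": net.n_nodes,
        "n_edges": net.n_edges,
        "n_clusters": int(cluster_table["cluster"].nunique()) if len(cluster_table) else 0,
        "n_retained_clusters": int(
            cluster_table.loc[cluster_table["retained"], "cluster"].nunique()
        )
        if len(cluster_table)
        else 0,
    }

    # ---- exploration ----
    scores, loadings, var_ratio = stage("explore")(pca_aois, expr_log, 10)
    scores.to_csv(outdir / "pca_scores.tsv", sep="\t", index_label="aoi_id", float_format=FLOAT_FORMAT)
    with open(outdir / "pca_variance.tsv", "w") as fh:
        fh.write("component\tvariance_fraction\n")
        for i, v in enumerate(var_ratio):
            fh.write(f"PC{i + 1}\t{v:.10g}\n")
    risk_genes = sorted(hgd_up | hgd_down)
    explore_manifest = {"n_components": int(scores.shape[1])}
    if len(risk_genes) >= 2 and expr_log.values.shape[1] >= config.n_risk_clusters:
        sub = GeneExpressionMatrix(expr_log.values.loc[risk_genes], stage="log")
        linkage, labels_, order = hierarchical_cluster(sub.values, axis="columns", zscore=True)
        risk = cut_clusters(linkage, labels_, config.n_risk_clusters)
        risk.to_csv(outdir / "risk_clusters.tsv", sep="\t", index_label="aoi_id", header=["cluster"])
        with open(outdir / "risk_dendrogram.nwk", "w") as fh:
            fh.write(to_newick(linkage, labels_) + "\n")
        explore_manifest["n_risk_genes"] = len(risk_genes)
        explore_manifest["risk_cluster_sizes"] = (
            risk.value_counts().sort_index().astype(int).tolist()
        )
    manifest["stages"]["explore"] = explore_manifest

    write_json(manifest, outdir / "manifest.json")
    return manifest
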