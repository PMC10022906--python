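"""Reading and writing the pipeline's plain-text formats.

All tables are TSV. Derived tables carry a small ``# key: value`` header
comment block recording stage provenance so that re-loaded matrices keep
their stage tag. Gene sets use the GMT format (set name, description,
member genes, tab separated).
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .containers import AOIAnnotation, GeneExpressionMatrix, GeneSet, ProbeCountMatrix

FLOAT_FORMAT = "%.10g"


# ---------------------------------------------------------------------------
# probe counts + manifest

def write_probe_counts(pcm: ProbeCountMatrix, counts_path, manifest_path) -> None:
    pcm.counts.to_csv(counts_path, sep="\t", index_label="probe_id")
    pcm.manifest.to_csv(manifest_path, sep="\t", index_label="probe_id")


def read_probe_counts(counts_path, manifest_path) -> ProbeCountMatrix:
    counts = pd.read_csv(counts_path, sep="\t", index_col="probe_id")
    manifest = pd.read_csv(manifest_path, sep="\t", index_col="probe_id")
    manifest["is_negative"] = manifest["is_negative"].astype(bool)
    manifest["gene"] = manifest["gene"].fillna("")
    return ProbeCountMatrix(counts.astype(int), manifest)


# ---------------------------------------------------------------------------
# AOI annotation

def write_annotation(ann: AOIAnnotation, path) -> None:
    ann.table.to_csv(path, sep="\t", index_label="aoi_id")


def read_annotation(path) -> AOIAnnotation:
    table = pd.read_csv(path, sep="\t", index_col="aoi_id")
    return AOIAnnotation(table)


# ---------------------------------------------------------------------------
# gene expression matrices (with stage header)

def write_expression(expr: GeneExpressionMatrix, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# stage: {expr.stage}\n")
        expr.values.to_csv(fh, sep="\t", index_label="gene", float_format=FLOAT_FORMAT)


def read_expression(path) -> GeneExpressionMatrix:
    path = Path(path)
    stage = "collapsed_raw"
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("# stage:"):
            stage = first.split(":", 1)[1].strip()
    values = pd.read_csv(path, sep="\t", index_col="gene", comment="#")
    return GeneExpressionMatrix(values, stage)


# ---------------------------------------------------------------------------
# GMT gene sets

def read_gmt(path) -> list:
    sets = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line (need >=3 fields): {line[:80]!r}")
            sets.append(GeneSet(fields[0], fields[1], tuple(g for g in fields[2:] if g)))
    return sets


def write_gmt(sets, path) -> None:
    with open(path, "w") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, gs.description, *gs.genes]) + "\n")


# ---------------------------------------------------------------------------
# misc JSON helpers

def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path):
    with open(path) as fh:
        return json.load(fh)
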