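"""Core in-memory containers for the spatial profiling pipeline.

The pipeline operates on three tables that mirror the files exported from a
digital spatial profiler run:

* a probe-count matrix (probes x AOIs) plus a probe manifest mapping each
  probe to a gene symbol and flagging negative-control probes,
* an AOI annotation table (slide, epithelial subtype, dysplasia grade,
  nuclei count, surface area),
* derived gene-expression matrices carrying a ``stage`` tag that records
  where in the normalization chain the values sit.

All containers wrap :class:`pandas.DataFrame` so that downstream modules can
use ordinary pandas indexing while the wrappers enforce the invariants the
pipeline relies on (non-negative counts, unique gene symbols, at least one
negative probe, aligned identifiers).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SUBTYPES = ("PB", "INT", "GF")
GRADES = ("LGD", "HGD")

#: normalization stages in pipeline order
STAGES = (
    "collapsed_raw",
    "background_subtracted",
    "scaled",
    "quantile_normalized",
    "log",
)


class ValidationError(ValueError):
    """Raised when a container violates one of its structural invariants."""


@dataclass
class ProbeCountMatrix:
    """Raw integer probe counts with a probe manifest.

    Parameters
    ----------
    counts
        Probes x AOIs matrix of non-negative integer counts. The row index
        holds probe identifiers, the columns AOI identifiers.
    manifest
        One row per probe (same index as ``counts``) with columns ``gene``
        (symbol, empty/NA for negative probes) and ``is_negative`` (bool).
    """

    counts: pd.DataFrame
    manifest: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.manifest.index):
            raise ValidationError("counts and manifest must share the same probe index")
        if (np.asarray(self.counts.values) < 0).any():
            raise ValidationError("probe counts must be non-negative")
        if "gene" not in self.manifest.columns or "is_negative" not in self.manifest.columns:
            raise ValidationError("manifest requires 'gene' and 'is_negative' columns")
        neg = self.manifest["is_negative"].astype(bool)
        if int(neg.sum()) < 1:
            raise ValidationError("at least one negative-control probe is required")
        genes = self.manifest.loc[~neg, "gene"]
        if genes.isna().any() or (genes == "").any():
            raise ValidationError("every gene probe must map to exactly one gene symbol")

    # -- convenience views ------------------------------------------------

    @property
    def aoi_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def is_negative(self) -> pd.Series:
        return self.manifest["is_negative"].astype(bool)

    @property
    def gene_probe_counts(self) -> pd.DataFrame:
        """Counts restricted to gene-targeting probes."""
        return self.counts.loc[~self.is_negative]

    @property
    def negative_probe_counts(self) -> pd.DataFrame:
        """Counts restricted to negative-control probes."""
        return self.counts.loc[self.is_negative]

    @property
    def n_negative_probes(self) -> int:
        return int(self.is_negative.sum())

    def subset_aois(self, aoi_ids) -> "ProbeCountMatrix":
        return ProbeCountMatrix(self.counts[list(aoi_ids)], self.manifest)

    def subset_probes(self, probe_ids) -> "ProbeCountMatrix":
        idx = pd.Index(probe_ids)
        return ProbeCountMatrix(self.counts.loc[idx], self.manifest.loc[idx])


@dataclass
class AOIAnnotation:
    """Per-AOI design labels and QC covariates.

    ``table`` is indexed by AOI id with columns ``slide``, ``subtype``
    (PB / INT / GF), ``grade`` (LGD / HGD), ``slide_subtype`` (the slide's
    predominant histologic subtype, used for subgroup contrasts), ``nuclei``
    and ``area``.
    """

    table: pd.DataFrame

    REQUIRED = ("slide", "subtype", "grade")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.table.columns:
                raise ValidationError(f"annotation missing required column '{col}'")
        bad_sub = set(self.table["subtype"]) - set(SUBTYPES)
        if bad_sub:
            raise ValidationError(f"unknown subtype labels: {sorted(bad_sub)}")
        bad_grade = set(self.table["grade"]) - set(GRADES)
        if bad_grade:
            raise ValidationError(f"unknown grade labels: {sorted(bad_grade)}")
        gf_hgd = self.table[(self.table["subtype"] == "GF") & (self.table["grade"] == "HGD")]
        if len(gf_hgd):
            raise ValidationError(
                "inconsistent design: label pair (GF, HGD) requested for AOIs "
                f"{list(gf_hgd.index[:5])}; gastric foveolar epithelium is uniformly low grade"
            )

    @property
    def aoi_ids(self) -> pd.Index:
        return self.table.index

    def subset(self, aoi_ids) -> "AOIAnnotation":
        return AOIAnnotation(self.table.loc[list(aoi_ids)])

    def subgroup(self) -> pd.Series:
        """Histopathologic subgroup label, e.g. ``PB-HGD``.

        Specimens are partitioned by the slide's predominant subtype, so the
        subgroup combines ``slide_subtype`` with the AOI grade.
        """
        if "slide_subtype" not in self.table.columns:
            raise ValidationError("annotation lacks 'slide_subtype' needed for subgroups")
        return self.table["slide_subtype"].str.cat(self.table["grade"], sep="-")


@dataclass
class GeneExpressionMatrix:
    """Genes x AOIs expression values with a provenance stage tag."""

    values: pd.DataFrame
    stage: str = "collapsed_raw"

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValidationError(f"unknown stage '{self.stage}'; expected one of {STAGES}")
        if self.values.index.has_duplicates:
            raise ValidationError("gene symbols must be unique")
        if self.stage != "log" and (np.asarray(self.values.values) < 0).any():
            raise ValidationError(f"negative values not allowed at stage '{self.stage}'")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def aoi_ids(self) -> pd.Index:
        return self.values.columns

    def with_values(self, values: pd.DataFrame, stage: str) -> "GeneExpressionMatrix":
        return GeneExpressionMatrix(values, stage)


@dataclass
class AOIQCRecord:
    """Per-AOI quality-control metrics and the pass/fail decision."""

    aoi_id: str
    total_counts: int
    snauc: float
    lod: float
    pct_probes_detected: float
    passed: bool
    reasons: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "aoi_id": self.aoi_id,
            "total_counts": int(self.total_counts),
            "snauc": float(self.snauc),
            "lod": float(self.lod),
            "pct_probes_detected": float(self.pct_probes_detected),
            "passed": bool(self.passed),
            "reasons": list(self.reasons),
        }


@dataclass
class GeneSet:
    """A named gene set (one GMT record)."""

    name: str
    description: str
    genes: tuple

    def __post_init__(self) -> None:
        self.genes = tuple(dict.fromkeys(self.genes))  # dedupe, keep order
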