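import numpy as np
import pandas as pd
import pytest

from ipmndsp import SimulationConfig, simulate_dataset
from ipmndsp.containers import AOIAnnotation, GeneExpressionMatrix


def flat_design(n_slides: int, aois_per_slide: int, subtype: str = "PB", grade: str = "LGD"):
    """A uniform design: every AOI the same (subtype, grade)."""
    return {f"s{i:02d}": [(subtype, grade)] * aois_per_slide for i in range(n_slides)}


def two_group_design(n_per_group: int = 10):
    """One slide of high-grade and one of low-grade PB AOIs."""
    return {"sA": [("PB", "HGD")] * n_per_group, "sB": [("PB", "LGD")] * n_per_group}


def expressed_config(**overrides) -> SimulationConfig:
    """A benchmark configuration where genes sit well above background.

    Used for method-performance tests (differential expression, network
    recovery) where the quantity under test is the statistic, not the
    detection filter.
    """
    defaults = dict(
        baseline_log_mean=6.0,
        gene_log_sd=1.5,
        library_size_range=(300_000, 900_000),
        planted_subtype_genes={},
        planted_hgd_genes=(0, 0.0),
        planted_modules=[],
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def small_dataset():
    """A small study-structured dataset shared across read-only tests."""
    from ipmndsp import default_design

    config = SimulationConfig(
        subtype_design=default_design(2, 2),
        n_genes=300,
        planted_subtype_genes={"PB": (10, 2.0), "INT": (10, 2.0), "GF": (10, 2.0)},
        planted_hgd_genes=(10, 2.0),
        planted_modules=[(15, 1.5)],
        baseline_log_mean=5.0,
        gene_log_sd=1.5,
        library_size_range=(150_000, 600_000),
        seed=11,
    )
    return simulate_dataset(config)


def expr_matrix(values, stage="log", genes=None, aois=None) -> GeneExpressionMatrix:
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    aois = aois or [f"a{j}" for j in range(values.shape[1])]
    return GeneExpressionMatrix(pd.DataFrame(values, index=genes, columns=aois), stage)


def make_probe_matrix(gene_rows, neg_rows, aois=None, genes=None):
    """Small probe-count matrix: one probe per entry of gene_rows."""
    from ipmndsp import ProbeCountMatrix

    n_aoi = len(gene_rows[0])
    aois = aois or [f"a{j}" for j in range(n_aoi)]
    genes = genes or [f"G{i:03d}" for i in range(len(gene_rows))]
    probes = [f"{g}_p1" for g in genes] + [f"NEG_p{k}" for k in range(len(neg_rows))]
    counts = pd.DataFrame(list(gene_rows) + list(neg_rows), index=probes, columns=aois)
    manifest = pd.DataFrame(
        {
            "gene": genes + [""] * len(neg_rows),
            "is_negative": [False] * len(gene_rows) + [True] * len(neg_rows),
        },
        index=probes,
    )
    return ProbeCountMatrix(counts, manifest)


def annotation_frame(groups: dict) -> AOIAnnotation:
    """Build an annotation from {aoi_id: (subtype, grade)}; one slide."""
    table = pd.DataFrame(
        {
            "slide": "s0",
            "subtype": [v[0] for v in groups.values()],
            "grade": [v[1] for v in groups.values()],
        },
        index=pd.Index(groups.keys(), name="aoi_id"),
    )
    return AOIAnnotation(table)
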