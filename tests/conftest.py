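import numpy as np
import pandas as pd
import pytest
from scipy import sparse

from step_profiler import LabeledCounts, QuantTable


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_quant(values, probe=2, comp=2, protein_ids=None):
    """Build a QuantTable from a dense array with the first `probe` columns
    as probe channels and the rest as competition channels."""
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    assert m == probe + comp
    channels = [f"probe_{i}" for i in range(probe)] + [f"comp_{i}" for i in range(comp)]
    groups = {c: ("probe" if c.startswith("probe") else "competition") for c in channels}
    ids = protein_ids or [f"P{i}" for i in range(n)]
    return QuantTable(pd.DataFrame(values, index=ids, columns=channels), groups)


@pytest.fixture
def small_quant():
    return make_quant(
        [
            [100.0, 110.0, 50.0, 55.0],
            [200.0, 210.0, 205.0, 195.0],
            [80.0, 85.0, 90.0, 88.0],
        ]
    )


@pytest.fixture
def tiny_counts():
    # 3 genes x 4 cells, 2 cell types
    mat = np.array(
        [
            [2, 0, 5, 1],
            [8, 4, 0, 3],
            [0, 0, 0, 0],
        ]
    )
    return LabeledCounts(
        gene_ids=["g0", "g1", "g2"],
        counts=sparse.csr_matrix(mat),
        cell_labels=["A", "A", "B", "B"],
    )


def demo_pipeline_config(outdir, seed=7, **overrides):
    cfg = {
        "seed": seed,
        "outdir": str(outdir),
        "simulate": {
            "chemo": {
                "n_proteins": 400,
                "n_true_targets": 30,
                "planted_log2fc": 2.0,
                "intensity_cv": 0.1,
            },
            "scrna": {
                "cell_types": ["PT", "DCT", "LOH", "Endothelial"],
                "cells_per_type": 60,
                "n_genes": 500,
                "baseline_mean": 1.0,
                "dispersion": 2.0,
                "home_celltype": "PT",
                "enrichment_fold": 4.0,
            },
            "genesets": {
                "n_sets": 20,
                "set_size_range": [8, 40],
                "planted_query_overlap": 15,
            },
        },
        "gate": {"fc_thresh": 1.2, "p_thresh": 0.05},
    }
    cfg.update(overrides)
    return cfg
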