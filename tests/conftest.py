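import warnings

import numpy as np
import pandas as pd
import pytest

from blastohet import (
    CountMatrix,
    SyntheticConfig,
    generate_dataset,
    log_transform,
    normalize,
    size_factors,
)

warnings.filterwarnings("ignore", category=UserWarning)


def make_config(**kw) -> SyntheticConfig:
    """Small, fast study configuration for unit tests."""
    base = dict(
        n_embryos_per_stage={4: 8},
        n_genes=500,
        n_spikeins=30,
        n_batches=1,
        seed=0,
    )
    base.update(kw)
    return SyntheticConfig(**base)


@pytest.fixture(scope="session")
def default_dataset():
    """One default-config dataset shared across read-only tests."""
    return generate_dataset(SyntheticConfig(seed=11))


@pytest.fixture()
def small_dataset():
    return generate_dataset(make_config(seed=5))


@pytest.fixture()
def small_normalized(small_dataset):
    matrix, truth = small_dataset
    nm = normalize(matrix, size_factors(matrix))
    return matrix, truth, nm


def tiny_count_matrix(values, spikein=None, mito=None, stage=4, embryos=None, batches=None):
    """Build a CountMatrix from a plain array with minimal metadata."""
    values = np.asarray(values)
    n_genes, n_cells = values.shape
    spikein = spikein if spikein is not None else [False] * n_genes
    mito = mito if mito is not None else [False] * n_genes
    genes = pd.DataFrame(
        {"is_spikein": spikein, "is_mito": mito},
        index=pd.Index([f"g{i}" for i in range(n_genes)], name="gene_id"),
    )
    embryos = embryos if embryos is not None else [f"e{j // 2}" for j in range(n_cells)]
    batches = batches if batches is not None else ["b1"] * n_cells
    cells = pd.DataFrame(
        {
            "embryo": embryos,
            "stage": [stage] * n_cells,
            "batch": batches,
            "division_pattern": ["NA"] * n_cells,
        },
        index=pd.Index([f"c{j}" for j in range(n_cells)], name="cell_id"),
    )
    return CountMatrix(values=values, genes=genes, cells=cells)
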