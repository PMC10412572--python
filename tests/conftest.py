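import numpy as np
import pandas as pd
import pytest

import crosscell as cc


@pytest.fixture(scope="session")
def default_pair():
    """One default-v1 paired dataset (seed 1), shared across tests."""
    return cc.generate_species_pair(cc.default_config())


@pytest.fixture(scope="session")
def default_hvg(default_pair):
    """HVG tables, bijection and shared pairs for the default pair."""
    pair = default_pair
    bij = cc.filter_one_to_one(pair.orthologs)
    hvg_a = cc.select_hvgs_mean_cutoff(
        cc.compute_gene_dispersion(pair.matrix_a), list(bij.rows["gene_a"]))
    hvg_b = cc.select_hvgs_mean_cutoff(
        cc.compute_gene_dispersion(pair.matrix_b), list(bij.rows["gene_b"]))
    shared = cc.intersect_homologous_hvgs(hvg_a, hvg_b, bij)
    return {"bijection": bij, "hvg_a": hvg_a, "hvg_b": hvg_b, "shared": shared}


@pytest.fixture
def small_counts():
    """A tiny deterministic counts matrix: 4 genes x 6 cells."""
    values = np.array([
        [5, 0, 1, 2, 0, 3],
        [0, 0, 0, 0, 0, 0],
        [1, 1, 1, 1, 1, 1],
        [2, 4, 0, 1, 3, 5],
    ], dtype=float)
    return cc.ExpressionMatrix("mouse", ["g1", "g2", "g3", "g4"],
                               [f"c{i}" for i in range(6)], "counts", values)


def random_counts(seed: int, n_genes: int = 50, n_cells: int = 20,
                  species: str = "sp") -> cc.ExpressionMatrix:
    rng = np.random.default_rng(seed)
    mu = np.exp(rng.normal(np.log(0.8), 1.0, n_genes))
    counts = rng.negative_binomial(
        2.0, 2.0 / (2.0 + np.tile(mu[:, None], (1, n_cells)))).astype(float)
    return cc.ExpressionMatrix(species, [f"g{i:03d}" for i in range(n_genes)],
                               [f"c{i:03d}" for i in range(n_cells)],
                               "counts", counts)


@pytest.fixture
def ortholog_table():
    rows = pd.DataFrame({
        "gene_a": ["a1", "a2", "a3", "a4", "a4"],
        "gene_b": ["b1", "b2", "b3", "b4", "b5"],
        "homology_type": ["one2one", "one2many", "one2one", "one2one", "one2one"],
        "confidence": [1, 1, 0, 1, 1],
    })
    return cc.OrthologTable(rows)
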