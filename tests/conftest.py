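"""Shared fixtures: panels, random count matrices, small synthetic truths."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from gabafc import ExpressionMatrix, SyntheticTruth, default_panel


@pytest.fixture(scope="session")
def panel():
    return default_panel()


def make_count_matrix(
    rng: np.random.Generator,
    n_cells: int = 50,
    extra_genes: int = 0,
    dataset_id: str = "fixture",
    sparsity: float = 0.5,
    max_count: int = 20,
    cell_meta: pd.DataFrame | None = None,
) -> ExpressionMatrix:
    """Random sparse non-negative integer matrix over panel (+extra) genes."""
    genes = default_panel().genes + [f"X{i:03d}" for i in range(extra_genes)]
    values = rng.integers(0, max_count, size=(n_cells, len(genes))).astype(float)
    values[rng.random(values.shape) < sparsity] = 0
    return ExpressionMatrix(
        dataset_id=dataset_id,
        cell_ids=[f"c{i}" for i in range(n_cells)],
        gene_symbols=genes,
        values=values,
        unit="UMI",
        cell_meta=cell_meta,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20230)


@pytest.fixture
def random_matrix(rng):
    return make_count_matrix(rng, n_cells=50, extra_genes=10)


def uniform_proportions() -> list[float]:
    p = np.full(19, 1.0 / 19)
    p[-1] = 1.0 - p[:-1].sum()
    return p.tolist()


def contrast_proportions() -> tuple[list[float], list[float]]:
    """OPC-like (alpha3/beta1/gamma3 heavy) vs neuron-like (alpha1/beta2/gamma2).

    The minor components carry opposite gradients so the two compositions
    differ in every gene, as real cell-type signatures do.
    """
    genes = default_panel().genes

    def build(heavy: dict[str, float], ascending: bool) -> list[float]:
        w = 1.0 + 0.15 * np.arange(19)
        if not ascending:
            w = w[::-1].copy()
        p = w / w.sum() * (1.0 - sum(heavy.values()))
        for g, v in heavy.items():
            p[genes.index(g)] = v
        p = p / p.sum()
        p[-1] = 1.0 - p[:-1].sum()
        return p.tolist()

    opc = build({"GABRA3": 0.28, "GABRB1": 0.28, "GABRG3": 0.22}, True)
    neuron = build({"GABRA1": 0.28, "GABRB2": 0.28, "GABRG2": 0.22}, False)
    return opc, neuron


@pytest.fixture(scope="session")
def two_type_truth():
    """8 datasets, OPC-like vs neuron-like panel signatures."""
    opc, neuron = contrast_proportions()
    return SyntheticTruth(
        seed=42,
        datasets=[
            {"dataset_id": f"sim{i}", "n_cells": 400, "age_group": "adult",
             "marker_positive_rate": 0.5}
            for i in range(8)
        ],
        cell_types=[
            {"name": "OPC", "marker_gene": "PDGFRA", "panel_proportions": opc,
             "mean_panel_counts": 150.0},
            {"name": "neuron", "marker_gene": "RBFOX3", "panel_proportions": neuron,
             "mean_panel_counts": 150.0},
        ],
        dropout_prob=0.05,
        n_background_genes=30,
        kappa=2000.0,
    )
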