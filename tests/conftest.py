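"""Shared fixtures: small hand-built matrices and one default simulated dataset."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from senatlas import CountMatrix, SimDesign, generate


def make_matrix(dense, gene_ids=None, cell_ids=None, mito_flags=None) -> CountMatrix:
    """CountMatrix from a dense genes x cells array with default identifiers."""
    dense = np.asarray(dense)
    n_genes, n_cells = dense.shape
    return CountMatrix(
        counts=sp.csr_matrix(dense),
        gene_ids=gene_ids if gene_ids is not None else [f"g{i}" for i in range(n_genes)],
        cell_ids=cell_ids if cell_ids is not None else [f"c{j}" for j in range(n_cells)],
        mito_flags=mito_flags,
    )


@pytest.fixture
def matrix_factory():
    return make_matrix


@pytest.fixture(scope="session")
def default_sim():
    """The default-design dataset: 2,000 genes, 4 cell types, 3+3 samples of
    500 cells, 3-fold senescence program, stromal senescent fractions
    0.03 (young) / 0.10 (aged), seed 0."""
    return generate(SimDesign(seed=0))


@pytest.fixture(scope="session")
def small_sim():
    """A light dataset for unit tests (800 genes, 200 cells per sample)."""
    design = SimDesign(
        n_genes=800,
        set_sizes={s: 20 for s in ("SM", "CA", "GA", "SE", "SASP", "IR")},
        cells_per_sample=200,
        n_markers_per_type=20,
        seed=11,
    )
    return generate(design)


def brute_force_ss(expr: np.ndarray, in_set: np.ndarray, alpha: float) -> float:
    """Independent running-sum oracle for one cell, written as plain loops.

    Genes are ordered by descending expression with ties broken by gene
    index; the gene at 1-based position i carries weight (N - i + 1)**alpha
    if it is in the set.  Returns sum_i [P_in(i) - P_out(i)].
    """
    n = len(expr)
    order = sorted(range(n), key=lambda g: (-expr[g], g))
    m = sum(1 for g in range(n) if in_set[g])
    total_in = 0.0
    for pos, g in enumerate(order, start=1):
        if in_set[g]:
            total_in += (n - pos + 1) ** alpha
    score = 0.0
    run_in = 0.0
    run_out = 0
    for pos, g in enumerate(order, start=1):
        if in_set[g]:
            run_in += (n - pos + 1) ** alpha
        else:
            run_out += 1
        score += run_in / total_in - run_out / (n - m)
    return score


@pytest.fixture
def ss_oracle():
    return brute_force_ss
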