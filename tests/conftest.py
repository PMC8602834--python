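"""Shared fixtures: small seeded synthetic datasets reused across tests."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import reactsig as rs


@pytest.fixture(scope="session")
def sc_data():
    """Default single-cell landscape: 500 genes, 600 cells, 4 states."""
    return rs.gen_sc_dataset(rs.ScDesign(seed=7))


@pytest.fixture(scope="session")
def derived_signature(sc_data):
    expr, ann = sc_data
    target = ann.truth["reactive_state"]
    markers = rs.wilcoxon_markers(expr, ann.states(), target)
    aucs = rs.gene_auc(expr, ann.states(), target)
    return rs.derive_signature(markers, aucs, k=20, source=target)


@pytest.fixture(scope="session")
def small_signature():
    return rs.GeneSignature(genes=[f"SIG{i}" for i in range(5)])


@pytest.fixture(scope="session")
def bulk_cohort(small_signature):
    """Bulk cohort with a protective latent effect and mild censoring."""
    design = rs.CohortDesign(n_samples=200, n_genes=300, seed=11)
    return rs.gen_bulk_cohort(design, small_signature)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def tiny_expr():
    """4 genes x 6 observations, deterministic values, log2 scale."""
    rng = np.random.default_rng(42)
    values = pd.DataFrame(
        rng.normal(5, 2, size=(4, 6)),
        index=[f"g{i}" for i in range(4)],
        columns=[f"s{j}" for j in range(6)],
    )
    return rs.ExpressionMatrix(values, scale="log2")
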