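"""Shared fixtures: the reference planted cohort and its network.

The reference cohort (6 modules x 50 genes, 700 background genes, 60
samples, loadings 0.6-0.95, seed 42) is the standing test bed for module
recovery, kME dominance and the integration stage; it is generated once per
session.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from netomics import network as nw
from netomics.synthetic import SimulationConfig, simulate_expression


@pytest.fixture(scope="session")
def ref_cohort():
    config = SimulationConfig(seed=42)
    expr, labels, factors = simulate_expression(config)
    return {"config": config, "expr": expr, "labels": labels, "factors": factors}


@pytest.fixture(scope="session")
def ref_network(ref_cohort):
    expr = ref_cohort["expr"]
    cor = nw.correlation_matrix(expr)
    beta, fit_table = nw.pick_soft_threshold(cor)
    adj = nw.adjacency(cor, beta)
    tom = nw.topological_overlap(adj)
    labels = nw.detect_modules(tom)
    eigengenes = nw.module_eigengene(expr, labels)
    kme = nw.module_membership(expr, eigengenes)
    return {
        "cor": cor,
        "beta": beta,
        "fit_table": fit_table,
        "adj": adj,
        "tom": tom,
        "labels": labels,
        "eigengenes": eigengenes,
        "kme": kme,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_adjacency(rng: np.random.Generator, n: int) -> np.ndarray:
    """Symmetric adjacency in [0, 1] with unit diagonal."""
    a = rng.uniform(0.0, 1.0, size=(n, n))
    a = (a + a.T) / 2.0
    np.fill_diagonal(a, 1.0)
    return a


def tom_bruteforce(a: np.ndarray) -> np.ndarray:
    """Double-loop oracle for the topological overlap matrix."""
    n = a.shape[0]
    k = np.array([sum(a[i, u] for u in range(n) if u != i) for i in range(n)])
    tom = np.ones((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(
                a[i, u] * a[u, j] for u in range(n) if u != i and u != j
            )
            tom[i, j] = (shared + a[i, j]) / (min(k[i], k[j]) + 1.0 - a[i, j])
    return tom
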