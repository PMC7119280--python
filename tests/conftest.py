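import numpy as np
import pandas as pd
import pytest

from netfeat import (
    CoexpressionConfig,
    ExpressionDataset,
    GeneNetwork,
    SimulationConfig,
    build_mutual_knn,
    generate_study,
)


@pytest.fixture
def tiny_dataset():
    """3 genes x 4 patients with hand-set values and labels."""
    values = pd.DataFrame(
        [[1.0, 2.0, -1.0, 0.5], [2.0, 1.0, 0.0, -0.5], [3.0, 0.0, 1.0, 2.0]],
        index=["gA", "gB", "gC"],
        columns=["p1", "p2", "p3", "p4"],
    )
    return ExpressionDataset(
        values=values,
        outcome=pd.Series([1, 1, 0, 0], index=values.columns, name="outcome"),
        cohort=pd.Series(["x", "x", "y", "y"], index=values.columns, name="cohort"),
    )


@pytest.fixture
def triangle_network():
    return GeneNetwork(edges=[("gA", "gB"), ("gB", "gC"), ("gA", "gC")])


@pytest.fixture(scope="session")
def small_study():
    """A single-cohort study with default module signal (session-cached)."""
    return generate_study(
        SimulationConfig(n_genes=200, cohorts=(("c1", 60, 120),), seed=11)
    )


@pytest.fixture(scope="session")
def small_networks(small_study):
    ce = build_mutual_knn(small_study.dataset, CoexpressionConfig(k=9))
    return {"CE": ce, "PPI": small_study.true_network}


def random_dataset(n_genes, n_patients, seed, gene_prefix="g"):
    """Unstructured Gaussian expression with alternating labels."""
    rng = np.random.default_rng(seed)
    values = pd.DataFrame(
        rng.standard_normal((n_genes, n_patients)),
        index=[f"{gene_prefix}{i:03d}" for i in range(n_genes)],
        columns=[f"p{j:03d}" for j in range(n_patients)],
    )
    outcome = pd.Series(
        np.arange(n_patients) % 2, index=values.columns, name="outcome", dtype=np.int8
    )
    cohort = pd.Series("c1", index=values.columns, name="cohort")
    return ExpressionDataset(values=values, outcome=outcome, cohort=cohort)
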