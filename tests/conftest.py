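import numpy as np
import pandas as pd
import pytest

from irdr.synthetic import (
    CohortSpec,
    PerturbationDbSpec,
    generate_perturbation_database,
)
from irdr.types import QuerySignature


@pytest.fixture
def tiny_signature() -> QuerySignature:
    """10-gene two-tailed signature over the default landmark universe."""
    return QuerySignature(
        name="toy",
        up_genes=[f"G{i:04d}" for i in range(5)],
        down_genes=[f"G{i:04d}" for i in range(5, 10)],
    )


@pytest.fixture(scope="session")
def small_db():
    """Small perturbation database with planted truth (shared across tests)."""
    signature = QuerySignature(
        name="toy",
        up_genes=[f"G{i:04d}" for i in range(5)],
        down_genes=[f"G{i:04d}" for i in range(5, 10)],
    )
    spec = PerturbationDbSpec(
        n_compounds=60,
        n_cells=4,
        fraction_reversers=0.1,
        fraction_mimickers=0.1,
        reversal_strength=3.0,
        n_kd=8,
        n_oe=8,
        seed=7,
    )
    profiles, truth = generate_perturbation_database(
        signature, spec, n_landmark=100
    )
    return signature, profiles, truth


@pytest.fixture(scope="session")
def default_scored():
    """Default-scale database (500 compounds, 9 cells, 5% reversers)
    scored against a 120-gene signature; shared across planted-truth
    recovery tests to keep the suite fast."""
    from irdr.connectivity import score_database

    signature = QuerySignature(
        name="default",
        up_genes=[f"G{i:04d}" for i in range(60)],
        down_genes=[f"G{i:04d}" for i in range(60, 120)],
    )
    spec = PerturbationDbSpec(seed=2024)
    profiles, truth = generate_perturbation_database(signature, spec)
    per_cell, aggregated = score_database(profiles, signature)
    return signature, truth, per_cell, aggregated


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def random_profile(rng: np.random.Generator, n: int = 50) -> pd.Series:
    genes = [f"G{i:04d}" for i in range(n)]
    return pd.Series(rng.normal(size=n), index=genes)
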