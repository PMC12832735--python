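import numpy as np
import pandas as pd
import pytest

from evcargo import CountMatrix, FeatureAnnotation, SimulationConfig, generate_study


@pytest.fixture
def toy_counts() -> CountMatrix:
    """5 features x 3 samples with simple integer counts."""
    df = pd.DataFrame(
        {
            "s1": [1, 10, 0, 5, 2],
            "s2": [3, 20, 0, 5, 2],
            "s3": [7, 30, 0, 5, 2],
        },
        index=["a", "b", "c", "d", "e"],
    )
    return CountMatrix(counts=df.astype(float), source_label="toy")


@pytest.fixture
def toy_annotation() -> FeatureAnnotation:
    return FeatureAnnotation(
        table=pd.DataFrame(
            {
                "biotype": ["protein_coding", "protein_coding", "lncRNA",
                            "pseudogene", "other"],
                "symbol": ["SYMA", "SYMB", "SYMC", "SYMD", "SYME"],
            },
            index=["a", "b", "c", "d", "e"],
        )
    )


@pytest.fixture(scope="session")
def study():
    """One full synthetic study, shared across tests (seed fixed)."""
    return generate_study(SimulationConfig(seed=42))


def random_count_matrix(rng: np.random.Generator, n_genes: int, n_samples: int,
                        label: str = "rand") -> CountMatrix:
    counts = rng.poisson(rng.lognormal(1.0, 1.0, size=(n_genes, 1)),
                         size=(n_genes, n_samples)).astype(float)
    return CountMatrix(
        counts=pd.DataFrame(
            counts,
            index=[f"g{i:04d}" for i in range(n_genes)],
            columns=[f"s{j}" for j in range(n_samples)],
        ),
        source_label=label,
    )
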