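import numpy as np
import pytest

from sagedriver.preprocess import CohortDataset, PPINetwork, preprocess_cohort
from sagedriver.synthetic import SyntheticSpec, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 30-gene, 12-sample planted cohort with strong signal."""
    return generate_cohort(
        SyntheticSpec(
            n_genes=30,
            n_samples=12,
            n_drivers=6,
            edge_prob=0.15,
            neighbor_shift=3.0,
            seed=42,
        )
    )


@pytest.fixture(scope="session")
def small_dataset(small_cohort) -> CohortDataset:
    c = small_cohort
    return preprocess_cohort(c.expression, c.mutation, c.ppi, c.drivers)


@pytest.fixture()
def toy_dataset() -> CohortDataset:
    """Hand-built 4-gene / 3-sample cohort with known drivers g1, g3."""
    genes = ["g1", "g2", "g3", "g4"]
    samples = ["s1", "s2", "s3"]
    Xg = np.array(
        [
            [1, 0, 1],
            [0, 1, 0],
            [1, 1, 0],
            [0, 0, 1],
        ],
        dtype=float,
    )
    Xs = np.arange(12, dtype=float).reshape(3, 4) / 10.0
    drivers = frozenset({"g1", "g3"})
    A = Xg * np.array([[1.0], [0.0], [1.0], [0.0]])
    return CohortDataset(
        genes=genes, samples=samples, Xg=Xg, Xs=Xs, A=A, known_drivers=drivers
    )


@pytest.fixture()
def triangle_ppi() -> PPINetwork:
    return PPINetwork.from_edges(
        [("A", "B", 0.9), ("B", "C", 0.8), ("A", "C", 0.7), ("C", "D", 0.6)]
    )
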