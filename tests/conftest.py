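import numpy as np
import pandas as pd
import pytest

from streamgut.io import CountTable, DistanceMatrix, load_neon_metadata


@pytest.fixture(scope="session")
def neon_metadata() -> pd.DataFrame:
    return load_neon_metadata()


@pytest.fixture
def toy_table() -> CountTable:
    """3 samples x 4 taxa with full bacterial lineages."""
    counts = pd.DataFrame(
        [[6, 2, 0, 4], [2, 2, 4, 0], [1, 0, 0, 11]],
        index=["s1", "s2", "s3"],
        columns=["t1", "t2", "t3", "t4"],
    )
    taxonomy = {
        "t1": ("Bacteria", "P1", "C1", "O1", "F1", "G1", None),
        "t2": ("Bacteria", "P1", "C1", "O1", "F1", "G2", None),
        "t3": ("Bacteria", "P1", "C1", "O2", "F2", None, None),
        "t4": ("Bacteria", "P2", "C2", "O3", None, None, None),
    }
    return CountTable(counts=counts, taxonomy=taxonomy)


def random_count_table(rng: np.random.Generator, n_samples: int = 10, n_taxa: int = 20) -> CountTable:
    mat = rng.integers(0, 50, size=(n_samples, n_taxa))
    mat[:, 0] += 1  # no all-zero samples
    return CountTable(
        counts=pd.DataFrame(
            mat,
            index=[f"s{i}" for i in range(n_samples)],
            columns=[f"t{j}" for j in range(n_taxa)],
        )
    )


def two_cluster_distance_matrix(n_per: int = 3, within: float = 0.0, between: float = 0.8) -> DistanceMatrix:
    n = 2 * n_per
    d = np.full((n, n), between)
    d[:n_per, :n_per] = within
    d[n_per:, n_per:] = within
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix([f"s{i}" for i in range(n)], d)
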