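import numpy as np
import pandas as pd
import pytest

from sigrobust import (
    AliasTable,
    SimulationParams,
    simulate_facs_reference,
    simulate_multiregion,
)
from sigrobust.cluster import DissimilarityMatrix


@pytest.fixture(scope="session")
def dataset():
    """Default synthetic multi-region cohort (24 patients x CT/IF/LN)."""
    return simulate_multiregion(SimulationParams(seed=1))


@pytest.fixture(scope="session")
def facs_reference():
    ref, labels = simulate_facs_reference(SimulationParams(seed=1))
    return ref, labels


@pytest.fixture()
def alias_table():
    """Tiny HGNC-style table: OLDSYM is the previous symbol of NEWSYM,
    ALT is an alias of GENE2, entrez 111 points at GENE3."""
    return AliasTable(
        approved=["NEWSYM", "GENE2", "GENE3"],
        previous={"oldsym": ["NEWSYM"]},
        alias={"alt": ["GENE2"]},
        entrez={"111": "GENE3"},
    )


def points_to_dm(points, ids=None):
    """Euclidean dissimilarity matrix from a coordinate array."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[0] == 1:
        pts = pts.T
    n = pts.shape[0]
    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    ids = ids or [f"s{i}" for i in range(n)]
    return DissimilarityMatrix(ids=list(ids), values=d)


@pytest.fixture()
def simple_matrix():
    """5 genes x 4 samples with exact values."""
    rng = np.random.default_rng(0)
    return pd.DataFrame(
        rng.normal(8, 1, (5, 4)),
        index=[f"g{i}" for i in range(5)],
        columns=[f"s{i}" for i in range(4)],
    )
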