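from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from mlcdn.io import BINARY, CONTINUOUS, FeatureMatrix, ResponseMatrix
from mlcdn.similarity import SimilarityNetwork
from mlcdn.synth import SynthConfig, generate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset():
    """A small planted-block dataset shared across tests (read-only)."""
    return generate(SynthConfig(n_cells=12, n_drugs=10, n_cell_blocks=3, n_drug_blocks=2, seed=3))


def make_response(rng, n_cells=10, n_drugs=8, missing_frac=0.2):
    arr = rng.normal(size=(n_cells, n_drugs))
    n_miss = int(round(missing_frac * arr.size))
    if n_miss:
        flat = rng.choice(arr.size, size=n_miss, replace=False)
        arr.ravel()[flat] = np.nan
    cells = [f"C{i}" for i in range(n_cells)]
    drugs = [f"D{j}" for j in range(n_drugs)]
    return ResponseMatrix(pd.DataFrame(arr, index=cells, columns=drugs))


def make_network(rng, ids, layer="path", measure="pearson"):
    from oracles import random_similarity

    return SimilarityNetwork(ids, random_similarity(rng, len(ids)), layer, measure)


def make_binary(rng, n=8, p=30, ids=None):
    vals = (rng.random((n, p)) < 0.4).astype(float)
    ids = ids or [f"E{i}" for i in range(n)]
    return FeatureMatrix(pd.DataFrame(vals, index=ids, columns=[f"f{k}" for k in range(p)]), BINARY)


def make_continuous(rng, n=6, p=20, ids=None):
    vals = rng.normal(size=(n, p))
    ids = ids or [f"E{i}" for i in range(n)]
    return FeatureMatrix(
        pd.DataFrame(vals, index=ids, columns=[f"f{k}" for k in range(p)]), CONTINUOUS
    )
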