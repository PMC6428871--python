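from __future__ import annotations

import numpy as np
import pytest

from cdrnet.distance import SimilarityLayer
from cdrnet.repertoire import CloneRecord, Repertoire


def make_layer(edges, n) -> SimilarityLayer:
    return SimilarityLayer(
        n=1, mode="exact",
        edges=np.array(edges, dtype=np.int64).reshape(-1, 2), n_nodes=n,
    )


def random_gnp_layer(n: int, p: float, rng: np.random.Generator) -> SimilarityLayer:
    """Plain Bernoulli edge sampling over the i<j triangle (no networkx)."""
    iu = np.triu_indices(n, k=1)
    mask = rng.random(iu[0].size) < p
    edges = np.column_stack((iu[0][mask], iu[1][mask]))
    return make_layer(edges, n)


@pytest.fixture
def three_clone_rep() -> Repertoire:
    """CARDY-CARDW at LD 1; CARVV at LD 2 from both."""
    return Repertoire(
        sample_id="tiny",
        clones=[
            CloneRecord("CARDY", 5),
            CloneRecord("CARDW", 3),
            CloneRecord("CARVV", 2),
        ],
    )


@pytest.fixture
def path3() -> SimilarityLayer:
    return make_layer([(0, 1), (1, 2)], 3)


@pytest.fixture
def triangle() -> SimilarityLayer:
    return make_layer([(0, 1), (0, 2), (1, 2)], 3)


@pytest.fixture
def star4() -> SimilarityLayer:
    """Hub 0 with three leaves."""
    return make_layer([(0, 1), (0, 2), (0, 3)], 4)
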