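import numpy as np
import pandas as pd
import pytest

from gazecoda import AOITable, CompositionMatrix, GeneratorConfig


@pytest.fixture
def two_observer_table() -> AOITable:
    """The two-observer, three-AOI fixture (proportional dwell patterns)."""
    from gazecoda.worked_example import example_table

    return AOITable(example_table(), ["Visitor", "Persons", "Background"])


@pytest.fixture
def small_matrix() -> CompositionMatrix:
    rng = np.random.default_rng(42)
    vals = np.exp(rng.normal(size=(12, 4)))
    meta = pd.DataFrame({
        "participant": [f"P{i}" for i in range(12)],
        "task": [1, 2, 3] * 4,
    })
    return CompositionMatrix(vals, ["A", "B", "C", "D"], meta)


@pytest.fixture
def small_config() -> GeneratorConfig:
    return GeneratorConfig(n_participants=30, seed=7)


def complete_linkage_oracle(dist: np.ndarray):
    """Brute-force O(n^3) complete-linkage agglomeration.

    Returns the sorted list of merge heights; tie-breaks by lowest member
    index, which matches any valid complete-linkage tree's height multiset.
    """
    n = dist.shape[0]
    clusters = [{i} for i in range(n)]
    heights = []
    while len(clusters) > 1:
        best = (np.inf, None, None)
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                h = max(dist[i, j] for i in clusters[a] for j in clusters[b])
                if h < best[0]:
                    best = (h, a, b)
        h, a, b = best
        heights.append(h)
        clusters[a] = clusters[a] | clusters[b]
        del clusters[b]
    return sorted(heights)
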