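import numpy as np
import pandas as pd
import pytest

from cseg import SyntheticSpec, filter_context, simulate_screen
from cseg.io import GeneEffectMatrix


@pytest.fixture(scope="session")
def default_spec():
    """The default study conditions: 1000 genes, 15 context + 15 other lines,
    10% common + 10% context essential, seed 42."""
    return SyntheticSpec()


@pytest.fixture(scope="session")
def default_screen(default_spec):
    return simulate_screen(default_spec)


@pytest.fixture(scope="session")
def context_matrix(default_screen):
    m, _ = default_screen
    return filter_context(m, [c for c in m.cell_lines if c.startswith("CTX_")])


@pytest.fixture
def small_matrix():
    """4 genes x 3 lines with one missing value, hand-readable scores."""
    scores = pd.DataFrame(
        {
            "L1": [-2.0, -1.0, 0.0, 0.3],
            "L2": [-1.8, -0.9, 0.1, np.nan],
            "L3": [-2.2, -1.1, -0.1, 0.2],
        },
        index=pd.Index(["g1", "g2", "g3", "g4"], name="gene"),
    )
    return GeneEffectMatrix(scores=scores)


def f1_score_sets(predicted: frozenset, truth: frozenset) -> float:
    if not predicted and not truth:
        return 1.0
    tp = len(predicted & truth)
    return 2.0 * tp / (len(predicted) + len(truth))
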