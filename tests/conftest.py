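import numpy as np
import pytest

from deazoib import ProductionDataset


@pytest.fixture
def toy_dataset():
    """Three units where B dominates C: at C's input bound (x=2) the
    frontier output is B's y=3, so C's outputs could be expanded 1.5-fold."""
    return ProductionDataset(
        unit_ids=("A", "B", "C"),
        inputs=np.array([[1.0], [2.0], [2.0]]),
        outputs=np.array([[1.0], [3.0], [2.0]]),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20210927)
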