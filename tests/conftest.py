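import numpy as np
import pytest

from evoscape.phylo import Chronogram
from evoscape.synthdata import SynthSpec, generate_dataset


@pytest.fixture
def chain_tree():
    """Binary tree containing a root-to-tip chain with durations (6, 0, 0).

    Tips t0..t3; internal: I2=4, I1=5, root=6; chain root->I1->I2->t0."""
    return Chronogram(
        labels=["t0", "t1", "t2", "t3"],
        parent=np.array([4, 6, 5, 4, 5, 6, -1]),
        ages=np.array([0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 6.0]),
    )


@pytest.fixture
def two_tip_tree():
    """Two tips a (duration 1) and b (duration 2) joined at the root."""
    return Chronogram(labels=["a", "b"], parent=np.array([2, 2, -1]),
                      ages=np.array([1.0, 0.0, 2.0]))


@pytest.fixture
def quartet_tree():
    """((A,B),(C,D)) with unit-depth cherries, root at age 2."""
    return Chronogram(labels=["A", "B", "C", "D"],
                      parent=np.array([4, 4, 5, 5, 6, 6, -1]),
                      ages=np.array([0.0, 0.0, 0.0, 0.0, 1.0, 1.0, 2.0]))


@pytest.fixture(scope="session")
def synth_default():
    """One default-condition synthetic dataset, shared across tests."""
    return generate_dataset(SynthSpec(seed=2024))


@pytest.fixture(scope="session")
def random_tree_16():
    from evoscape.synthdata import gen_chronogram

    chron, _ = gen_chronogram(SynthSpec(seed=42, n_tips=16))
    return chron
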