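import numpy as np
import pytest

from genome3d.layout import GenomeLayout
from genome3d.model import Model3D
from genome3d.synthetic import make_truth


@pytest.fixture
def tiny_layout() -> GenomeLayout:
    return GenomeLayout(
        (("chrI", 30_000), ("chrII", 25_000)),
        resolution_bp=10_000,
        centromeres={"chrI": 15_000, "chrII": 12_000},
    )


@pytest.fixture(scope="session")
def truth_small():
    return make_truth("small", seed=1)


@pytest.fixture(scope="session")
def truth_distance_map(truth_small):
    return truth_small.true_distance_map()


@pytest.fixture
def random_model(tiny_layout) -> Model3D:
    rng = np.random.default_rng(42)
    return Model3D(tiny_layout, rng.uniform(-400, 400, size=(tiny_layout.n_beads, 3)))
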