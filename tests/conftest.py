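import numpy as np
import pytest

from nevosim import membrane_geometry as mg


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def single_papilla_membrane():
    curve = mg.build_shape_curve(60.0, 100.0, 0.7)
    return mg.MembraneModel(
        (1000.0, 1000.0),
        [mg.PapillaChart(np.array([500.0, 500.0]), curve)],
    )


@pytest.fixture(scope="session")
def composite_membrane():
    """Two papillae of different shape plus one chi elevation."""
    c1 = mg.build_shape_curve(60.0, 100.0, 0.8)
    c2 = mg.build_shape_curve(40.0, 70.0, 0.2)
    return mg.MembraneModel(
        (1000.0, 1000.0),
        [
            mg.PapillaChart(np.array([300.0, 300.0]), c1),
            mg.PapillaChart(np.array([650.0, 600.0]), c2),
        ],
        [mg.DeformationBump(np.array([500.0, 200.0]), 400.0, 30.0)],
    )


@pytest.fixture(scope="session")
def flat_membrane():
    return mg.MembraneModel((1000.0, 1000.0))
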