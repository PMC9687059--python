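import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def water_dimer():
    """Two water-like molecules with a textbook linear hydrogen bond:
    donor O-H points straight at the acceptor O at 2.8 A."""
    from phytoscreen.structures import Atom, Molecule, mark_polar_hydrogens

    donor = Molecule(
        [
            Atom("O", (0.0, 0.0, 0.0), name="O"),
            Atom("H", (0.96, 0.0, 0.0), name="H1"),
            Atom("H", (-0.24, 0.93, 0.0), name="H2"),
        ],
        label="donor",
    )
    acceptor = Molecule(
        [
            Atom("O", (2.8, 0.0, 0.0), name="O"),
            Atom("H", (3.04, 0.93, 0.0), name="H1"),
            Atom("H", (3.04, -0.93, 0.0), name="H2"),
        ],
        label="acceptor",
    )
    mark_polar_hydrogens(donor)
    mark_polar_hydrogens(acceptor)
    return donor, acceptor
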