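import numpy as np
import pytest

from conjmap.core import (ConjugateFrame, ConjugateTopology,
                          ConjugateTrajectory)
from conjmap.synthetic import (make_conjugate_topology, two_domain_ensemble)


@pytest.fixture(scope="session")
def toy_topology():
    """Backbone-only conjugate topology with 20 residues per subunit."""
    return make_conjugate_topology(20)


@pytest.fixture(scope="session")
def small_ensemble():
    """200-frame two-basin ensemble (70/30) of 20-residue subunits."""
    traj, labels, spec = two_domain_ensemble(
        200, [0.7, 0.3], n_residues=20, seed=11)
    return traj, labels, spec


@pytest.fixture()
def single_pair_topology():
    """One particle per subunit — the minimal conjugate."""
    return ConjugateTopology(
        residue_index=[1, 1],
        subunit=["distal", "proximal"],
        residue_name=["ALA", "ALA"],
        is_backbone=[True, True],
        polarity=["apolar", "polar"],
        radius=[0.23, 0.23],
    )


def make_frame(coords):
    return ConjugateFrame(coordinates=np.asarray(coords, dtype=float))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
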