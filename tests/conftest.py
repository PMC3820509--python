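import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import ensdyn

settings.register_profile(
    "ci", derandomize=True,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("ci")


def make_chain(seq: str, source_id: str = "toy_A",
               start: int = 1) -> ensdyn.ChainRecord:
    """ChainRecord from a one-letter sequence, Cα on a 3.8 Å line."""
    from Bio.SeqUtils import seq3
    residues = []
    for i, aa in enumerate(seq):
        ca = np.array([3.8 * i, 0.0, 0.0])
        residues.append(ensdyn.Residue(
            number=start + i, name=seq3(aa).upper(), ca=ca,
            atoms={"CA": ca, "CB": ca + np.array([0.0, 1.5, 0.0])},
            bfactor=10.0 + i))
    return ensdyn.ChainRecord(source_id=source_id, residues=residues)


@pytest.fixture
def toy():
    return ensdyn.toy_structure()


@pytest.fixture
def two_state():
    return ensdyn.toy_two_state()


@pytest.fixture
def switching():
    up, down = ensdyn.toy_two_state()
    spec = ensdyn.GeneratorSpec(seed=11, states=[up, down], noise=0.3,
                                schedule=[(0, 300), (1, 300)])
    return ensdyn.switching_trajectory(spec, 600)


@pytest.fixture
def block_traj():
    blocks = [np.arange(0, 10), np.arange(10, 20), np.arange(20, 30)]
    spec = ensdyn.GeneratorSpec(seed=7, blocks=blocks, intra=0.8, inter=0.0)
    ens, truth = ensdyn.block_correlated_trajectory(spec, 3000)
    return ens, truth, blocks
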