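import numpy as np
import pytest

from mwfmap.core_model import build_grid, field_signals, mese_schedule
from mwfmap.volume import EchoVolume


@pytest.fixture(scope="session")
def grid():
    return build_grid()


@pytest.fixture(scope="session")
def mese():
    return mese_schedule()


@pytest.fixture(scope="session")
def single_voxel_volume(grid, mese):
    """Factory: noiseless single-voxel EchoVolume from a parameter vector or T2."""

    def make(theta8=None, t2=None, density=1.0):
        if theta8 is not None:
            sig = field_signals(np.asarray(theta8, float)[None, :], grid, mese)
        else:
            sig = density * np.exp(-mese.times / t2)[None, :]
        return EchoVolume(
            data=sig.reshape(1, 1, 1, -1),
            schedule=mese,
            mask=np.ones((1, 1, 1), bool),
        )

    return make


# Pure-tissue parameter vectors of the brain-phantom recipe.
WM_THETA = [0.145, 25.0, 5.0, 0.855, 100.0, 20.0, 0.0, 1800.0]
GM_THETA = [0.045, 25.0, 5.0, 0.955, 100.0, 20.0, 0.0, 1800.0]
CSF_THETA = [0.0, 25.0, 5.0, 0.0, 100.0, 20.0, 1.0, 1800.0]
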