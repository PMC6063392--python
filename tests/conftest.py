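import numpy as np
import pytest

from atlassel.phantom import LibrarySpec, PhantomSpec, make_library, make_phantom
from atlassel.volio import LabelVolume, VolumeGrid

#: Small grid for hand-built volumes.
SMALL_GRID = VolumeGrid((4, 4, 4))


def label_volume(array, grid=None, table=None):
    arr = np.asarray(array, dtype=np.int32)
    grid = grid or VolumeGrid(arr.shape)
    table = table if table is not None else {
        int(i): f"label_{int(i)}" for i in np.unique(arr) if i != 0
    }
    return LabelVolume(grid, arr, table)


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free, bias-free phantom at default geometry."""
    return make_phantom(PhantomSpec(noise_sd=0.0, bias_amplitude=0.0, seed=7), "clean")


@pytest.fixture(scope="session")
def noisy_phantom():
    """Phantom at the default intensity model (noise sd 2.5, 5% bias)."""
    return make_phantom(PhantomSpec(seed=21), "noisy")


@pytest.fixture(scope="session")
def clean_library9():
    """9 phantoms, evenly spaced ventricle scales, all jitters and noise off."""
    lspec = LibrarySpec(
        n_atlases=9,
        base=PhantomSpec(noise_sd=0.0, bias_amplitude=0.0),
        ventricle_scale_range=(0.7, 1.3),
        cortex_jitter_mm=0.0,
        structure_jitter_mm=0.0,
        seed=5,
    )
    return make_library(lspec)


@pytest.fixture(scope="session")
def default_library8():
    """8 phantoms under the default library conditions (jitter + noise on)."""
    return make_library(LibrarySpec(n_atlases=8, seed=17))
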