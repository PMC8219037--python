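import numpy as np
import pytest

from puzzlecell import synthcell
from puzzlecell.voxelio import LabeledVolume


@pytest.fixture(scope="session")
def sphere_volume():
    """Digital ball, r = 10 µm at 0.25 µm spacing (fine-resolution phantom)."""
    spec = synthcell.LobedCellSpec(
        base_radii=(10.0, 10.0, 10.0), n_lobes=0, bump_amplitude=0.0,
        spacing=(0.25, 0.25, 0.25), seed=0,
    )
    vol, truth = synthcell.make_lobed_cell(spec)
    return vol, truth


@pytest.fixture(scope="session")
def lobed_volume():
    """12-lobe phantom at 0.5 µm spacing."""
    spec = synthcell.LobedCellSpec(
        base_radii=(10.0, 10.0, 10.0), n_lobes=12, bump_amplitude=0.35,
        spacing=(0.5, 0.5, 0.5), seed=1,
    )
    vol, truth = synthcell.make_lobed_cell(spec)
    return vol, truth


@pytest.fixture(scope="session")
def reference_library():
    return synthcell.default_reference_library()


def random_label_volume(seed: int, shape=(12, 12, 12), n_blobs=3) -> LabeledVolume:
    """Small random multi-label volume for oracle-equivalence checks."""
    rng = np.random.default_rng(seed)
    labels = np.zeros(shape, dtype=np.int32)
    for lab in range(1, n_blobs + 1):
        center = rng.uniform(2, np.array(shape) - 2, 3)
        radius = rng.uniform(2.0, 4.0)
        zz, yy, xx = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
        d2 = (zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xx - center[2]) ** 2
        labels[(d2 <= radius**2) & (labels == 0)] = lab
    return LabeledVolume(labels, (1.0, 1.0, 1.0))
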