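import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from orgcontact import synthetic
from orgcontact.volume_io import LabelVolume


@pytest.fixture
def ball_scene():
    """One ball mitochondrion (r = 8 vox) with a full wrapped ER shell at
    gap 3 voxels, plus one lipid droplet and one nucleus."""
    spec = synthetic.SceneSpec(
        shape=(48, 48, 48),
        mitochondria=[synthetic.MitoSpec("ball", center=(24.0, 24.0, 18.0), radius=8.0)],
        er_structures=[
            synthetic.ERSpec("wrapped_shell", attached_to=1, gap_voxels=3)
        ],
        lipid_droplets=[synthetic.BallSpec(center=(24.0, 10.0, 38.0), radius=5.0)],
        nuclei=[synthetic.BallSpec(center=(10.0, 38.0, 38.0), radius=6.0)],
        seed=11,
    )
    return synthetic.generate_scene(spec)


@pytest.fixture
def cube_volume():
    """A 10^3-voxel cube at 8 nm pitch, labeled 1."""
    data = np.zeros((14, 14, 14), dtype=np.uint8)
    data[2:12, 2:12, 2:12] = 1
    return LabelVolume(data, 8.0, name="cube")
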