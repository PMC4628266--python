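import numpy as np
import pytest

from parenchyma3d.phantom import generate_ball, generate_tissue, generate_tube


@pytest.fixture(scope="session")
def phantom_1mm():
    """1 mm^3 tissue phantom at 8 um pitch, moderate fragmentation."""
    return generate_tissue(
        shape_um=(1000.0, 1000.0, 1000.0),
        pitch_um=8.0,
        porosity=0.15,
        fragmentation=0.2,
        seed=3,
    )


@pytest.fixture(scope="session")
def ball200():
    """Digital ball, 200 um diameter at 2 um pitch (100 voxels across)."""
    return generate_ball(200.0, 2.0)


@pytest.fixture(scope="session")
def tube1000():
    """Straight tube, 1000 um long, 40 um wide, at 4 um pitch."""
    return generate_tube(1000.0, 40.0, axis=0, pitch_um=4.0)


def two_ball_mask(d_um=150.0, gap_um=140.0, pitch_um=2.5):
    """Two overlapping digital balls with centers gap_um apart along z."""
    r = d_um / 2.0 / pitch_um
    margin = 25
    nz = int((gap_um + d_um) / pitch_um) + 2 * margin
    ncross = int(d_um / pitch_um) + 2 * margin
    c = ncross / 2.0
    z0 = margin + r
    z1 = z0 + gap_um / pitch_um
    zz, yy, xx = np.indices((nz, ncross, ncross)).astype(float)
    m = ((zz - z0) ** 2 + (yy - c) ** 2 + (xx - c) ** 2 <= r**2) | (
        (zz - z1) ** 2 + (yy - c) ** 2 + (xx - c) ** 2 <= r**2
    )
    return m, (z0, c, c), (z1, c, c)
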