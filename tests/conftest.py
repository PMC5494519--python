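import numpy as np
import pytest

from mitofuse.series import ImageSeries


def make_series(
    pixels,
    pixel_um=0.1,
    frame_interval_s=4.0,
    t_act=1,
    act_rois=(),
    bit_depth=8,
    cell_roi=None,
):
    """Build an ImageSeries from a raw (T, 2, H, W) array."""
    dtype = np.uint8 if bit_depth == 8 else np.uint16
    return ImageSeries(
        pixels=np.asarray(pixels, dtype=dtype),
        pixel_um=pixel_um,
        frame_interval_s=frame_interval_s,
        t_act=t_act,
        act_rois=list(act_rois),
        bit_depth=bit_depth,
        cell_roi=cell_roi,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def flat_series():
    """4 frames, 16x16, constant intensities: GFP 40, DsRed 80."""
    px = np.zeros((4, 2, 16, 16), dtype=np.uint8)
    px[:, 0] = 40
    px[:, 1] = 80
    return make_series(px, t_act=1, act_rois=[(4, 4, 8, 8)])
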