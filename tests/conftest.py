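import numpy as np
import pytest

import t6sspipe as tp


@pytest.fixture(scope="session")
def small_field_truth():
    """20 isolated cells in a quarter-size field, mask + sheath channels."""
    cfg = tp.FieldConfig(n_cells=20, width_um=20.48, height_um=20.48)
    channels = [tp.mask_channel(), tp.tssb_channel()]
    return cfg, channels, tp.sample_field(cfg, channels, seed=123)


@pytest.fixture(scope="session")
def small_field_stacks(small_field_truth):
    cfg, channels, truth = small_field_truth
    optics = tp.OpticsModel()
    stacks = {
        ch.name: tp.render_channel(truth, ch, optics, seed=1000 + i)
        for i, ch in enumerate(channels)
    }
    return cfg, truth, optics, stacks


def gaussian_spot(shape, x0, y0, sigma, amplitude=1000.0):
    """Pixel-integrated 2D Gaussian spot (photon-conserving), float image."""
    from scipy.special import erf

    rows = np.arange(shape[0])
    cols = np.arange(shape[1])

    def cdf(edges, mu):
        return 0.5 * (1 + erf((edges - mu) / (sigma * np.sqrt(2))))

    wy = np.diff(cdf(np.concatenate([rows - 0.5, [rows[-1] + 0.5]]), y0))
    wx = np.diff(cdf(np.concatenate([cols - 0.5, [cols[-1] + 0.5]]), x0))
    return amplitude * np.outer(wy, wx)
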