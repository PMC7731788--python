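import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from csfflow.geometry import circle_polygon
from csfflow.synthetic import CompartmentSpec, FlowSpec


def make_blob_image(shape, positions_px, amplitude=100.0, sigma_px=1.0,
                    noise_sd=0.0, baseline=20.0, rng=None):
    """Render isotropic Gaussian blobs at sub-pixel (x, y) positions."""
    h, w = shape
    img = np.full((h, w), baseline, dtype=float)
    jj, ii = np.meshgrid(np.arange(w), np.arange(h))
    for (x, y) in positions_px:
        img += amplitude * np.exp(-((jj - x) ** 2 + (ii - y) ** 2) / (2 * sigma_px**2))
    if noise_sd > 0:
        img += (rng or np.random.default_rng(0)).normal(0, noise_sd, (h, w))
    return img


@pytest.fixture
def blob_image_factory():
    return make_blob_image


def small_vortex_spec(speed=10.0, seed=0, n_frames=40, radius=40.0, **kw):
    """Single counterclockwise vortex in a small frame, for fast fixtures."""
    px = kw.pop("pixel_size_um", 2.0)
    margin = 8.0
    c = radius + margin
    side = int(np.ceil(2 * c / px)) + 1
    comp = CompartmentSpec(
        label="IVp",
        region=circle_polygon((c, c), radius),
        flow_model="vortex" if speed > 0 else "static",
        polarity="counterclockwise",
        median_speed_target=speed,
        center=(c, c),
        radius=radius,
    )
    return FlowSpec(
        compartments=[comp],
        image_shape=(side, side),
        pixel_size_um=px,
        n_frames=n_frames,
        seed=seed,
        **kw,
    )


@pytest.fixture
def vortex_spec_factory():
    return small_vortex_spec
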