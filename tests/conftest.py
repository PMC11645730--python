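import numpy as np
import pytest

from tmjmotion import JawModel, RenderParams, deviation_bump, raised_cosine_opening, simulate_trajectory
from tmjmotion.synthetic import render_frames


def make_model(opening_deg=18.0, deviation_mm=0.0, deviation_phase=0.5,
               jaw_length=100.0, coupling=0.05):
    """Study-scale jaw model: ~80-100 mm condyle-chin distance, natural
    (not forced-maximal) opening, deviation up to a few millimetres."""
    return JawModel(
        condyle_center=(0.0, -40.0),
        jaw_length=jaw_length,
        opening_profile=raised_cosine_opening(opening_deg),
        deviation_profile=deviation_bump(deviation_mm, center=deviation_phase),
        marker_a_coupling=coupling,
    )


SMALL_RENDER = dict(image_size=(360, 360), mm_per_px=0.3)


@pytest.fixture(scope="session")
def default_cycle():
    """101-frame deviated cycle with exact ground truth."""
    return simulate_trajectory(make_model(deviation_mm=4.0), 101)


@pytest.fixture(scope="session")
def rendered_cycle(default_cycle):
    """Noiseless rendered stack plus its sub-pixel ground-truth table."""
    params = RenderParams(**SMALL_RENDER, noise_sd=0.0, seed=7)
    stack, table = render_frames(default_cycle, params)
    return stack, table, params, default_cycle


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)
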