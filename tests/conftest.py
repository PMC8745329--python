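import numpy as np
import pytest

from thromboflow.kinetics import FlowRunConfig, simulate_kinetics
from thromboflow.render import RenderConfig, render_images
from thromboflow.segment import SegmentationConfig


@pytest.fixture(scope="session")
def seg_config():
    return SegmentationConfig()


@pytest.fixture(scope="session")
def quarter_render():
    return RenderConfig.quarter_scale(seed=11)


@pytest.fixture(scope="session")
def vehicle_tf_run(quarter_render):
    """A rendered vehicle collagen/TF run (states, image sets, truth)."""
    config = FlowRunConfig(surface="collagen_TF", preset="vehicle", seed=11)
    states = simulate_kinetics(config)
    image_sets, truth = render_images(states, config, quarter_render)
    return config, states, image_sets, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
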