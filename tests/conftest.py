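import numpy as np
import pytest

from nemameter import image_io, phantom, pipeline
from nemameter.image_io import RunConfig


@pytest.fixture(scope="session")
def straight_spec():
    """Noiseless straight phantom: two-level image, exact ground truth."""
    return phantom.PhantomSpec(
        backbone_control_points=[(40, 60), (160, 60), (280, 60)],
        radius_profile=phantom.tapered_radius_profile(14.0),
        image_size=(320, 120),
        noise_sd=0.0,
        illumination_gradient=0.0,
        scale=1.0,
        seed=0,
    )


@pytest.fixture(scope="session")
def straight_render(straight_spec):
    return phantom.render_phantom(straight_spec)


@pytest.fixture(scope="session")
def noisy_adult():
    """One realistic adult phantom (noise sd 3, shading 30) plus truth."""
    spec = phantom.adult_spec(seed=7)
    img, truth = phantom.render_phantom(spec)
    return spec, img, truth


@pytest.fixture(scope="session")
def measured_adult(noisy_adult):
    """The noisy adult pushed through the full pipeline; one passing worm."""
    spec, img, truth = noisy_adult
    worms = pipeline.process_image(
        image_io.IntensityImage(img, scale=spec.scale), RunConfig(),
        image_name="adult7")
    passed = [w for w in worms if w.passed]
    assert len(passed) == 1
    return spec, truth, passed[0]


def run_one_phantom(spec, config=None):
    """Helper: render a spec and return (truth, passing WormObject)."""
    img, truth = phantom.render_phantom(spec)
    worms = pipeline.process_image(
        image_io.IntensityImage(img, scale=spec.scale),
        config or RunConfig(), image_name="p")
    passed = [w for w in worms if w.passed]
    assert len(passed) == 1, [w.fail_reason for w in worms]
    return truth, passed[0]


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260918)
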