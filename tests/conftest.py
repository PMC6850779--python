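import numpy as np
import pytest

from ciliascreen import CiliumTruth, DetectionParams, make_cilium_stack

# the detector at "noiseless settings": no median smoothing is needed when
# there is no noise, and only then is the recovered mask pixel-exact
NOISELESS_PARAMS = DetectionParams(median_radius_px=0)


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture
def three_cilia_truths():
    """Three well-separated cilia with distinct truth ratios 1, 2 and 4."""
    return [
        CiliumTruth(center=(60.0, 60.0), orientation_deg=0.0,
                    probe_intensity_cilium=100.0),
        CiliumTruth(center=(128.0, 128.0), orientation_deg=45.0,
                    probe_intensity_cilium=200.0),
        CiliumTruth(center=(200.0, 80.0), orientation_deg=100.0,
                    probe_intensity_cilium=400.0),
    ]


@pytest.fixture
def noiseless_stack(three_cilia_truths):
    """Noiseless stack with 3 cilia and the default pair of distractors."""
    return make_cilium_stack(
        three_cilia_truths, distractors="default", noise_model="none", seed=0
    )
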