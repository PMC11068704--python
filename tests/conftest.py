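import numpy as np
import pytest

from wavenetid.frame import FrameSpec


@pytest.fixture()
def rng():
    # fresh, fixed-seed generator per test: results never depend on test order
    return np.random.default_rng(20260927)


@pytest.fixture()
def unit_frame():
    """Small 3-input frame with fixed [0,1] normalization."""
    return FrameSpec(
        n_inputs=3,
        n_superpositions=3,
        n_levels=1,
        family="quadratic_spline",
        identity_inputs=(0, 1),
        normalization=((0.0, 1.0), (0.0, 1.0), (0.0, 1.0)),
    )
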