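import numpy as np
import pytest

from phenofuse import synth
from phenofuse.ssmm import ScalingFactors


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def single_cycle_params():
    """A fixed mid-latitude single-season truth curve."""
    return synth.TruthParams(
        cycles=(
            synth.TruthCycle(
                rise_mid=140.0,
                rise_rate=0.09,
                fall_mid=270.0,
                fall_rate=0.08,
                amplitude=0.4,
            ),
        ),
        evi2_b=0.08,
    )


@pytest.fixture
def truth122(single_cycle_params):
    return synth.make_truth_curve(single_cycle_params, 2019)


@pytest.fixture
def matched_pair(single_cycle_params):
    """(donor, factors, pixel truth values, valid mask) with lam=1.05, beta=9."""
    factors = ScalingFactors(np.nan, np.nan, 1.05, 9.0)
    donor, true_factors = synth.donor_from_truth(
        single_cycle_params, factors, 2019, "camA", (0, 0)
    )
    values, valid = synth.pixel_from_donor(donor, true_factors, 2019)
    return donor, true_factors, values, valid
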