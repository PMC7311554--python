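import numpy as np
import pytest

from intergaze.social_utility import AllocationOption, GroupContext, SocialPreference


@pytest.fixture
def option_a():
    # worked-example Option A: 7.50 for self, 5.20 for the partner
    return AllocationOption(7.50, 5.20)


@pytest.fixture
def option_b():
    return AllocationOption(6.90, 6.10)


@pytest.fixture
def prosocial():
    return SocialPreference(0.5, 0.5)


@pytest.fixture
def individualist():
    return SocialPreference(0.9, 0.1)


@pytest.fixture
def ingroup():
    return GroupContext.ingroup()


@pytest.fixture
def outgroup_half():
    return GroupContext.outgroup(0.5)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def study_layout():
    from intergaze.synthetic_data import generate_layout

    return generate_layout(("top", "bottom"))
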