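import numpy as np
import pytest
from hypothesis import settings

from phosphozip import STRAND_E, build_class_zipper, table1_variants
from phosphozip.simulate import study_outcome_fixture

settings.register_profile("default", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("default")


@pytest.fixture(scope="session")
def variants():
    return table1_variants()


@pytest.fixture(scope="session")
def class7_zipper():
    return build_class_zipper(STRAND_E, 7)


@pytest.fixture(scope="session")
def class8_zipper():
    return build_class_zipper(STRAND_E, 8)


@pytest.fixture(scope="session")
def outcome_fixture():
    return study_outcome_fixture()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
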