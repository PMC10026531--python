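import numpy as np
import pytest

from aompk import SubjectCovariates, build_typical_parameters


@pytest.fixture
def female_em():
    return SubjectCovariates(sex="female", bmi=28.0, metabolizer="EM")


@pytest.fixture
def typical_params(female_em):
    return build_typical_parameters(female_em)


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)
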