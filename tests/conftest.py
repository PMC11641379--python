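import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from msnpls.rois import DESIKAN_KILLIANY_LH, FEATURE_NAMES

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_feature_table(rng: np.random.Generator) -> pd.DataFrame:
    """A random, valid 34 x 13 regional feature table."""
    values = rng.standard_normal((len(DESIKAN_KILLIANY_LH), len(FEATURE_NAMES)))
    return pd.DataFrame(
        values, index=list(DESIKAN_KILLIANY_LH), columns=list(FEATURE_NAMES)
    )


@pytest.fixture
def feature_table(rng):
    return make_feature_table(rng)
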