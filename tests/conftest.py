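import warnings

import numpy as np
import pandas as pd
import pytest

warnings.filterwarnings("ignore", category=FutureWarning, module="arviz")

from vtstain import synthetic, tiling


@pytest.fixture(scope="session")
def stain_pair():
    """One medium synthetic pseudo-H&E / pseudo-trichrome pair with its key."""
    spec = synthetic.SyntheticSlideSpec(seed=42, dims=(256, 256), true_stage=3)
    return synthetic.make_stain_pair(spec)


@pytest.fixture(scope="session")
def staging_small():
    """A compact rater staging table with known generating parameters."""
    spec = synthetic.RaterSimSpec(n_cases=60, seed=7)
    return synthetic.simulate_rater_stages(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
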