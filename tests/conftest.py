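import numpy as np
import pytest

from eegdx import CohortSpec, bandpass_1_30, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Four SCI + four AD subjects at default effect sizes, 1-30 Hz filtered."""
    spec = CohortSpec(n_per_group={"SCI": 4, "AD": 4}, seed=7)
    return [bandpass_1_30(rec) for rec in generate_cohort(spec)]


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
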