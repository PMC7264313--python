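import numpy as np
import pytest

from myoscreen import ConfusionMatrix, default_spec, generate_cohort


@pytest.fixture(scope="session")
def study_counts():
    """2x2 counts at the published 1.30 cutoff (23 metabolic vs 60 myalgia)."""
    return ConfusionMatrix(tp=16, fn=7, fp=2, tn=58)


@pytest.fixture(scope="session")
def small_cohort():
    """Default-sized synthetic cohort (118 subjects), fixed seed."""
    return generate_cohort(default_spec(seed=42))


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)
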