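import hypothesis
import pytest

import dipalp as d

hypothesis.settings.register_profile(
    "det", derandomize=True, max_examples=50, deadline=None)
hypothesis.settings.load_profile("det")

DEFAULT_SEED = 0


@pytest.fixture(scope="session")
def default_cohort():
    """The default in vivo-calibrated cohort (12 patients, fixed seed)."""
    return d.generate_cohort(d.CohortConfig(seed=DEFAULT_SEED))


@pytest.fixture(scope="session")
def geometry():
    return d.ProbeGeometry()


@pytest.fixture(scope="session")
def default_features(default_cohort, geometry):
    """Feature table from the full simulate -> extract round trip."""
    recordings = d.simulate_cohort(default_cohort, geometry)
    return d.extract_cohort_features(recordings, geometry)
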