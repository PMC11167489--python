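import numpy as np
import pytest

from actiprofile import CohortSpec, generate_cohort, generate_epoch_series, ilr_transform


@pytest.fixture(scope="session")
def table_cohort():
    """A study-conditions cohort: n=253, four published profiles, seed 0."""
    return generate_cohort(CohortSpec(n=253, seed=0))


@pytest.fixture(scope="session")
def table_cohort_ilr(table_cohort):
    return ilr_transform(
        table_cohort[["sleep_pct", "sb_pct", "lpa_pct", "mvpa_pct"]].to_numpy()
    )


@pytest.fixture(scope="session")
def epoch_week():
    """Seven days of synthetic minute epochs with known day targets."""
    targets = {"sleep": 450.0, "sb": 600.0, "lpa": 280.0, "mvpa": 80.0}
    return targets, generate_epoch_series(targets, n_days=7, seed=42)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
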