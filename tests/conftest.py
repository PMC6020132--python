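import numpy as np
import pytest

from stopddm import DDMParams, GroupSpec, SessionConfig, SubjectParams, simulate_cohort


@pytest.fixture(scope="session")
def bias_params() -> DDMParams:
    """A high-bias subject: threshold 8.86, start 0.43, drift 8.48, shift 0.28 s."""
    return DDMParams(a=8.86, z=0.43, v=8.48, t=0.28)


@pytest.fixture(scope="session")
def near_deterministic_900ms() -> SubjectParams:
    """Go RT essentially fixed at 900 ms (Wald SD ~0.3 ms), fixed 300 ms stop latency."""
    # decision mean 0.1 s with a(1-z) = 100 makes the variance negligible
    return SubjectParams(
        ddm=DDMParams(a=200.0, z=0.5, v=1000.0, t=0.8),
        ssrt_mean_ms=300.0,
        ssrt_sd_ms=0.0,
    )


@pytest.fixture(scope="session")
def two_group_specs() -> list[GroupSpec]:
    return [
        GroupSpec(label="high-bias", n_subjects=4, z_mean=0.43),
        GroupSpec(label="control", n_subjects=4, z_mean=0.30),
    ]


@pytest.fixture(scope="session")
def small_cohort(two_group_specs):
    """Eight subjects, two blocks each: enough for every summary to exist."""
    return simulate_cohort(two_group_specs, SessionConfig(n_blocks=2), seed=42)
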