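import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from exomirdx import CohortConfig, generate_cohort, preprocess_cohort

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def vector_with_moments(mean: float, sd: float, n: int, rng=None) -> np.ndarray:
    """A length-n sample with exactly the requested mean and sample SD.

    Standardizes an arbitrary base vector (ddof=1), so t-based CIs computed
    from the result are exact functions of (mean, sd, n).
    """
    if rng is None:
        base = np.linspace(-1.0, 1.0, n)
    else:
        base = rng.normal(size=n)
    z = (base - base.mean()) / base.std(ddof=1)
    return mean + sd * z


@pytest.fixture(scope="session")
def moments_vector():
    return vector_with_moments


@pytest.fixture(scope="session")
def cohort():
    """One default study-sized cohort (19 control / 15 PDAC, 18 candidates)."""
    return generate_cohort(CohortConfig(seed=11))


@pytest.fixture(scope="session")
def delta_matrix(cohort):
    raw, _ = cohort
    return preprocess_cohort(raw)


@pytest.fixture(scope="session")
def metadata(cohort):
    return cohort[1]


def make_raw_table(samples_cq: dict, volume: float = 750.0) -> pd.DataFrame:
    """Build a long-format raw table from {sample: {mirna: [rep cqs]}}."""
    rows = []
    for sid, mirnas in samples_cq.items():
        for mid, reps in mirnas.items():
            for i, cq in enumerate(reps, start=1):
                rows.append(
                    {
                        "sample_id": sid,
                        "mirna_id": mid,
                        "replicate": i,
                        "cq": cq,
                        "volume_ul": volume,
                    }
                )
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def raw_table_builder():
    return make_raw_table
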