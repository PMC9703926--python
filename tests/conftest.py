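import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

import sirscan
from sirscan.survival import RegionTable

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_region_table(observed, expected, centroids, adjacency) -> RegionTable:
    """Assemble a RegionTable from plain arrays (test helper)."""
    observed = np.asarray(observed, dtype=float)
    expected = np.asarray(expected, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        sir = np.where(expected > 0, observed / expected, np.nan)
    return RegionTable(
        table=pd.DataFrame(
            {
                "region_id": np.arange(len(observed)),
                "observed": observed,
                "expected": expected,
                "sir": sir,
            }
        ),
        centroids=np.asarray(centroids, dtype=float),
        adjacency=adjacency,
    )


@pytest.fixture(scope="session")
def grid9():
    return sirscan.generate_regions(9, seed=2, layout="grid")


@pytest.fixture(scope="session")
def planar12():
    return sirscan.generate_regions(12, seed=5, layout="random-planar")


@pytest.fixture(scope="session")
def planar59():
    return sirscan.generate_regions(59, seed=7, layout="random-planar")


@pytest.fixture(scope="session")
def small_cohort(planar12):
    """A 30,000-subject simulated cohort with outcomes (session-shared)."""
    cfg = sirscan.SimConfig(n_subjects=30_000, seed=3)
    params = sirscan.HazardParams()
    cohort = sirscan.generate_cohort(cfg, planar12)
    return sirscan.simulate_outcomes(cohort, params, planar12, seed=3)
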