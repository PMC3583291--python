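"""Shared fixtures: the expensive reference ensembles are session-scoped and
reused across analysis, property and acceptance tests."""

from __future__ import annotations

import pytest

from plaquesim import build_model1, build_model2, simulate_ensemble

#: One fixed root seed for the whole suite; per-experiment seeds are offsets.
SUITE_SEED = 20120702


@pytest.fixture(scope="session")
def model1_normal_ens():
    """100 turnover-only cells at the normal clearance rate (100 y, 500 pts)."""
    return simulate_ensemble(build_model1(2.1e-5), 100, base_seed=SUITE_SEED + 1)


@pytest.fixture(scope="session")
def model1_ad_ens():
    """100 turnover-only cells at the AD clearance rate."""
    return simulate_ensemble(build_model1(1.5e-5), 100, base_seed=SUITE_SEED + 2)


@pytest.fixture(scope="session")
def model2_normal_ens():
    """200 aggregation-model cells under normal constant clearance."""
    return simulate_ensemble(build_model2("normal"), 200, base_seed=SUITE_SEED + 3)


@pytest.fixture(scope="session")
def model2_declining_ens():
    """200 aggregation-model cells under age-declining clearance."""
    return simulate_ensemble(build_model2("declining"), 200,
                             base_seed=SUITE_SEED + 4)


@pytest.fixture(scope="session")
def model2_impaired_ens():
    """100 aggregation-model cells with clearance impaired from birth."""
    return simulate_ensemble(build_model2("constant_impaired"), 100,
                             base_seed=SUITE_SEED + 5)


@pytest.fixture(scope="session")
def declining_small_ens():
    """60 declining-clearance cells: shared control arm for interventions."""
    return simulate_ensemble(build_model2("declining"), 60,
                             base_seed=SUITE_SEED + 6)
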