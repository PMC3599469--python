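from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings

from raresieve import SimulationConfig, SitePlan, simulate_cohort

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def cohort(tmp_path_factory):
    """Default imbalanced-chemistry cohort: 10 samples, one cousin pair.

    Shared across tests; treated as read-only.
    """
    out = tmp_path_factory.mktemp("cohort")
    return simulate_cohort(SimulationConfig(seed=101), str(out))


@pytest.fixture(scope="session")
def balanced_cohort(tmp_path_factory):
    """Balanced-chemistry cohort (equal mate lengths, no short-mate class)."""
    out = tmp_path_factory.mktemp("balanced")
    config = SimulationConfig(
        seed=202,
        balanced_pairs=True,
        reference_length=5000,
        mean_coverage=25,
        site_plan=SitePlan(n_true_rare_per_sample=4, n_common=6,
                           n_artefact_mapping=10, n_artefact_pe=6),
    )
    return simulate_cohort(config, str(out))


@pytest.fixture(scope="session")
def cohort_classes(cohort):
    """Map variant identity -> planted site class for the default cohort."""
    return {
        (row.chrom, int(row.pos), row.ref, row.alt): row.site_class
        for row in cohort.truth.table.itertuples()
    }
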