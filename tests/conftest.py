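import dataclasses

import pytest
from hypothesis import HealthCheck, settings

from aluedit import SimParams, simulate_cohort

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


TINY_PARAMS = SimParams(
    n_samples=12,
    n_ighv_mutated=5,
    n_ighv_unmutated=5,
    n_normal_b=4,
    n_contigs=2,
    contig_length=12_000,
    n_alu_pairs=10,
    n_genes=14,
    cds_exon_length=90,
    intron_length=60,
    utr_length=30,
    seed=3,
)


@pytest.fixture(scope="session")
def tiny_cohort():
    """A small but complete synthetic cohort shared across fast tests."""
    return simulate_cohort(TINY_PARAMS)


@pytest.fixture(scope="session")
def default_cohort():
    """The full study-condition cohort (45 CLL + 9 normal B samples)."""
    return simulate_cohort(SimParams(seed=11))


@pytest.fixture()
def tiny_params():
    return dataclasses.replace(TINY_PARAMS)
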