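import pytest

from rxadhere import synth
from rxadhere.pdc import compute_adherence


@pytest.fixture(scope="session")
def cohort5000():
    """Large synthetic cohort shared by the recovery and equivalence tests."""
    cfg = synth.SyntheticCohortConfig(n_patients=5000, seed=11)
    records, truth = synth.generate_cohort(cfg)
    return records, truth


@pytest.fixture(scope="session")
def adherence5000(cohort5000):
    records, _ = cohort5000
    return compute_adherence(records)


@pytest.fixture(scope="session")
def cohort_small():
    cfg = synth.SyntheticCohortConfig(n_patients=100, seed=3)
    records, truth = synth.generate_cohort(cfg)
    return records, truth
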