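import pytest

from qcrvisc import cohort
from qcrvisc.seeding import stage_seed

#: Global seed for test fixtures; per-use seeds derive from it via stage_seed.
SEED = 0


@pytest.fixture(scope="session")
def edta_cohort():
    cfg = cohort.default_config("edta", seed=stage_seed(SEED, "cohort:edta"))
    return cohort.generate_cohort(cfg)


@pytest.fixture(scope="session")
def heparin_cohort():
    cfg = cohort.default_config("heparin", seed=stage_seed(SEED, "cohort:heparin"))
    return cohort.generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_cohort():
    """A fast cohort for classifier mechanics tests (not for accuracy claims)."""
    cfg = cohort.default_config(
        "edta",
        seed=stage_seed(SEED, "cohort:small"),
        n_inflammatory_samples=8,
        n_infectious_samples=4,
        points_per_repeat=10,
        repeats_range=(2, 3),
        target_rows=None,
    )
    return cohort.generate_cohort(cfg)
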