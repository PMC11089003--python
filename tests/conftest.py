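import numpy as np
import pytest

from xenoglia import de
from xenoglia.synthetic import SimCohortConfig, SimImageConfig, simulate_cohort


def small_config(**overrides) -> SimCohortConfig:
    """A cohort small enough for fast tests but with every feature present."""
    base = dict(
        mice_per_group=3,
        cells_per_mouse=120,
        n_genes=400,
        n_mito_genes=8,
        program_size=10,
        seed=11,
    )
    base.update(overrides)
    return SimCohortConfig(**base)


@pytest.fixture(scope="session")
def cohort():
    """One simulated cohort shared across read-only tests."""
    cfg = small_config()
    counts, hashes, truth = simulate_cohort(cfg)
    return cfg, counts, hashes, truth


@pytest.fixture(scope="session")
def marker_cohort():
    """Cohort sized for marker recovery: ~200 cells per state, 2 states."""
    cfg = small_config(
        group_names=("g1",),
        state_names=("HM", "DAM"),
        state_proportions_per_group=((0.5, 0.5),),
        mice_per_group=2,
        cells_per_mouse=400,
        n_genes=600,
        program_size=20,
        doublet_rate=0.0,
        negative_rate=0.0,
        dirichlet_concentration=1e7,
        seed=3,
    )
    counts, hashes, truth = simulate_cohort(cfg)
    norm = de.normalize_log(counts)
    return cfg, counts, truth, norm


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
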