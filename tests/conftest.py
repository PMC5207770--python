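import numpy as np
import pandas as pd
import pytest

from methadmix.simulate import (
    EthnicityProfile,
    SimulationConfig,
    ethnicity_profile,
    simulate_study,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def two_group_config(n_per_group=100, **overrides) -> SimulationConfig:
    kwargs = dict(
        profiles=[
            ethnicity_profile("Mexican", n_per_group),
            ethnicity_profile("PuertoRican", n_per_group),
        ],
        n_snps=80,
        n_cpgs=120,
        n_meqtl=10,
        n_ancestry_cpgs=15,
        n_env_cpgs=15,
    )
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)


@pytest.fixture(scope="session")
def small_study():
    """Shared 200-sample, 120-CpG study with all effect classes present."""
    return simulate_study(two_group_config(), seed=7)


@pytest.fixture(scope="session")
def diverse_cohort():
    """A single broadly admixed group: large ancestry variance, no
    between-group structure — the regime where global-ancestry effects are
    individually detectable."""
    profile = EthnicityProfile("Admixed", np.array([2.0, 2.0, 2.0]), 500)
    rng = np.random.default_rng(99)
    q = pd.DataFrame(
        rng.dirichlet(profile.dirichlet_alpha, size=profile.n),
        index=[f"S{i:04d}" for i in range(profile.n)],
        columns=["AFR", "EUR", "NAM"],
    )
    return q
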