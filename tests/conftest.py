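import numpy as np
import pytest

from glyctraj import default_registry_config, generate_cohort
from glyctraj.cohort import build_cohort
from glyctraj.lcga import BasisSpec, StackedData


@pytest.fixture(scope="session")
def small_registry():
    """Default five-class population at n=300 (shared across tests)."""
    cfg = default_registry_config(n_subjects=300, seed=9)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_cohort(small_registry):
    r = small_registry
    return build_cohort(r.measurements, r.subjects, r.events, rng_seed=0)


@pytest.fixture(scope="session")
def midsize_recovery():
    """n=2000 default-population registry + cohort, for recovery tests."""
    cfg = default_registry_config(n_subjects=2000, seed=42)
    reg = generate_cohort(cfg)
    co = build_cohort(reg.measurements, reg.subjects, reg.events, rng_seed=0)
    return cfg, reg, co


def make_two_level_trajectories(
    n=24, levels=(6.5, 8.0), sd=0.4, n_meas=6, t_max=200.0, seed=3
):
    """Alternating two-level linear trajectories; tiny EM test bed."""
    rng = np.random.default_rng(seed)
    times, vals = [], []
    for i in range(n):
        t = np.sort(rng.uniform(0, t_max, n_meas))
        mu = levels[i % len(levels)] + 0.002 * t
        times.append(t)
        vals.append(mu + rng.normal(0, sd, n_meas))
    return times, vals


@pytest.fixture()
def two_level_data():
    return make_two_level_trajectories()


@pytest.fixture()
def two_level_stacked(two_level_data):
    return StackedData.build(two_level_data, BasisSpec("linear"))
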