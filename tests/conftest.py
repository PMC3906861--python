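import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from codsge import (
    SimConfig,
    build_A,
    build_A_inverse,
    build_matrices,
    simulate_dataset,
)
from codsge.reml import VarianceComponents

#: strongly social fin-length truth (trait scale mm): the headline simulation
#: world, with σ²_e chosen so that σ²_P = 11.41 at n = 21
TRUE_VC = VarianceComponents(
    sigma2_AD=6.13,
    sigma2_AS=0.03,
    sigma_ADS=0.23,
    sigma2_c=0.51,
    sigma2_t=0.15,
    sigma2_e=4.02,
)

#: same world with the social terms removed (null for LRT calibration)
NULL_VC = VarianceComponents(
    sigma2_AD=6.13,
    sigma2_AS=0.0,
    sigma_ADS=0.0,
    sigma2_c=0.51,
    sigma2_t=0.15,
    sigma2_e=4.02,
)


def small_config(vc=TRUE_VC, **overrides) -> SimConfig:
    """8 families × 6 offspring in 8 tanks of 6 (3 families × 2 fish)."""
    kw = dict(
        n_families=8,
        offspring_per_family=6,
        n_groups_per_family=3,
        n_tanks=8,
        families_per_tank=3,
        n_sires=6,
        n_dams=8,
        vc=vc,
    )
    kw.update(overrides)
    return SimConfig(**kw)


def tiny_config(vc=TRUE_VC, **overrides) -> SimConfig:
    """4 families × 6 offspring in 4 tanks of 6 — 24 observations."""
    kw = dict(
        n_families=4,
        offspring_per_family=6,
        n_groups_per_family=3,
        n_tanks=4,
        families_per_tank=3,
        n_sires=3,
        n_dams=4,
        vc=vc,
    )
    kw.update(overrides)
    return SimConfig(**kw)


def calibration_config(vc=NULL_VC, **overrides) -> SimConfig:
    """20 tanks × 6 fish, the scaled-down null-calibration design."""
    kw = dict(
        n_families=20,
        offspring_per_family=6,
        n_groups_per_family=3,
        n_tanks=20,
        families_per_tank=3,
        n_sires=15,
        n_dams=20,
        vc=vc,
    )
    kw.update(overrides)
    return SimConfig(**kw)


@pytest.fixture(scope="session")
def small_sim():
    """One seeded small replicate with matrices and relationship structures."""
    res = simulate_dataset(small_config(), seed=1)
    A = build_A(res.ped)
    Ainv = build_A_inverse(res.ped)
    mm_s = build_matrices(res.table, res.groups, res.ped, "finD1", 3, "social")
    mm_c = build_matrices(res.table, res.groups, res.ped, "finD1", 3, "conventional")
    return dict(res=res, A=A, Ainv=Ainv, mm_social=mm_s, mm_conventional=mm_c)


@pytest.fixture()
def rng():
    return np.random.default_rng(20140124)
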