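import numpy as np
import pandas as pd
import pytest

from codsge import (
    Pedigree,
    SimConfig,
    build_A,
    build_groups,
    simulate_breeding_values,
    simulate_dataset,
    simulate_design,
    simulate_pedigree,
    total_breeding_variance,
)
from codsge.reml import VarianceComponents
from codsge.simulate import family_of
from conftest import TRUE_VC, small_config, tiny_config


class TestPedigreeGeneration:
    def test_default_counts_match_experiment(self):
        cfg = SimConfig()
        ped = simulate_pedigree(cfg, np.random.default_rng(0))
        n_offspring = int((~ped.founder_mask).sum())
        assert n_offspring == 2100
        assert int(ped.founder_mask.sum()) == 73 + 100
        sires_used = {ped.ids[s] for s in ped.sire[ped.sire >= 0]}
        assert len(sires_used) == 73  # every sire contributes

    def test_sire_reuse_creates_half_sibs(self):
        cfg = SimConfig(
            n_families=3, offspring_per_family=2, n_groups_per_family=1,
            n_tanks=1, families_per_tank=3, n_sires=2, n_dams=3,
        )
        ped = simulate_pedigree(cfg, np.random.default_rng(1))
        assert len(ped) == 2 + 3 + 6
        A = build_A(ped)
        off = np.where(~ped.founder_mask)[0]
        rel = {round(A[i, j], 2) for i in off for j in off if i < j}
        assert 0.25 in rel

    def test_seeded_determinism(self):
        p1 = simulate_pedigree(SimConfig(), np.random.default_rng(9))
        p2 = simulate_pedigree(SimConfig(), np.random.default_rng(9))
        assert p1.ids == p2.ids and np.array_equal(p1.sire, p2.sire)


class TestDesignGeneration:
    def test_default_design_constraints(self):
        cfg = SimConfig()
        rng = np.random.default_rng(2)
        simulate_pedigree(cfg, rng)
        groups = simulate_design(cfg, rng)
        assert len(groups.tanks) == 100
        fam_tank_count: dict[str, int] = {}
        for tank in groups.tanks:
            members = groups.members[tank]
            assert len(members) == 21
            fams = [family_of(m) for m in members]
            counts = pd.Series(fams).value_counts()
            assert len(counts) == 3 and set(counts) == {7}
            for f in counts.index:
                fam_tank_count[f] = fam_tank_count.get(f, 0) + 1
        assert set(fam_tank_count.values()) == {3}  # each family in 3 tanks

    def test_toy_design_same_constraints(self):
        cfg = tiny_config()
        rng = np.random.default_rng(3)
        groups = simulate_design(cfg, rng)
        for tank in groups.tanks:
            fams = {family_of(m) for m in groups.members[tank]}
            assert len(fams) == cfg.families_per_tank

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError, match="fill the tanks"):
            SimConfig(n_families=10, n_tanks=5, n_dams=10, n_sires=8)


class TestPhenotypeGeneration:
    def test_all_variances_zero_gives_fixed_part_exactly(self):
        vc0 = VarianceComponents(0.0, 0.0, 0.0, 0.0, 0.0, 0.0)
        cfg = small_config(vc=vc0, scorer_effects=(0.0, 0.0, 0.0))
        res = simulate_dataset(cfg, seed=5)
        y = res.table.trait_values("finD1", 3)
        expected = cfg.mean + cfg.age_slope * res.table.age(3)
        assert np.allclose(y, expected, atol=1e-12)

    def test_pairwise_difference_in_two_fish_tanks(self):
        # tanks of n = 2: y₁ − y₂ = (a_D,1 − a_D,2) − (a_S,1 − a_S,2)
        vc = VarianceComponents(3.0, 0.8, 0.0, 0.0, 0.0, 0.0)
        cfg = SimConfig(
            n_families=4, offspring_per_family=2, n_groups_per_family=2,
            n_tanks=4, families_per_tank=2, n_sires=3, n_dams=4,
            vc=vc, age_slope=0.0, scorer_effects=(0.0, 0.0, 0.0),
            hatch_jitter_days=0,
        )
        res = simulate_dataset(cfg, seed=6)
        aD = {res.ped.ids[k]: res.breeding_values[k, 0] for k in range(len(res.ped))}
        aS = {res.ped.ids[k]: res.breeding_values[k, 1] for k in range(len(res.ped))}
        y = res.table.trait_values("finD1", 3)
        y_by_id = dict(zip(res.table.df["id"], y))
        for tank, (i1, i2) in ((t, m) for t, m in res.groups.members.items()):
            lhs = y_by_id[i1] - y_by_id[i2]
            rhs = (aD[i1] - aD[i2]) - (aS[i1] - aS[i2])
            assert lhs == pytest.approx(rhs, abs=1e-10)

    def test_breeding_value_covariances_through_pedigree(self):
        """Mendelian-sampling recursion reproduces G ⊗ A: full sibs correlate
        at ½σ²_AD on the direct scale and founder pairs (a_D, a_S) covary at
        σ_ADS."""
        n_fam = 20_000
        entries = []
        for m in range(n_fam):
            entries += [
                (f"s{m}", None, None),
                (f"d{m}", None, None),
                (f"a{m}", f"s{m}", f"d{m}"),
                (f"b{m}", f"s{m}", f"d{m}"),
            ]
        ped = Pedigree.from_entries(entries)
        u = simulate_breeding_values(ped, TRUE_VC.G, np.random.default_rng(12))
        ix = {ped.ids[k]: k for k in range(len(ped))}
        sib1 = np.array([u[ix[f"a{m}"], 0] for m in range(n_fam)])
        sib2 = np.array([u[ix[f"b{m}"], 0] for m in range(n_fam)])
        founders_u = np.array([u[ix[f"s{m}"]] for m in range(n_fam)])
        mc_tol = 4.0 / np.sqrt(n_fam)
        assert np.cov(sib1, sib2)[0, 1] == pytest.approx(
            0.5 * TRUE_VC.sigma2_AD, rel=0.05
        )
        assert np.var(sib1) == pytest.approx(TRUE_VC.sigma2_AD, rel=0.05)
        assert np.cov(founders_u[:, 0], founders_u[:, 1])[0, 1] == pytest.approx(
            TRUE_VC.sigma_ADS, abs=mc_tol
        )

    def test_tbv_variance_matches_formula(self):
        """Empirical Var(a_D + 20·a_S) over 20 000 unrelated individuals is
        within 2% of the σ²_TBV formula."""
        ped = Pedigree.from_entries([(f"f{i}", None, None) for i in range(20_000)])
        u = simulate_breeding_values(ped, TRUE_VC.G, np.random.default_rng(42))
        tbv = u[:, 0] + 20.0 * u[:, 1]
        formula = total_breeding_variance(TRUE_VC, 21)
        assert np.var(tbv) == pytest.approx(formula, rel=0.02)

    def test_end_to_end_seeded_determinism(self):
        r1 = simulate_dataset(small_config(), seed=77)
        r2 = simulate_dataset(small_config(), seed=77)
        pd.testing.assert_frame_equal(r1.table.df, r2.table.df)
        r3 = simulate_dataset(small_config(), seed=78)
        assert not r3.table.df.equals(r1.table.df)

    def test_mortality_mask_keeps_partners(self):
        cfg = small_config(n_missing=5)
        res = simulate_dataset(cfg, seed=8)
        col = "finD1_3"
        assert int(res.table.df[col].isna().sum()) == 5
        groups = build_groups(res.table)
        assert set(groups.sizes.values()) == {cfg.tank_size}
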