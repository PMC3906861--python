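"""Synthetic cod-experiment generator.

Emulates the experiment's structure end to end: 100 full-sib families from
73 sires × 100 dams (sire reuse creating half-sib links), 21 tagged offspring
per family split into three groups of seven, 100 experimental tanks each
receiving three groups from three distinct families (21 fish per tank), and
phenotypes generated under the social animal model

    y_i = μ + β·age_i [+ scorer] + a_D,i + Σ_{j ∈ tank mates} a_S,j
          + c_family(i) + t_tank(i) + e_i,

with bivariate breeding values (a_D, a_S) propagated through the pedigree by
Mendelian-sampling recursion so that Cov(vec(a)) = G ⊗ A exactly.

Default true variance components are a strongly social fin-length world
(trait scale: mm): σ²_AD = 6.13, σ²_AS = 0.03, σ_ADS = 0.23, σ²_c = 0.51,
σ²_t = 0.15, σ²_e = 4.02 (σ²_P = 11.41 at n = 21).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .design import GroupStructure
from .pedigree import UNKNOWN, Pedigree, mendelian_variance
from .phenotypes import FIN_LENGTH_TRAITS, TraitTable, write_phenotypes
from .pedigree import write_pedigree
from .reml import VarianceComponents

DEFAULT_TRUE_VC = VarianceComponents(
    sigma2_AD=6.13,
    sigma2_AS=0.03,
    sigma_ADS=0.23,
    sigma2_c=0.51,
    sigma2_t=0.15,
    sigma2_e=4.02,
)


@dataclass
class SimConfig:
    """Stated world of the emulated experiment.

    The defaults reproduce the design counts of the cod study; scaled-down
    configurations (for fast calibration experiments) keep the same structure
    with smaller numbers.
    """

    n_families: int = 100
    offspring_per_family: int = 21
    n_groups_per_family: int = 3
    n_tanks: int = 100
    families_per_tank: int = 3
    n_sires: int = 73
    n_dams: int = 100
    vc: VarianceComponents = field(default_factory=lambda: DEFAULT_TRUE_VC)
    mean: float = 15.8
    age_slope: float = 0.05
    scorer_effects: tuple[float, float, float] = (0.0, 0.4, -0.3)
    scorer_props: tuple[float, float, float] = (0.40, 0.49, 0.11)
    base_age_days: int = 222
    recording_offsets: tuple[int, int, int] = (0, 14, 42)
    hatch_jitter_days: int = 10
    trait: str = "finD1"
    recording: int = 3
    n_missing: int = 0

    def __post_init__(self) -> None:
        if self.n_dams != self.n_families:
            raise ValueError("one dam per family: n_dams must equal n_families")
        if self.n_sires > self.n_dams:
            raise ValueError("need n_sires <= n_dams for sire reuse")
        if self.offspring_per_family % self.n_groups_per_family:
            raise ValueError("offspring_per_family must split evenly into groups")
        total_groups = self.n_families * self.n_groups_per_family
        if total_groups != self.n_tanks * self.families_per_tank:
            raise ValueError(
                "family groups must fill the tanks exactly: "
                f"{total_groups} groups vs {self.n_tanks} tanks × {self.families_per_tank}"
            )
        self.vc.validate()

    @property
    def group_split(self) -> int:
        return self.offspring_per_family // self.n_groups_per_family

    @property
    def tank_size(self) -> int:
        return self.families_per_tank * self.group_split

    @property
    def n_offspring(self) -> int:
        return self.n_families * self.offspring_per_family


def simulate_pedigree(cfg: SimConfig, rng: np.random.Generator) -> Pedigree:
    """Founders plus one full-sib family of offspring per dam.

    Sires are mated to dams with reuse: ``n_dams − n_sires`` randomly chosen
    sires serve two dams (half-sib links); the rest serve one.
    """
    n_extra = cfg.n_dams - cfg.n_sires
    sire_pool = np.concatenate(
        [np.arange(cfg.n_sires), rng.choice(cfg.n_sires, size=n_extra, replace=False)]
    )
    rng.shuffle(sire_pool)
    entries: list[tuple[str, str | None, str | None]] = []
    for s in range(cfg.n_sires):
        entries.append((f"S{s + 1}", None, None))
    for d in range(cfg.n_dams):
        entries.append((f"D{d + 1}", None, None))
    for f in range(cfg.n_families):
        sire_id = f"S{sire_pool[f] + 1}"
        dam_id = f"D{f + 1}"
        for k in range(cfg.offspring_per_family):
            entries.append((f"F{f + 1}_{k + 1}", sire_id, dam_id))
    return Pedigree.from_entries(entries)


def family_of(ind_id: str) -> str:
    """Family label of a simulated offspring id (``F<f>_<k>`` → ``F<f>``)."""
    return ind_id.split("_")[0]


def simulate_design(
    cfg: SimConfig, rng: np.random.Generator, max_tries: int = 10_000
) -> GroupStructure:
    """Random assignment of family groups to tanks, no family twice per tank.

    Each family's offspring are shuffled and split into equal groups; the
    groups are then repeatedly dealt into tanks until every tank holds groups
    from distinct families (rejection sampling; a handful of tries at the
    default sizes).
    """
    groups_by_family: list[tuple[int, list[str]]] = []
    for f in range(cfg.n_families):
        ids = [f"F{f + 1}_{k + 1}" for k in range(cfg.offspring_per_family)]
        perm = rng.permutation(len(ids))
        split = cfg.group_split
        for g in range(cfg.n_groups_per_family):
            members = [ids[i] for i in perm[g * split : (g + 1) * split]]
            groups_by_family.append((f, members))

    n_groups = len(groups_by_family)
    for _ in range(max_tries):
        order = rng.permutation(n_groups)
        ok = True
        for t in range(cfg.n_tanks):
            fams = [
                groups_by_family[order[t * cfg.families_per_tank + j]][0]
                for j in range(cfg.families_per_tank)
            ]
            if len(set(fams)) != cfg.families_per_tank:
                ok = False
                break
        if ok:
            members: dict[str, list[str]] = {}
            rearing: dict[str, str] = {}
            for t in range(cfg.n_tanks):
                tank_id = f"T{t + 1}"
                inds: list[str] = []
                for j in range(cfg.families_per_tank):
                    fam, ids = groups_by_family[order[t * cfg.families_per_tank + j]]
                    inds.extend(ids)
                    for i in ids:
                        rearing[i] = f"F{fam + 1}"
                members[tank_id] = inds
            return GroupStructure(members=members, rearing_group_of=rearing)
    raise RuntimeError(f"no valid tank assignment found in {max_tries} tries")


def simulate_breeding_values(
    ped: Pedigree, G: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Bivariate (direct, social) breeding values with Cov(vec) = G ⊗ A.

    Mendelian-sampling recursion down the topologically sorted pedigree:
    founders ~ N(0, G); an offspring is the parental mean plus a deviation
    with covariance d_i·G, d_i = ½ − ¼(F_s + F_d) (adjusted when a parent is
    unknown). Returns an (n, 2) array, column 0 direct, column 1 social.
    """
    d = mendelian_variance(ped)
    n = len(ped)
    tr = float(np.trace(G))
    if tr <= 0:
        return np.zeros((n, 2))
    L = np.linalg.cholesky(G + 1e-14 * tr * np.eye(2))
    z = rng.standard_normal((n, 2)) @ L.T

    # process generation levels in bulk: individuals within a level are
    # conditionally independent given their (earlier-level) parents
    sire, dam = ped.sire, ped.dam
    level = np.zeros(n, dtype=np.int64)
    for i in range(n):
        lv = 0
        if sire[i] != UNKNOWN:
            lv = level[sire[i]] + 1
        if dam[i] != UNKNOWN:
            lv = max(lv, level[dam[i]] + 1)
        level[i] = lv

    u = np.zeros((n, 2))
    sd = np.sqrt(d)[:, None]
    for lv in range(int(level.max()) + 1):
        idx = np.where(level == lv)[0]
        mean = np.zeros((len(idx), 2))
        s_known = sire[idx] != UNKNOWN
        d_known = dam[idx] != UNKNOWN
        mean[s_known] += 0.5 * u[sire[idx][s_known]]
        mean[d_known] += 0.5 * u[dam[idx][d_known]]
        u[idx] = mean + sd[idx] * z[idx]
    return u


def simulate_phenotypes(
    ped: Pedigree,
    groups: GroupStructure,
    cfg: SimConfig,
    rng: np.random.Generator,
    return_effects: bool = False,
):
    """Phenotype table under the social animal model.

    Every offspring gets the configured trait at the configured recording;
    ``cfg.n_missing`` randomly chosen fish have the value masked (mimicking
    mortality) while remaining social partners and pedigree members.
    """
    u = simulate_breeding_values(ped, cfg.vc.G, rng)
    a_D = {ped.ids[k]: u[k, 0] for k in range(len(ped))}
    a_S = {ped.ids[k]: u[k, 1] for k in range(len(ped))}

    fam_ids = sorted({groups.rearing_group_of[i] for t in groups.members.values() for i in t})
    c_eff = dict(zip(fam_ids, rng.normal(0.0, np.sqrt(cfg.vc.sigma2_c), len(fam_ids))))
    t_eff = dict(
        zip(groups.tanks, rng.normal(0.0, np.sqrt(cfg.vc.sigma2_t), len(groups.tanks)))
    )
    jitter = dict(
        zip(
            fam_ids,
            rng.integers(-cfg.hatch_jitter_days, cfg.hatch_jitter_days + 1, len(fam_ids)),
        )
    )

    rows = []
    fin_trait = cfg.trait in FIN_LENGTH_TRAITS
    rec = cfg.recording
    for tank in groups.tanks:
        inds = groups.members[tank]
        for ind in inds:
            fam = groups.rearing_group_of[ind]
            ages = [
                cfg.base_age_days + off + jitter[fam] for off in cfg.recording_offsets
            ]
            scorer = int(rng.choice(3, p=cfg.scorer_props)) + 1
            social_sum = sum(a_S[m] for m in inds if m != ind)
            fixed = cfg.mean + cfg.age_slope * ages[rec - 1]
            if fin_trait:
                fixed += cfg.scorer_effects[scorer - 1]
            e_i = rng.normal(0.0, np.sqrt(cfg.vc.sigma2_e))
            value = fixed + a_D[ind] + social_sum + c_eff[fam] + t_eff[tank] + e_i
            row = {
                "id": ind,
                "family": fam,
                "rearing_group": fam,
                "tank": tank,
                "scorer": scorer,
                "age1": ages[0],
                "age2": ages[1],
                "age3": ages[2],
            }
            col = f"{cfg.trait}_{rec}" if cfg.trait.startswith("fin") else f"{cfg.trait}{rec}"
            row[col] = value
            rows.append(row)
    df = pd.DataFrame(rows)

    if cfg.n_missing > 0:
        col = f"{cfg.trait}_{rec}" if cfg.trait.startswith("fin") else f"{cfg.trait}{rec}"
        dead = rng.choice(len(df), size=cfg.n_missing, replace=False)
        df.loc[dead, col] = np.nan

    table = TraitTable(df)
    if return_effects:
        return table, u
    return table


@dataclass
class SimResult:
    cfg: SimConfig
    ped: Pedigree
    groups: GroupStructure
    table: TraitTable
    breeding_values: np.ndarray  # (pedigree size, 2): direct, social


def simulate_dataset(cfg: SimConfig | None = None, seed: int = 0) -> SimResult:
    """One fully seeded replicate of the experiment (pedigree → phenotypes)."""
    cfg = cfg or SimConfig()
    rng = np.random.default_rng(seed)
    ped = simulate_pedigree(cfg, rng)
    groups = simulate_design(cfg, rng)
    table, u = simulate_phenotypes(ped, groups, cfg, rng, return_effects=True)
    return SimResult(cfg=cfg, ped=ped, groups=groups, table=table, breeding_values=u)


def write_dataset(result: SimResult, outdir) -> None:
    """Write pedigree CSV, phenotype CSV and the true-parameter record."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_pedigree(result.ped, outdir / "pedigree.csv")
    write_phenotypes(result.table, outdir / "phenotypes.csv")
    pd.DataFrame(
        [(t, i) for t, inds in result.groups.members.items() for i in inds],
        columns=["tank", "id"],
    ).to_csv(outdir / "groups.csv", index=False)
    truth = {
        "vc": {k: getattr(result.cfg.vc, k) for k in (
            "sigma2_AD", "sigma2_AS", "sigma_ADS", "sigma2_c", "sigma2_t", "sigma2_e")},
        "mean": result.cfg.mean,
        "age_slope": result.cfg.age_slope,
        "trait": result.cfg.trait,
        "recording": result.cfg.recording,
    }
    (outdir / "truth.json").write_text(json.dumps(truth, indent=2))
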