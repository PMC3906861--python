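"""Group structure and model-matrix construction for the animal models.

The conventional model is  y = Xb + Z_D a_D + W_c c + W_t t + e ; the social
model adds  Z_S a_S , where row i of Z_S carries a 1 for every tank mate of
fish i (never for i itself). Fixed effects are an intercept, the age of the
fish at the recording (centred for conditioning), and — for fin-length traits
only — the scorer factor (three persons measured the digital images).

Genetic incidence matrices span *all* pedigree individuals, ancestors
included, so the sparse A⁻¹ applies directly in the mixed-model equations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

from .pedigree import Pedigree
from .phenotypes import FIN_LENGTH_TRAITS, TraitTable

logger = logging.getLogger(__name__)


class DesignError(ValueError):
    """Invalid group/tank structure."""


@dataclass
class GroupStructure:
    """Tank → ordered member list, with per-individual lookups."""

    members: dict[str, list[str]]
    tank_of: dict[str, str] = field(default_factory=dict)
    rearing_group_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.tank_of:
            self.tank_of = {
                ind: tank for tank, inds in self.members.items() for ind in inds
            }
        for tank, inds in self.members.items():
            if len(inds) < 2:
                raise DesignError(f"tank {tank!r} has fewer than 2 members")
        counts: dict[str, int] = {}
        for inds in self.members.values():
            for ind in inds:
                counts[ind] = counts.get(ind, 0) + 1
        multi = [ind for ind, c in counts.items() if c > 1]
        if multi:
            raise DesignError(f"individual {multi[0]!r} listed in more than one tank")

    @property
    def tanks(self) -> list[str]:
        return list(self.members)

    def size(self, tank: str) -> int:
        return len(self.members[tank])

    @property
    def sizes(self) -> dict[str, int]:
        return {tank: len(inds) for tank, inds in self.members.items()}


def build_groups(records: TraitTable) -> GroupStructure:
    """Group structure from the tank / rearing-group columns of the table."""
    df = records.df
    members: dict[str, list[str]] = {}
    for tank, sub in df.groupby("tank", sort=False):
        members[str(tank)] = [str(i) for i in sub["id"]]
    rg = {str(r.id): str(r.rearing_group) for r in df.itertuples()}
    return GroupStructure(members=members, rearing_group_of=rg)


def read_groups(path) -> GroupStructure:
    """Optional `tank,id` CSV; overrides the phenotype table's tank column."""
    df = pd.read_csv(path, dtype=str)
    members: dict[str, list[str]] = {}
    for r in df.itertuples():
        members.setdefault(str(r.tank), []).append(str(r.id))
    return GroupStructure(members=members)


@dataclass
class ModelMatrices:
    """Response, fixed and random-effect incidence matrices for one trait.

    ``Z_D``/``Z_S`` have one column per pedigree individual; ``W_c``/``W_t``
    one per rearing-group / tank level present among the retained rows.
    ``Z_S`` is ``None`` for the conventional model. ``tank_sizes`` records the
    nominal group size backing each observation (for derived parameters).
    """

    y: np.ndarray
    X: np.ndarray
    Z_D: sparse.csr_matrix
    Z_S: sparse.csr_matrix | None
    W_c: sparse.csr_matrix | None
    W_t: sparse.csr_matrix | None
    obs_ids: list[str]
    x_labels: list[str]
    c_levels: list[str]
    t_levels: list[str]
    tank_sizes: np.ndarray | None = None

    @property
    def n_obs(self) -> int:
        return self.y.shape[0]

    @property
    def model(self) -> str:
        return "social" if self.Z_S is not None else "conventional"


def _indicator(levels: pd.Series) -> tuple[sparse.csr_matrix, list[str]]:
    cats = pd.Categorical(levels)
    n = len(levels)
    mat = sparse.csr_matrix(
        (np.ones(n), (np.arange(n), cats.codes)), shape=(n, len(cats.categories))
    )
    return mat, [str(c) for c in cats.categories]


def build_matrices(
    records: TraitTable,
    groups: GroupStructure,
    ped: Pedigree,
    trait: str,
    recording: int = 3,
    model: str = "social",
) -> ModelMatrices:
    """Assemble y, X, Z_D, Z_S, W_c, W_t for one trait/recording/model.

    Rows with a missing trait value are dropped from y, but the dropped fish
    keep their genetic columns and still appear as social partners in the
    Z_S rows of their tank mates (their genes act on the group whether or not
    their own phenotype was recorded).
    """
    if model not in ("conventional", "social"):
        raise ValueError("model must be 'conventional' or 'social'")
    df = records.df
    y_all = records.trait_values(trait, recording).to_numpy(dtype=float)
    keep = ~np.isnan(y_all)
    if not keep.any():
        raise DesignError(f"no phenotypes available for {trait!r} recording {recording}")
    sub = df.loc[keep].reset_index(drop=True)
    y = y_all[keep]
    obs_ids = [str(i) for i in sub["id"]]

    for ind in obs_ids:
        if ind not in ped.index:
            raise DesignError(f"phenotyped individual {ind!r} absent from pedigree")
        if ind not in groups.tank_of:
            raise DesignError(f"phenotyped individual {ind!r} has no tank assignment")

    n = len(sub)
    q = len(ped)

    # --- fixed effects: intercept + centred age (+ scorer contrasts) -------
    cols = [np.ones(n)]
    labels = ["intercept"]
    age_col = f"age{recording}"
    if age_col in sub.columns and not sub[age_col].isna().all():
        age = sub[age_col].to_numpy(dtype=float)
        if np.ptp(age) > 0:
            cols.append(age - age.mean())
            labels.append("age")
    if trait in FIN_LENGTH_TRAITS and "scorer" in sub.columns:
        scorers = sub["scorer"].astype(str)
        levels = sorted(scorers.unique())
        if len(levels) >= 2:
            for lev in levels[1:]:  # first level is the reference
                cols.append((scorers == lev).to_numpy(dtype=float))
                labels.append(f"scorer[{lev}]")
        else:
            logger.warning("single scorer level; scorer factor dropped")
    X = np.column_stack(cols)

    # --- genetic incidence over the full pedigree --------------------------
    own = np.array([ped.index[i] for i in obs_ids])
    Z_D = sparse.csr_matrix((np.ones(n), (np.arange(n), own)), shape=(n, q))

    Z_S = None
    tank_sizes = np.zeros(n)
    rows_s: list[int] = []
    cols_s: list[int] = []
    for r, ind in enumerate(obs_ids):
        tank = groups.tank_of[ind]
        mates = [m for m in groups.members[tank] if m != ind]
        tank_sizes[r] = len(mates) + 1
        if model == "social":
            for m in mates:
                if m not in ped.index:
                    raise DesignError(f"social partner {m!r} absent from pedigree")
                rows_s.append(r)
                cols_s.append(ped.index[m])
    if model == "social":
        Z_S = sparse.csr_matrix(
            (np.ones(len(rows_s)), (rows_s, cols_s)), shape=(n, q)
        )

    # --- environmental incidences ------------------------------------------
    rearing = sub["rearing_group"].astype(str)
    W_c, c_levels = _indicator(rearing)
    tanks = pd.Series([groups.tank_of[i] for i in obs_ids])
    W_t, t_levels = _indicator(tanks)

    return ModelMatrices(
        y=y,
        X=X,
        Z_D=Z_D,
        Z_S=Z_S,
        W_c=W_c,
        W_t=W_t,
        obs_ids=obs_ids,
        x_labels=labels,
        c_levels=c_levels,
        t_levels=t_levels,
        tank_sizes=tank_sizes,
    )
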