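"""Per-fish records and derived growth/condition traits.

Phenotypes live in a wide table with one row per fish and per-recording
columns (three recordings: stocking, two weeks, six weeks). Derived traits:

* condition factor  CF = weight / length³  (g, cm → dimensionless, ~0.009 for
  juvenile cod; an index of plumpness under cubic allometry);
* change in condition factor  CCF = CF₃ − CF₁;
* specific growth rate  SGR = (ln w₃ − ln w₁)/(t₃ − t₁) × 100  (%/day).

Missing values propagate as NaN for per-record derivations; structurally
invalid inputs (non-positive weight/length, non-increasing times) raise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: default elapsed time between recordings 1 and 3 (days); the experiment
#: ran for six weeks
DEFAULT_DURATION_DAYS = 42.0

RECORDINGS = (1, 2, 3)

#: analysis traits measured per recording → column stem
PER_RECORDING_TRAITS = {
    "weight": "weight",
    "length": "length",
    "finD1": "finD1",
    "finD2": "finD2",
    "finD3": "finD3",
    "finC": "finC",
}
#: fin erosion is scored once, at recording 3
EROSION_TRAITS = {"eroD1", "eroD2", "eroD3", "eroC"}
#: derived whole-experiment traits
DERIVED_TRAITS = {"sgr", "ccf"}

FIN_LENGTH_TRAITS = {"finD1", "finD2", "finD3", "finC"}

PHENOTYPE_COLUMNS = (
    ["id", "family", "rearing_group", "tank", "scorer"]
    + [f"age{r}" for r in RECORDINGS]
    + [f"weight{r}" for r in RECORDINGS]
    + [f"length{r}" for r in RECORDINGS]
    + [f"finD1_{r}" for r in RECORDINGS]
    + [f"finD2_{r}" for r in RECORDINGS]
    + [f"finD3_{r}" for r in RECORDINGS]
    + [f"finC_{r}" for r in RECORDINGS]
    + ["eroD1", "eroD2", "eroD3", "eroC"]
)


def condition_factor(weight_g, length_cm):
    """CF = weight / length³. NaN inputs give NaN; non-positive inputs raise."""
    w = np.asarray(weight_g, dtype=float)
    l = np.asarray(length_cm, dtype=float)
    if np.any(w[~np.isnan(w)] <= 0) or np.any(l[~np.isnan(l)] <= 0):
        raise ValueError("weight and length must be positive")
    out = w / l**3
    return float(out) if out.ndim == 0 else out


def change_in_condition_factor(weight1_g, length1_cm, weight3_g, length3_cm):
    """CCF = CF₃ − CF₁; missing inputs propagate to a missing result."""
    return condition_factor(weight3_g, length3_cm) - condition_factor(
        weight1_g, length1_cm
    )


def specific_growth_rate(weight1_g, weight3_g, t1_days, t3_days):
    """SGR = (ln w₃ − ln w₁) / (t₃ − t₁) × 100, in % per day."""
    w1 = np.asarray(weight1_g, dtype=float)
    w3 = np.asarray(weight3_g, dtype=float)
    t1 = np.asarray(t1_days, dtype=float)
    t3 = np.asarray(t3_days, dtype=float)
    if np.any(w1[~np.isnan(w1)] <= 0) or np.any(w3[~np.isnan(w3)] <= 0):
        raise ValueError("weights must be positive")
    if np.any(t3 <= t1):
        raise ValueError("t3 must exceed t1")
    out = (np.log(w3) - np.log(w1)) / (t3 - t1) * 100.0
    return float(out) if out.ndim == 0 else out


@dataclass
class TraitTable:
    """Wide per-fish phenotype table plus trait extraction.

    One row per fish; ids are strings and must be resolvable in the pedigree
    used for the genetic model. ``trait_values`` returns the analysis vector
    for one (trait, recording) pair with NaN marking missing records.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in ("id", "family", "rearing_group", "tank") if c not in self.df.columns]
        if missing:
            raise ValueError(f"phenotype table lacks columns {missing}")
        if self.df["id"].duplicated().any():
            dup = self.df.loc[self.df["id"].duplicated(), "id"].iloc[0]
            raise ValueError(f"duplicate phenotype row for id {dup!r}")
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def ids(self) -> pd.Series:
        return self.df["id"]

    def trait_column(self, trait: str, recording: int) -> str:
        if trait in PER_RECORDING_TRAITS:
            return f"{PER_RECORDING_TRAITS[trait]}{'_' if trait.startswith('fin') else ''}{recording}"
        if trait in EROSION_TRAITS:
            if recording != 3:
                raise ValueError("fin erosion is only scored at recording 3")
            return trait
        raise KeyError(f"unknown stored trait {trait!r}")

    def trait_values(self, trait: str, recording: int = 3) -> pd.Series:
        """Analysis vector for a trait; derived traits computed on the fly."""
        df = self.df
        if trait == "sgr":
            t1 = df.get("age1")
            t3 = df.get("age3")
            if t1 is None or t3 is None or (t3 - t1).isna().all():
                elapsed = DEFAULT_DURATION_DAYS
                return pd.Series(
                    specific_growth_rate(df["weight1"], df["weight3"], 0.0, elapsed),
                    index=df.index,
                    name="sgr",
                )
            return pd.Series(
                specific_growth_rate(df["weight1"], df["weight3"], t1, t3),
                index=df.index,
                name="sgr",
            )
        if trait == "ccf":
            return pd.Series(
                change_in_condition_factor(
                    df["weight1"], df["length1"], df["weight3"], df["length3"]
                ),
                index=df.index,
                name="ccf",
            )
        if trait == "cf":
            col_w, col_l = f"weight{recording}", f"length{recording}"
            return pd.Series(
                condition_factor(df[col_w], df[col_l]), index=df.index, name="cf"
            )
        col = self.trait_column(trait, recording)
        return df[col].astype(float)

    def age(self, recording: int) -> pd.Series:
        return self.df[f"age{recording}"].astype(float)


def read_phenotypes(path) -> TraitTable:
    """Read the phenotype CSV dialect (missing values as empty fields)."""
    df = pd.read_csv(path, dtype={"id": str, "family": str, "rearing_group": str, "tank": str})
    if "scorer" in df.columns:
        df["scorer"] = df["scorer"].astype("Int64").astype(object)
    return TraitTable(df)


def write_phenotypes(table: TraitTable, path) -> None:
    cols = [c for c in PHENOTYPE_COLUMNS if c in table.df.columns]
    extra = [c for c in table.df.columns if c not in cols]
    table.df[cols + extra].to_csv(path, index=False)
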