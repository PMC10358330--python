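"""Adult-female-equivalent (AFE) conversion.

Each household member counts as the ratio of their energy requirement to the
reference adult female's requirement; summing over members gives the household
AFE, and dividing the raw household food log by that total yields per-AFE
daily intakes of items, food groups, energy and (post-retention) nutrients.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .config import DEFAULT_ENERGY_ROWS, DEFAULT_REFERENCE_REQUIREMENT
from .exceptions import ConfigError, LinkageError, StratumLookupError
from .model import (
    DEFAULT_NUTRIENTS,
    PATTERN_GROUPS,
    ConsumptionRecord,
    HouseholdRecord,
    IndividualProfile,
)


@dataclass(frozen=True)
class EnergyRequirementTable:
    """Energy requirements (kcal/day) keyed by (sex, age band, activity).

    Age bands are inclusive and must not overlap within a (sex, activity)
    slice.  ``reference_requirement`` is the requirement of the reference
    female (one AFE).
    """

    rows: tuple[tuple[str, int, int, str, float], ...]
    reference_requirement: float = DEFAULT_REFERENCE_REQUIREMENT

    def __post_init__(self) -> None:
        if self.reference_requirement <= 0:
            raise ConfigError("reference_requirement must be > 0")
        for sex, lo, hi, act, kcal in self.rows:
            if kcal <= 0:
                raise ConfigError(f"energy requirement must be > 0 for ({sex},{lo}-{hi},{act})")

    @classmethod
    def default(cls) -> "EnergyRequirementTable":
        return cls(rows=tuple(tuple(r) for r in DEFAULT_ENERGY_ROWS))

    @classmethod
    def from_config(cls, block: dict) -> "EnergyRequirementTable":
        return cls(
            rows=tuple(tuple(r) for r in block["rows"]),
            reference_requirement=float(block["reference"]),
        )

    def requirement(self, member: IndividualProfile) -> float:
        for sex, lo, hi, act, kcal in self.rows:
            if sex == member.sex and act == member.activity_level and lo <= member.age <= hi:
                return float(kcal)
        raise StratumLookupError(
            f"no energy-requirement stratum for (sex={member.sex}, age={member.age}, "
            f"activity={member.activity_level})"
        )


def afe_ratio(member: IndividualProfile, table: EnergyRequirementTable) -> float:
    """Member's energy requirement as a fraction of the reference female's."""
    return table.requirement(member) / table.reference_requirement


def household_afe(household: HouseholdRecord, table: EnergyRequirementTable) -> float:
    """Total household AFE: sum of the member ratios."""
    return sum(afe_ratio(m, table) for m in household.members)


@dataclass
class PerAFEIntake:
    """Per-adult-female-equivalent daily intake for one household."""

    household_id: str
    afe_total: float
    item_intake: dict[str, float]          # g/day per AFE, by item code
    group_intake: pd.Series                # g/day per AFE over the 18 pattern groups
    energy: float                          # kcal/day per AFE
    nutrient_intake: dict[str, float]      # per nutrient, post-retention
    nutrient_intake_raw: dict[str, float] = field(default_factory=dict)  # pre-retention


def per_afe_intake(
    household: HouseholdRecord,
    consumption: Sequence[ConsumptionRecord],
    fct: pd.DataFrame,
    groupmap: pd.DataFrame,
    table: EnergyRequirementTable,
    nutrients: Sequence[str] = DEFAULT_NUTRIENTS,
) -> PerAFEIntake:
    """Convert one household's raw food log to per-AFE daily intakes.

    ``consumption`` may contain rows for other households; only rows matching
    ``household.household_id`` are used.
    """
    afe = household_afe(household, table)
    rows = [r for r in consumption if r.household_id == household.household_id]
    missing = sorted({r.item_code for r in rows} - set(fct.index))
    if missing:
        raise LinkageError(
            f"household {household.household_id!r}: consumed item(s) absent from "
            f"composition table: {missing}"
        )

    grams: dict[str, float] = {}
    for r in rows:
        grams[r.item_code] = grams.get(r.item_code, 0.0) + r.grams_raw
    # sum household grams first, divide once: matches the vectorized path
    item_intake = {code: g / afe for code, g in grams.items()}

    group = pd.Series(0.0, index=list(PATTERN_GROUPS))
    energy = 0.0
    nutrient: dict[str, float] = {n: 0.0 for n in nutrients}
    nutrient_raw: dict[str, float] = {n: 0.0 for n in nutrients}
    for code, grams in item_intake.items():
        entry = fct.loc[code]
        group[groupmap.loc[code, "pattern_group"]] += grams
        energy += grams * float(entry["energy_kcal_100g"]) / 100.0
        for n in nutrients:
            raw = grams * float(entry[f"{n}_per_100g"]) / 100.0
            nutrient_raw[n] += raw
            nutrient[n] += raw * float(entry[f"ret_{n}"])

    return PerAFEIntake(
        household_id=household.household_id,
        afe_total=afe,
        item_intake=item_intake,
        group_intake=group,
        energy=energy,
        nutrient_intake=nutrient,
        nutrient_intake_raw=nutrient_raw,
    )


# ---------------------------------------------------------------------------
# Vectorized population conversion
# ---------------------------------------------------------------------------

def convert_population(
    households: Sequence[HouseholdRecord],
    consumption: Sequence[ConsumptionRecord],
    fct: pd.DataFrame,
    groupmap: pd.DataFrame,
    table: EnergyRequirementTable,
    nutrients: Sequence[str] = DEFAULT_NUTRIENTS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Convert a whole survey at once.

    Returns
    -------
    per_afe : DataFrame
        One row per household: ``household_id, afe_total, energy``, one
        ``group_<g>`` column per pattern group and one ``nutrient_<n>``
        column per nutrient (post-retention), in roster order.
    items : DataFrame
        Long item-level table ``household_id, item_code, grams_per_afe``.
    """
    afe = pd.Series(
        {h.household_id: household_afe(h, table) for h in households}, name="afe_total"
    )
    log = pd.DataFrame(
        [(r.household_id, r.item_code, r.grams_raw) for r in consumption],
        columns=["household_id", "item_code", "grams_raw"],
    )
    missing = sorted(set(log["item_code"]) - set(fct.index))
    if missing:
        raise LinkageError(f"consumed item(s) absent from composition table: {missing}")

    log = log.groupby(["household_id", "item_code"], as_index=False, sort=False)[
        "grams_raw"
    ].sum()
    log["grams_per_afe"] = log["grams_raw"].to_numpy() / afe.reindex(
        log["household_id"]
    ).to_numpy()

    merged = log.merge(
        fct.reset_index()[["item_code", "energy_kcal_100g"]], on="item_code", how="left"
    ).merge(groupmap.reset_index()[["item_code", "pattern_group"]], on="item_code", how="left")
    merged["energy"] = merged["grams_per_afe"] * merged["energy_kcal_100g"] / 100.0
    for n in nutrients:
        dens = fct[f"{n}_per_100g"].reindex(merged["item_code"]).to_numpy()
        ret = fct[f"ret_{n}"].reindex(merged["item_code"]).to_numpy()
        merged[f"nutrient_{n}"] = merged["grams_per_afe"] * dens / 100.0 * ret

    hid_order = [h.household_id for h in households]
    energy = merged.groupby("household_id")["energy"].sum().reindex(hid_order, fill_value=0.0)
    groups = (
        merged.pivot_table(
            index="household_id",
            columns="pattern_group",
            values="grams_per_afe",
            aggfunc="sum",
            fill_value=0.0,
        )
        .reindex(index=hid_order, columns=list(PATTERN_GROUPS), fill_value=0.0)
    )
    out = pd.DataFrame({"household_id": hid_order})
    out["afe_total"] = afe.reindex(hid_order).to_numpy()
    out["energy"] = energy.to_numpy()
    for g in PATTERN_GROUPS:
        out[f"group_{g}"] = groups[g].to_numpy()
    nut = merged.groupby("household_id")[[f"nutrient_{n}" for n in nutrients]].sum()
    nut = nut.reindex(hid_order, fill_value=0.0)
    for n in nutrients:
        out[f"nutrient_{n}"] = nut[f"nutrient_{n}"].to_numpy()

    items = log[["household_id", "item_code", "grams_per_afe"]].copy()
    return out, items


def group_matrix(per_afe: pd.DataFrame) -> pd.DataFrame:
    """Extract the n x 18 food-group intake matrix from a per-AFE table."""
    cols = [f"group_{g}" for g in PATTERN_GROUPS]
    mat = per_afe[cols].copy()
    mat.columns = list(PATTERN_GROUPS)
    mat.index = per_afe["household_id"].to_numpy()
    return mat
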