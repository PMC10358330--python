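"""Reading and writing every table the pipeline touches.

All files are UTF-8, comma-delimited, single header row, decimal point.

CSV schemas
-----------
roster
    ``household_id, member_id, age, sex, activity_level, region, wealth_quintile``
    (one row per member; region/wealth repeated within a household)
consumption
    ``household_id, item_code, grams_raw`` (long format, one row per
    household x item, raw uncooked grams per day for the whole household)
fct (food composition)
    ``item_code, name, energy_kcal_100g, <nutrient>_per_100g ..., ret_<nutrient> ...``
groupmap
    ``item_code, pattern_group, mddw_group`` (mddw_group may be empty)
footprint
    ``item_code, ghge_kgco2e_per_kg, bluewater_m3_per_kg`` (blue water may be
    empty, and MUST be empty for condiments / sweet foods / alcohol items;
    an empty field means "no factor", never 0)
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import ReferentialError, SchemaError, ValidationError, VocabularyError
from .model import (
    BWU_EXCLUDED_GROUPS,
    DEFAULT_NUTRIENTS,
    MDDW_GROUPS,
    PATTERN_GROUPS,
    ConsumptionRecord,
    HouseholdRecord,
    IndividualProfile,
)

ROSTER_COLUMNS = (
    "household_id",
    "member_id",
    "age",
    "sex",
    "activity_level",
    "region",
    "wealth_quintile",
)
CONSUMPTION_COLUMNS = ("household_id", "item_code", "grams_raw")


def _require_columns(df: pd.DataFrame, required: Iterable[str], table: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{table}: missing required column(s) {missing}")


# ---------------------------------------------------------------------------
# Survey tables
# ---------------------------------------------------------------------------

def read_survey(
    roster_path: str | Path, consumption_path: str | Path
) -> tuple[list[HouseholdRecord], list[ConsumptionRecord]]:
    """Read the household roster and the 24-h consumption log.

    Raises
    ------
    SchemaError
        if either file lacks a required column.
    ReferentialError
        if the log references household ids absent from the roster.
    ValidationError / VocabularyError
        if a row violates a domain invariant.
    """
    roster = pd.read_csv(roster_path, dtype={"household_id": str, "member_id": str})
    _require_columns(roster, ROSTER_COLUMNS, "roster")
    log = pd.read_csv(consumption_path, dtype={"household_id": str, "item_code": str})
    _require_columns(log, CONSUMPTION_COLUMNS, "consumption")

    households: list[HouseholdRecord] = []
    for hid, grp in roster.groupby("household_id", sort=False):
        regions = grp["region"].unique()
        wealth = grp["wealth_quintile"].unique()
        if len(regions) > 1 or len(wealth) > 1:
            raise ValidationError(
                f"household {hid!r}: inconsistent region/wealth across roster rows"
            )
        members = tuple(
            IndividualProfile(
                member_id=str(row.member_id),
                age=int(row.age),
                sex=str(row.sex),
                activity_level=str(row.activity_level),
            )
            for row in grp.itertuples()
        )
        households.append(
            HouseholdRecord(
                household_id=str(hid),
                region=str(regions[0]),
                wealth_quintile=int(wealth[0]),
                members=members,
            )
        )

    known = {h.household_id for h in households}
    unknown = sorted(set(log["household_id"]) - known)
    if unknown:
        raise ReferentialError(
            f"consumption log references household id(s) absent from roster: {unknown}"
        )
    records = [
        ConsumptionRecord(
            household_id=str(row.household_id),
            item_code=str(row.item_code),
            grams_raw=float(row.grams_raw),
        )
        for row in log.itertuples()
    ]
    return households, records


def households_to_frame(households: Sequence[HouseholdRecord]) -> pd.DataFrame:
    """Flatten household records to the roster CSV layout."""
    rows = []
    for h in households:
        for m in h.members:
            rows.append(
                (h.household_id, m.member_id, m.age, m.sex, m.activity_level, h.region, h.wealth_quintile)
            )
    return pd.DataFrame(rows, columns=list(ROSTER_COLUMNS))


def consumption_to_frame(records: Sequence[ConsumptionRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.household_id, r.item_code, r.grams_raw) for r in records],
        columns=list(CONSUMPTION_COLUMNS),
    )


# ---------------------------------------------------------------------------
# Reference tables
# ---------------------------------------------------------------------------

def read_reference_tables(
    fct_path: str | Path,
    groupmap_path: str | Path,
    footprint_path: str | Path,
    nutrients: Sequence[str] = DEFAULT_NUTRIENTS,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Read and cross-validate the three reference tables.

    Returns ``(fct, groupmap, footprint)``, each indexed by ``item_code``.
    The three tables must cover exactly the same item codes (referential
    closure), and items mapped to blue-water-excluded groups must carry no
    blue-water factor.
    """
    fct = pd.read_csv(fct_path, dtype={"item_code": str})
    fct_cols = ["item_code", "name", "energy_kcal_100g"]
    fct_cols += [f"{n}_per_100g" for n in nutrients] + [f"ret_{n}" for n in nutrients]
    _require_columns(fct, fct_cols, "fct")
    groupmap = pd.read_csv(groupmap_path, dtype={"item_code": str})
    _require_columns(groupmap, ("item_code", "pattern_group", "mddw_group"), "groupmap")
    footprint = pd.read_csv(footprint_path, dtype={"item_code": str})
    _require_columns(
        footprint, ("item_code", "ghge_kgco2e_per_kg", "bluewater_m3_per_kg"), "footprint"
    )

    fct = fct.set_index("item_code")
    groupmap = groupmap.set_index("item_code")
    footprint = footprint.set_index("item_code")
    validate_reference_tables(fct, groupmap, footprint, nutrients)
    return fct, groupmap, footprint


def validate_reference_tables(
    fct: pd.DataFrame,
    groupmap: pd.DataFrame,
    footprint: pd.DataFrame,
    nutrients: Sequence[str] = DEFAULT_NUTRIENTS,
) -> None:
    """Invariant checks shared by file-based and in-memory reference tables."""
    bad_groups = sorted(set(groupmap["pattern_group"]) - set(PATTERN_GROUPS))
    if bad_groups:
        raise VocabularyError(f"groupmap: unknown pattern group label(s) {bad_groups}")
    mddw = groupmap["mddw_group"].dropna()
    bad_mddw = sorted(set(mddw) - set(MDDW_GROUPS))
    if bad_mddw:
        raise VocabularyError(f"groupmap: unknown MDD-W group label(s) {bad_mddw}")

    fct_items = set(fct.index)
    for name, items in (("groupmap", set(groupmap.index)), ("footprint", set(footprint.index))):
        dangling = sorted(items - fct_items)
        if dangling:
            raise ReferentialError(f"{name}: item code(s) not in composition table: {dangling}")
        orphans = sorted(fct_items - items)
        if orphans:
            raise ReferentialError(f"fct: item code(s) missing from {name}: {orphans}")

    if (fct["energy_kcal_100g"] < 0).any():
        raise ValidationError("fct: negative energy density")
    for n in nutrients:
        if (fct[f"{n}_per_100g"] < 0).any():
            raise ValidationError(f"fct: negative density for nutrient {n!r}")
        ret = fct[f"ret_{n}"]
        if ((ret < 0) | (ret > 1)).any():
            raise ValidationError(f"fct: retention factor for {n!r} outside [0,1]")

    if (footprint["ghge_kgco2e_per_kg"] < 0).any():
        raise ValidationError("footprint: negative GHGE factor")
    bw = footprint["bluewater_m3_per_kg"]
    if (bw.dropna() < 0).any():
        raise ValidationError("footprint: negative blue-water factor")
    excluded = groupmap.index[groupmap["pattern_group"].isin(BWU_EXCLUDED_GROUPS)]
    offending = sorted(set(excluded) & set(bw.dropna().index))
    if offending:
        raise ValidationError(
            "footprint: blue-water factor present for item(s) in excluded groups "
            f"(condiments / sweet foods / alcohol): {offending}"
        )


# ---------------------------------------------------------------------------
# Result tables
# ---------------------------------------------------------------------------

def write_results(results: pd.DataFrame, path: str | Path) -> None:
    """Write a result table as UTF-8 CSV with stable column order.

    Floats are written with shortest round-trip representation (repr), so
    reading the file back reproduces the values bit-exactly.
    """
    results.to_csv(
        path, index=False, encoding="utf-8", float_format=lambda v: repr(float(v))
    )


def read_results(path: str | Path) -> pd.DataFrame:
    # round_trip parser: exact inverse of the repr-based writer
    return pd.read_csv(path, encoding="utf-8", float_precision="round_trip")


def frames_equal(a: pd.DataFrame, b: pd.DataFrame, rtol: float = 1e-12) -> bool:
    """Round-trip equality check used by tests: exact for non-floats,
    relative tolerance for floats."""
    if list(a.columns) != list(b.columns) or len(a) != len(b):
        return False
    for col in a.columns:
        x, y = a[col], b[col]
        if np.issubdtype(x.dtype, np.floating) or np.issubdtype(y.dtype, np.floating):
            if not np.allclose(x.astype(float), y.astype(float), rtol=rtol, equal_nan=True):
                return False
        else:
            if not (x.astype(object) == y.astype(object)).all():
                return False
    return True
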