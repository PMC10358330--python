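"""Dietary greenhouse-gas and blue-water footprint linkage.

Each consumed item is matched to per-kg emission and blue-water factors.
A missing GHGE factor for a consumed item is a data defect and raises; a
missing blue-water factor is legal only for items in the excluded groups
(condiments, sweet foods, liquor/alcohol), whose mass is tracked separately.
Per-2,000-kcal standardization is applied per household BEFORE any population
averaging (mean of ratios, never ratio of means).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import AlignmentError, DegenerateInputError, LinkageError
from .model import BWU_EXCLUDED_GROUPS, PATTERN_GROUPS


@dataclass
class FootprintResult:
    """Per-household dietary footprint (per AFE per day)."""

    household_id: str
    ghge_total: float                 # kg CO2-eq/day
    bwu_total: float                  # m3/day
    group_ghge: pd.Series             # per pattern group, kg CO2-eq/day
    group_bwu: pd.Series              # per pattern group, m3/day (0 for excluded)
    excluded_mass: float              # g/day excluded from blue-water accounting
    ghge_per2000: float | None = None  # kg CO2-eq per 2,000 kcal
    bwu_per2000: float | None = None   # m3 per 2,000 kcal


def link_footprints(
    item_intake: Mapping[str, float],
    footprints: pd.DataFrame,
    groupmap: pd.DataFrame,
    household_id: str = "",
) -> FootprintResult:
    """Attach footprint factors to one household's per-AFE item intakes.

    ``item_intake`` maps item code to g/day per AFE.  Factors are per kg, so
    each item contributes ``grams / 1000 * factor``.
    """
    codes = list(item_intake)
    missing = sorted(set(codes) - set(footprints.index))
    if missing:
        raise LinkageError(f"consumed item(s) without footprint factors: {missing}")

    group_ghge = pd.Series(0.0, index=list(PATTERN_GROUPS))
    group_bwu = pd.Series(0.0, index=list(PATTERN_GROUPS))
    excluded_mass = 0.0
    for code in codes:
        grams = item_intake[code]
        group = groupmap.loc[code, "pattern_group"]
        ghge = footprints.loc[code, "ghge_kgco2e_per_kg"]
        if pd.isna(ghge):
            raise LinkageError(f"item {code!r} has no GHGE factor")
        group_ghge[group] += grams / 1000.0 * float(ghge)
        bw = footprints.loc[code, "bluewater_m3_per_kg"]
        if group in BWU_EXCLUDED_GROUPS:
            excluded_mass += grams
        elif pd.isna(bw):
            raise LinkageError(
                f"item {code!r} (group {group!r}) has no blue-water factor but its "
                "group is not excluded from water accounting"
            )
        else:
            group_bwu[group] += grams / 1000.0 * float(bw)

    return FootprintResult(
        household_id=household_id,
        ghge_total=float(group_ghge.sum()),
        bwu_total=float(group_bwu.sum()),
        group_ghge=group_ghge,
        group_bwu=group_bwu,
        excluded_mass=excluded_mass,
    )


def per_2000kcal(result: FootprintResult, energy: float) -> FootprintResult:
    """Fill the per-2,000-kcal fields of a footprint result."""
    if energy <= 0:
        raise DegenerateInputError(f"energy must be > 0 to standardize, got {energy}")
    result.ghge_per2000 = result.ghge_total * 2000.0 / energy
    result.bwu_per2000 = result.bwu_total * 2000.0 / energy
    return result


def footprint_table(
    items: pd.DataFrame,
    per_afe: pd.DataFrame,
    footprints: pd.DataFrame,
    groupmap: pd.DataFrame,
) -> pd.DataFrame:
    """Footprint every household in a converted survey.

    Returns one row per household (roster order): totals, per-2,000-kcal
    values, per-group GHGE/BWU columns and excluded mass.
    """
    missing = sorted(set(items["item_code"]) - set(footprints.index))
    if missing:
        raise LinkageError(f"consumed item(s) without footprint factors: {missing}")

    merged = items.merge(
        footprints.reset_index()[["item_code", "ghge_kgco2e_per_kg", "bluewater_m3_per_kg"]],
        on="item_code",
        how="left",
    ).merge(groupmap.reset_index()[["item_code", "pattern_group"]], on="item_code", how="left")
    if merged["ghge_kgco2e_per_kg"].isna().any():
        bad = sorted(merged.loc[merged["ghge_kgco2e_per_kg"].isna(), "item_code"].unique())
        raise LinkageError(f"item(s) with no GHGE factor: {bad}")
    excluded = merged["pattern_group"].isin(BWU_EXCLUDED_GROUPS)
    bad_bw = merged["bluewater_m3_per_kg"].isna() & ~excluded
    if bad_bw.any():
        raise LinkageError(
            "item(s) with no blue-water factor outside the excluded groups: "
            f"{sorted(merged.loc[bad_bw, 'item_code'].unique())}"
        )

    merged["ghge"] = merged["grams_per_afe"] / 1000.0 * merged["ghge_kgco2e_per_kg"]
    merged["bwu"] = np.where(
        excluded, 0.0, merged["grams_per_afe"] / 1000.0 * merged["bluewater_m3_per_kg"]
    )
    merged["excl_mass"] = np.where(excluded, merged["grams_per_afe"], 0.0)

    hid_order = per_afe["household_id"].tolist()
    g_ghge = merged.pivot_table(
        index="household_id", columns="pattern_group", values="ghge",
        aggfunc="sum", fill_value=0.0,
    ).reindex(index=hid_order, columns=list(PATTERN_GROUPS), fill_value=0.0)
    g_bwu = merged.pivot_table(
        index="household_id", columns="pattern_group", values="bwu",
        aggfunc="sum", fill_value=0.0,
    ).reindex(index=hid_order, columns=list(PATTERN_GROUPS), fill_value=0.0)
    excl = (
        merged.groupby("household_id")["excl_mass"].sum().reindex(hid_order, fill_value=0.0)
    )

    energy = per_afe.set_index("household_id")["energy"].reindex(hid_order)
    if (energy <= 0).any():
        raise DegenerateInputError("household with energy <= 0 cannot be standardized")

    out = pd.DataFrame({"household_id": hid_order})
    out["ghge_total"] = g_ghge.sum(axis=1).to_numpy()
    out["bwu_total"] = g_bwu.sum(axis=1).to_numpy()
    out["ghge_per2000"] = out["ghge_total"] * 2000.0 / energy.to_numpy()
    out["bwu_per2000"] = out["bwu_total"] * 2000.0 / energy.to_numpy()
    out["excluded_mass"] = excl.to_numpy()
    out["energy"] = energy.to_numpy()
    for g in PATTERN_GROUPS:
        out[f"ghge_{g}"] = g_ghge[g].to_numpy()
    for g in PATTERN_GROUPS:
        out[f"bwu_{g}"] = g_bwu[g].to_numpy()
    return out


def group_contribution_table(
    results: pd.DataFrame,
    quintiles: pd.DataFrame,
    measure: str = "ghge",
) -> pd.DataFrame:
    """Mean per-2,000-kcal food-group contributions per pattern x quintile.

    ``results`` is the output of :func:`footprint_table`; ``quintiles`` has
    one column per pattern of Q1..Q5 labels, indexed by household id.
    Returns a tidy frame ``(pattern, quintile, group, mean_value)`` whose
    group means sum to the stratum's mean per-2,000-kcal total.
    """
    if measure not in ("ghge", "bwu"):
        raise ValueError("measure must be 'ghge' or 'bwu'")
    res = results.set_index("household_id")
    if not res.index.equals(pd.Index(quintiles.index)) and set(res.index) != set(
        quintiles.index
    ):
        raise AlignmentError("results and quintiles do not cover the same households")
    quintiles = quintiles.reindex(res.index)
    scale = 2000.0 / res["energy"]

    rows = []
    for pattern in quintiles.columns:
        for q, idx in quintiles.groupby(quintiles[pattern]).groups.items():
            sub = res.loc[idx]
            sub_scale = scale.loc[idx]
            for g in PATTERN_GROUPS:
                contrib = (sub[f"{measure}_{g}"] * sub_scale).mean()
                rows.append((pattern, q, g, float(contrib)))
    return pd.DataFrame(rows, columns=["pattern", "quintile", "group", "mean_value"])
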