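"""Synthetic survey generator with planted latent dietary patterns.

The generator emulates the *structure* of a national household nutrition
survey — multi-member households across 6 regions and 5 wealth strata, an
item-level 24-h food log, and reference tables — with K latent dietary
patterns planted as additive g/day signatures on the 18 food-group intakes.
The true latent scores are returned so downstream pattern recovery can be
tested against known ground truth.  No attempt is made to match any real
survey's marginal distributions.

Model: per household, latent scores z ~ Normal(bias(region, wealth),
score_sd); per-AFE group intake = max(0, baseline + sum_k z_k * signature_k +
Normal(0, noise_sd)); group intake is split uniformly across the group's
items and multiplied by the household AFE to give raw household grams.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .afe import EnergyRequirementTable, household_afe
from .exceptions import ConfigError
from .io import consumption_to_frame, households_to_frame
from .model import (
    ACTIVITY_LEVELS,
    BWU_EXCLUDED_GROUPS,
    DEFAULT_NUTRIENTS,
    PATTERN_GROUPS,
    REGIONS,
    ConsumptionRecord,
    HouseholdRecord,
    IndividualProfile,
)

#: Region sampling probabilities (population shares of the 6 regions).
REGION_PROBS = (0.169, 0.244, 0.246, 0.071, 0.085, 0.185)

#: Mean g/day per AFE per pattern group in the absence of latent effects.
DEFAULT_BASELINE = np.array(
    [365.0, 36.0, 32.0, 54.0, 13.0, 12.0, 2.0, 65.0, 12.0, 10.0,
     109.0, 112.0, 49.0, 5.0, 3.0, 18.0, 5.0, 8.0]
)

# g/day shift per unit latent score.  Three thematic signatures:
# 1. meat-rich (more non-rice staples / meats / dairy / fruits, less rice & fish)
# 2. rice-based (more rice / vegetables / fats, less fish & oils)
# 3. fish-rich (more fish / condiments / oils / rice)
# Overlap between signatures is kept small and their strengths distinct so
# each is recoverable as a separate principal component.
DEFAULT_SIGNATURES = np.array(
    [
        # sig1   sig2   sig3
        [-50.0,  65.0,  15.0],   # Rice
        [ 35.0, -15.0,   0.0],   # Non-rice starchy staples
        [  0.0,  25.0,   0.0],   # Root, tubers, nuts, and seeds
        [ 35.0,   0.0,   0.0],   # Red meat
        [ 12.0,   0.0,   0.0],   # White meat
        [ 12.0,   0.0,   0.0],   # Organs
        [  3.0,   0.0,   0.0],   # Processed meat
        [-15.0, -10.0,  55.0],   # Fish and seafood
        [  7.0,   0.0,   0.0],   # Eggs
        [ 12.0,   0.0,   0.0],   # Milk and dairy products
        [  0.0,  60.0,   0.0],   # Rich vitamin vegetables
        [  0.0,  20.0,   0.0],   # Other vegetables
        [ 45.0,   0.0,   0.0],   # Fruits
        [  0.0,  -3.0,   4.0],   # Oils
        [  0.0,   6.0,   0.0],   # Fats
        [  0.0,   0.0,  12.0],   # Condiments
        [  5.0,   0.0,   0.0],   # Sweet foods
        [  5.0,   0.0,   0.0],   # Liquor and alcohol
    ]
)

DEFAULT_REGION_BIAS = {
    "Red river delta": (0.3, 0.0, -0.05),
    "Northern mountainous": (-0.2, 0.3, -0.1),
    "North Central and Coastal": (0.0, -0.1, 0.25),
    "Central Highland": (0.0, 0.0, 0.0),
    "Southeast": (0.2, -0.1, 0.0),
    "Mekong delta": (0.0, -0.05, 0.05),
}

DEFAULT_WEALTH_BIAS = {
    q: (0.15 * (q - 3), -0.10 * (q - 3), 0.03 * (q - 3)) for q in (1, 2, 3, 4, 5)
}


@dataclass
class GeneratorConfig:
    n_households: int = 2000
    seed: int = 0
    pattern_signatures: np.ndarray = field(default_factory=lambda: DEFAULT_SIGNATURES.copy())
    score_sd: np.ndarray = field(default_factory=lambda: np.ones(3))
    baseline_intake: np.ndarray = field(default_factory=lambda: DEFAULT_BASELINE.copy())
    noise_sd: float = 4.0
    region_pattern_bias: dict = field(default_factory=lambda: dict(DEFAULT_REGION_BIAS))
    wealth_pattern_bias: dict = field(default_factory=lambda: dict(DEFAULT_WEALTH_BIAS))
    household_size_range: tuple[int, int] = (1, 6)

    def __post_init__(self) -> None:
        self.pattern_signatures = np.asarray(self.pattern_signatures, dtype=float)
        self.score_sd = np.asarray(self.score_sd, dtype=float)
        self.baseline_intake = np.asarray(self.baseline_intake, dtype=float)
        if self.pattern_signatures.shape[0] != len(PATTERN_GROUPS):
            raise ConfigError(
                f"pattern_signatures must have {len(PATTERN_GROUPS)} rows, "
                f"got {self.pattern_signatures.shape[0]}"
            )
        if self.n_households < 10 * self.n_patterns:
            raise ConfigError(
                f"n_households must be >= {10 * self.n_patterns} "
                f"(10 per pattern), got {self.n_households}"
            )
        if (self.baseline_intake < 0).any():
            raise ConfigError("baseline_intake must be >= 0")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")

    @property
    def n_patterns(self) -> int:
        return self.pattern_signatures.shape[1]


# ---------------------------------------------------------------------------
# Reference tables
# ---------------------------------------------------------------------------

# group -> (energy kcal/100g, ghge kg CO2e/kg, blue water m3/kg or None,
#           item definitions [(suffix, mddw group or None), ...])
_GROUP_SPECS: dict[str, tuple[float, float, float | None, list[tuple[str, str | None]]]] = {
    "Rice": (350, 2.7, 0.45, [("white rice", "Grains, white roots and tubers, and plantains"),
                              ("sticky rice", "Grains, white roots and tubers, and plantains")]),
    "Non-rice starchy staples": (140, 1.5, 0.10,
        [("noodles", "Grains, white roots and tubers, and plantains"),
         ("sweet potato", "Grains, white roots and tubers, and plantains")]),
    "Root, tubers, nuts, and seeds": (250, 2.0, 0.40,
        [("taro", "Grains, white roots and tubers, and plantains"),
         ("peanut", "Nuts and seeds"),
         ("mung bean", "Pulses (beans, peas and lentils)")]),
    "Red meat": (220, 27.0, 0.45, [("pork", "Meat, poultry and fish"),
                                   ("beef", "Meat, poultry and fish")]),
    "White meat": (170, 6.9, 0.30, [("chicken", "Meat, poultry and fish"),
                                    ("duck", "Meat, poultry and fish")]),
    "Organs": (130, 10.0, 0.35, [("pork liver", "Meat, poultry and fish"),
                                 ("chicken giblets", "Meat, poultry and fish")]),
    "Processed meat": (250, 12.0, 0.40, [("sausage", "Meat, poultry and fish"),
                                         ("pate", "Meat, poultry and fish")]),
    "Fish and seafood": (120, 5.4, 0.20, [("carp", "Meat, poultry and fish"),
                                          ("shrimp", "Meat, poultry and fish")]),
    "Eggs": (150, 4.5, 0.20, [("chicken egg", "Eggs"), ("duck egg", "Eggs")]),
    "Milk and dairy products": (70, 3.0, 0.25, [("fresh milk", "Dairy"),
                                                ("condensed milk", "Dairy")]),
    "Rich vitamin vegetables": (30, 2.0, 0.05,
        [("water spinach", "Dark green leafy vegetables"),
         ("carrot", "Other vitamin A-rich fruits and vegetables")]),
    "Other vegetables": (25, 1.5, 0.05, [("cabbage", "Other vegetables"),
                                         ("cucumber", "Other vegetables")]),
    "Fruits": (60, 1.1, 0.25, [("banana", "Other fruits"),
                               ("mango", "Other vitamin A-rich fruits and vegetables")]),
    "Oils": (880, 3.5, 0.30, [("vegetable oil", None), ("sesame oil", None)]),
    "Fats": (750, 8.0, 0.35, [("lard", None), ("butter", None)]),
    "Condiments": (100, 2.0, None, [("fish sauce", None), ("soy sauce", None)]),
    "Sweet foods": (400, 3.0, None, [("sugar", None), ("candy", None)]),
    "Liquor and alcohol": (50, 2.0, None, [("rice wine", None), ("beer", None)]),
}

# per-100g nutrient density bases per group, order = DEFAULT_NUTRIENTS:
# protein, vit A, vit C, B6, B12, vit E, folate, iron, zinc, calcium, magnesium
_GROUP_NUTRIENTS: dict[str, tuple[float, ...]] = {
    "Rice": (7.0, 0, 0, 0.15, 0, 0.1, 8, 1.2, 1.5, 10, 35),
    "Non-rice starchy staples": (3.0, 2, 5, 0.1, 0, 0.2, 15, 0.8, 0.6, 20, 25),
    "Root, tubers, nuts, and seeds": (12.0, 3, 4, 0.3, 0, 3.0, 120, 3.0, 2.0, 60, 110),
    "Red meat": (19.0, 2, 0, 0.45, 0.7, 0.3, 5, 1.5, 2.8, 7, 22),
    "White meat": (20.0, 16, 0, 0.5, 0.3, 0.3, 6, 0.9, 1.3, 12, 25),
    "Organs": (18.0, 5000, 15, 0.6, 20.0, 0.5, 200, 7.0, 3.5, 9, 20),
    "Processed meat": (15.0, 0, 0, 0.2, 0.6, 0.3, 4, 1.2, 2.0, 10, 15),
    "Fish and seafood": (18.0, 25, 0, 0.2, 1.5, 0.6, 15, 0.9, 1.5, 40, 30),
    "Eggs": (13.0, 190, 0, 0.15, 1.1, 1.0, 47, 1.8, 1.1, 55, 12),
    "Milk and dairy products": (3.3, 45, 1, 0.05, 0.45, 0.1, 5, 0.05, 0.4, 120, 11),
    "Rich vitamin vegetables": (2.6, 440, 28, 0.2, 0, 1.1, 60, 2.7, 0.5, 100, 70),
    "Other vegetables": (1.4, 5, 36, 0.12, 0, 0.15, 43, 0.5, 0.2, 48, 12),
    "Fruits": (1.1, 3, 20, 0.35, 0, 0.1, 20, 0.3, 0.15, 6, 27),
    "Oils": (0.0, 0, 0, 0, 0, 14.0, 0, 0, 0, 0, 0),
    "Fats": (0.3, 60, 0, 0, 0.1, 2.0, 1, 0, 0, 2, 1),
    "Condiments": (5.0, 0, 0, 0.05, 0.4, 0, 5, 1.0, 0.3, 40, 20),
    "Sweet foods": (0.5, 0, 1, 0.01, 0, 0, 1, 0.2, 0.1, 5, 3),
    "Liquor and alcohol": (0.3, 0, 0, 0.01, 0, 0, 2, 0.1, 0.05, 3, 5),
}


def generate_reference_tables(
    config: GeneratorConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Deterministically generate the (fct, groupmap, footprint) tables.

    Every pattern group carries >= 2 items, energy and footprint factors are
    positive, and items in the excluded groups have no blue-water factor.
    """
    rng = np.random.default_rng([config.seed, 17])
    fct_rows, gm_rows, fp_rows = [], [], []
    idx = 0
    for group in PATTERN_GROUPS:
        energy, ghge, bw, items = _GROUP_SPECS[group]
        base = _GROUP_NUTRIENTS[group]
        for suffix, mddw in items:
            idx += 1
            code = f"I{idx:03d}"
            jitter = rng.uniform(0.9, 1.1, size=len(base) + 1)
            row = {
                "item_code": code,
                "name": suffix,
                "energy_kcal_100g": round(energy * jitter[0], 4),
            }
            for j, n in enumerate(DEFAULT_NUTRIENTS):
                row[f"{n}_per_100g"] = round(base[j] * jitter[j + 1], 6)
            rets = rng.uniform(0.8, 1.0, size=len(DEFAULT_NUTRIENTS))
            for j, n in enumerate(DEFAULT_NUTRIENTS):
                row[f"ret_{n}"] = round(float(rets[j]), 4)
            fct_rows.append(row)
            gm_rows.append({"item_code": code, "pattern_group": group, "mddw_group": mddw})
            fp_rows.append(
                {
                    "item_code": code,
                    "ghge_kgco2e_per_kg": round(ghge * rng.uniform(0.9, 1.1), 4),
                    "bluewater_m3_per_kg": (
                        np.nan if bw is None or group in BWU_EXCLUDED_GROUPS
                        else round(bw * rng.uniform(0.9, 1.1), 4)
                    ),
                }
            )
    fct = pd.DataFrame(fct_rows).set_index("item_code")
    groupmap = pd.DataFrame(gm_rows).set_index("item_code")
    footprint = pd.DataFrame(fp_rows).set_index("item_code")
    return fct, groupmap, footprint


# ---------------------------------------------------------------------------
# Population
# ---------------------------------------------------------------------------

def generate_population(
    config: GeneratorConfig,
    ereq: EnergyRequirementTable | None = None,
) -> tuple[list[HouseholdRecord], list[ConsumptionRecord], pd.DataFrame]:
    """Generate households, an item-level food log and the true latent scores.

    Returns ``(households, consumption, truth)`` where ``truth`` has one row
    per household with columns ``household_id, z1..zK`` (the planted latent
    scores) and ``group_<g>`` columns holding the true per-AFE group intakes.
    """
    ereq = ereq or EnergyRequirementTable.default()
    _, groupmap, _ = generate_reference_tables(config)
    group_items = {
        g: list(groupmap.index[groupmap["pattern_group"] == g]) for g in PATTERN_GROUPS
    }

    rng = np.random.default_rng([config.seed, 29])
    n = config.n_households
    K = config.n_patterns

    regions = rng.choice(len(REGIONS), size=n, p=REGION_PROBS)
    wealth = rng.integers(1, 6, size=n)
    lo, hi = config.household_size_range
    sizes = rng.integers(lo, hi + 1, size=n)

    bias = np.zeros((n, K))
    for i in range(n):
        rb = config.region_pattern_bias.get(REGIONS[regions[i]], (0.0,) * K)
        wb = config.wealth_pattern_bias.get(int(wealth[i]), (0.0,) * K)
        bias[i] = np.asarray(rb[:K]) + np.asarray(wb[:K])
    z = bias + rng.normal(size=(n, K)) * config.score_sd

    group_per_afe = (
        config.baseline_intake
        + z @ config.pattern_signatures.T
        + rng.normal(size=(n, len(PATTERN_GROUPS))) * config.noise_sd
    )
    np.clip(group_per_afe, 0.0, None, out=group_per_afe)

    households: list[HouseholdRecord] = []
    consumption: list[ConsumptionRecord] = []
    for i in range(n):
        hid = f"H{i + 1:05d}"
        members = [
            IndividualProfile(
                member_id=f"{hid}_m1", age=25, sex="female", activity_level="moderate"
            )
        ]
        for j in range(int(sizes[i]) - 1):
            members.append(
                IndividualProfile(
                    member_id=f"{hid}_m{j + 2}",
                    age=int(rng.integers(0, 80)),
                    sex=str(rng.choice(["female", "male"])),
                    activity_level=str(rng.choice(ACTIVITY_LEVELS)),
                )
            )
        hh = HouseholdRecord(
            household_id=hid,
            region=REGIONS[regions[i]],
            wealth_quintile=int(wealth[i]),
            members=tuple(members),
        )
        households.append(hh)
        afe = household_afe(hh, ereq)
        for g_idx, g in enumerate(PATTERN_GROUPS):
            items = group_items[g]
            per_item = group_per_afe[i, g_idx] / len(items) * afe
            if per_item <= 0:
                continue
            for code in items:
                consumption.append(
                    ConsumptionRecord(household_id=hid, item_code=code, grams_raw=per_item)
                )

    truth = pd.DataFrame({"household_id": [h.household_id for h in households]})
    for k in range(K):
        truth[f"z{k + 1}"] = z[:, k]
    for g_idx, g in enumerate(PATTERN_GROUPS):
        truth[f"group_{g}"] = group_per_afe[:, g_idx]
    return households, consumption, truth


def write_simulation(
    out_dir: str | Path,
    config: GeneratorConfig,
    ereq: EnergyRequirementTable | None = None,
) -> dict[str, Path]:
    """Generate a survey and write the five input CSVs plus the truth table."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fct, groupmap, footprint = generate_reference_tables(config)
    households, consumption, truth = generate_population(config, ereq)
    paths = {
        "roster": out / "roster.csv",
        "consumption": out / "consumption.csv",
        "fct": out / "fct.csv",
        "groupmap": out / "groupmap.csv",
        "footprint": out / "footprint.csv",
        "truth_scores": out / "truth_scores.csv",
    }
    households_to_frame(households).to_csv(paths["roster"], index=False, encoding="utf-8")
    consumption_to_frame(consumption).to_csv(
        paths["consumption"], index=False, encoding="utf-8"
    )
    fct.reset_index().to_csv(paths["fct"], index=False, encoding="utf-8")
    groupmap.reset_index().to_csv(paths["groupmap"], index=False, encoding="utf-8")
    footprint.reset_index().to_csv(paths["footprint"], index=False, encoding="utf-8")
    truth.to_csv(paths["truth_scores"], index=False, encoding="utf-8")
    return paths


# ---------------------------------------------------------------------------
# Worked example
# ---------------------------------------------------------------------------

@dataclass
class WorkedExample:
    """A hand-computed 3-household, 12-item fixture.

    All intermediate values are documented in ``docs/worked_example.md``;
    ``expected`` holds the hand-computed numbers asserted by unit tests.
    """

    households: list[HouseholdRecord]
    consumption: list[ConsumptionRecord]
    fct: pd.DataFrame
    groupmap: pd.DataFrame
    footprint: pd.DataFrame
    ereq: EnergyRequirementTable
    expected: dict


def make_worked_example() -> WorkedExample:
    """Build the documented worked example (see docs/worked_example.md)."""
    # item: (name, pattern group, mddw group, energy, ghge, blue water,
    #        11 nutrient densities per 100 g)
    items = {
        "I01": ("Gạo tẻ", "Rice", "Grains, white roots and tubers, and plantains",
                350, 2.7, 0.5, (7.0, 0, 0, 0.15, 0, 0.1, 8, 1.2, 1.5, 10, 35)),
        "I02": ("Khoai lang", "Non-rice starchy staples",
                "Grains, white roots and tubers, and plantains",
                120, 1.4, 0.1, (1.5, 700, 20, 0.2, 0, 0.3, 11, 0.6, 0.3, 30, 25)),
        "I03": ("Lạc", "Root, tubers, nuts, and seeds", "Nuts and seeds",
                570, 3.2, 0.6, (26, 0, 0, 0.35, 0, 8.0, 240, 4.5, 3.3, 90, 170)),
        "I04": ("Thịt lợn", "Red meat", "Meat, poultry and fish",
                250, 12.0, 0.45, (19, 2, 0, 0.45, 0.7, 0.3, 5, 1.0, 2.4, 7, 22)),
        "I05": ("Thịt gà", "White meat", "Meat, poultry and fish",
                170, 6.9, 0.3, (20, 16, 0, 0.5, 0.3, 0.3, 6, 0.9, 1.3, 12, 25)),
        "I06": ("Cá chép", "Fish and seafood", "Meat, poultry and fish",
                120, 5.4, 0.2, (18, 25, 0, 0.2, 1.5, 0.6, 15, 0.9, 1.5, 40, 30)),
        "I07": ("Trứng gà", "Eggs", "Eggs",
                150, 4.5, 0.2, (13, 190, 0, 0.15, 1.1, 1.0, 47, 1.8, 1.1, 55, 12)),
        "I08": ("Sữa tươi", "Milk and dairy products", "Dairy",
                65, 3.0, 0.25, (3.3, 45, 1, 0.05, 0.45, 0.1, 5, 0.05, 0.4, 120, 11)),
        "I09": ("Rau muống", "Rich vitamin vegetables", "Dark green leafy vegetables",
                25, 2.0, 0.05, (2.6, 440, 28, 0.2, 0, 1.1, 60, 2.7, 0.5, 100, 70)),
        "I10": ("Bắp cải", "Other vegetables", "Other vegetables",
                25, 1.5, 0.05, (1.4, 5, 36, 0.12, 0, 0.15, 43, 0.5, 0.2, 48, 12)),
        "I11": ("Chuối", "Fruits", "Other fruits",
                90, 1.1, 0.3, (1.1, 3, 9, 0.35, 0, 0.1, 20, 0.3, 0.15, 6, 27)),
        "I12": ("Nước mắm", "Condiments", None,
                35, 2.0, None, (5.0, 0, 0, 0.05, 0.4, 0, 5, 1.0, 0.3, 40, 20)),
    }
    # retention factors: 1.0 except a few documented losses
    retention_overrides = {
        ("I09", "vitamin_c"): 0.6,
        ("I10", "vitamin_c"): 0.7,
        ("I09", "folate"): 0.7,
    }
    fct_rows, gm_rows, fp_rows = [], [], []
    for code, (name, group, mddw, energy, ghge, bw, dens) in items.items():
        row = {"item_code": code, "name": name, "energy_kcal_100g": float(energy)}
        for j, n in enumerate(DEFAULT_NUTRIENTS):
            row[f"{n}_per_100g"] = float(dens[j])
        for n in DEFAULT_NUTRIENTS:
            row[f"ret_{n}"] = retention_overrides.get((code, n), 1.0)
        fct_rows.append(row)
        gm_rows.append({"item_code": code, "pattern_group": group,
                        "mddw_group": mddw if mddw else np.nan})
        fp_rows.append({"item_code": code, "ghge_kgco2e_per_kg": float(ghge),
                        "bluewater_m3_per_kg": np.nan if bw is None else float(bw)})

    def member(hid, j, age, sex, act):
        return IndividualProfile(member_id=f"{hid}_m{j}", age=age, sex=sex, activity_level=act)

    households = [
        HouseholdRecord("W1", "Red river delta", 3,
                        (member("W1", 1, 25, "female", "moderate"),)),
        HouseholdRecord("W2", "Mekong delta", 2,
                        (member("W2", 1, 25, "female", "moderate"),
                         member("W2", 2, 28, "female", "moderate"))),
        HouseholdRecord("W3", "Northern mountainous", 4,
                        (member("W3", 1, 25, "female", "moderate"),
                         member("W3", 2, 25, "male", "moderate"),
                         member("W3", 3, 8, "female", "moderate"))),
    ]
    log = [
        ("W1", "I01", 365.0), ("W1", "I04", 50.0), ("W1", "I07", 60.0),
        ("W1", "I09", 100.0), ("W1", "I11", 50.0), ("W1", "I12", 20.0),
        ("W2", "I01", 600.0), ("W2", "I02", 100.0), ("W2", "I03", 20.0),
        ("W2", "I06", 200.0), ("W2", "I08", 100.0), ("W2", "I10", 200.0),
        ("W2", "I12", 30.0),
        ("W3", "I01", 900.0), ("W3", "I04", 100.0), ("W3", "I05", 50.0),
        ("W3", "I06", 100.0), ("W3", "I07", 30.0), ("W3", "I09", 150.0),
        ("W3", "I11", 100.0), ("W3", "I12", 30.0),
    ]
    consumption = [ConsumptionRecord(h, c, g) for h, c, g in log]

    # Hand-computed values (arithmetic documented in docs/worked_example.md).
    expected = {
        "afe": {"W1": 1.0, "W2": 2.0, "W3": 6700.0 / 2200.0},
        "energy": {"W1": 1569.5, "W2": 1349.75},
        "nutrients_W1": {"protein": 47.0, "iron": 9.01, "vitamin_c": 21.3},
        "dds": {"W1": 5, "W2": 4, "W3": 4},
        "mdd_met": {"W1": True, "W2": False, "W3": False},
        "ghge_W1": 2.1505,
        "bwu_W1": 0.237,
        "excluded_mass_W1": 20.0,
        "rice_per_afe_W3": 19800.0 / 67.0,
    }
    return WorkedExample(
        households=households,
        consumption=consumption,
        fct=pd.DataFrame(fct_rows).set_index("item_code"),
        groupmap=pd.DataFrame(gm_rows).set_index("item_code"),
        footprint=pd.DataFrame(fp_rows).set_index("item_code"),
        ereq=EnergyRequirementTable.default(),
        expected=expected,
    )
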