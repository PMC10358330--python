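"""Shared domain types and closed vocabularies.

The survey rows are plain dataclasses with eager invariant checks; the
reference tables (food composition, group map, footprint factors) are pandas
DataFrames indexed by ``item_code`` with schemas documented in :mod:`hhdiet.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .exceptions import ValidationError, VocabularyError

# ---------------------------------------------------------------------------
# Closed vocabularies
# ---------------------------------------------------------------------------

SEXES = ("female", "male")
ACTIVITY_LEVELS = ("light", "moderate", "heavy")

REGIONS = (
    "Red river delta",
    "Northern mountainous",
    "North Central and Coastal",
    "Central Highland",
    "Southeast",
    "Mekong delta",
)

#: The 18 food groups used as dietary-pattern input variables, in canonical
#: display order.
PATTERN_GROUPS = (
    "Rice",
    "Non-rice starchy staples",
    "Root, tubers, nuts, and seeds",
    "Red meat",
    "White meat",
    "Organs",
    "Processed meat",
    "Fish and seafood",
    "Eggs",
    "Milk and dairy products",
    "Rich vitamin vegetables",
    "Other vegetables",
    "Fruits",
    "Oils",
    "Fats",
    "Condiments",
    "Sweet foods",
    "Liquor and alcohol",
)

#: The 10 food groups of the women's minimum dietary diversity score.
MDDW_GROUPS = (
    "Grains, white roots and tubers, and plantains",
    "Pulses (beans, peas and lentils)",
    "Nuts and seeds",
    "Dairy",
    "Meat, poultry and fish",
    "Eggs",
    "Dark green leafy vegetables",
    "Other vitamin A-rich fruits and vegetables",
    "Other vegetables",
    "Other fruits",
)

#: Pattern groups with no blue-water factors in the source compilations; items
#: in these groups are excluded from water-use accounting.
BWU_EXCLUDED_GROUPS = frozenset({"Condiments", "Sweet foods", "Liquor and alcohol"})

#: Default nutrient vocabulary for adequacy scoring (11 nutrients).
DEFAULT_NUTRIENTS = (
    "protein",
    "vitamin_a",
    "vitamin_c",
    "vitamin_b6",
    "vitamin_b12",
    "vitamin_e",
    "folate",
    "iron",
    "zinc",
    "calcium",
    "magnesium",
)


# ---------------------------------------------------------------------------
# Survey records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IndividualProfile:
    """One household member, as needed for energy-requirement lookup."""

    member_id: str
    age: int
    sex: str
    activity_level: str

    def __post_init__(self) -> None:
        if self.age < 0:
            raise ValidationError(f"member {self.member_id!r}: age must be >= 0, got {self.age}")
        if self.sex not in SEXES:
            raise VocabularyError(f"member {self.member_id!r}: unknown sex {self.sex!r}")
        if self.activity_level not in ACTIVITY_LEVELS:
            raise VocabularyError(
                f"member {self.member_id!r}: unknown activity level {self.activity_level!r}"
            )


#: The distinguished reference profile: adult female, 20-30 years, moderate
#: activity, whose energy requirement defines one adult-female equivalent.
REFERENCE_FEMALE = IndividualProfile(
    member_id="__reference__", age=25, sex="female", activity_level="moderate"
)


@dataclass(frozen=True)
class HouseholdRecord:
    """Roster entry for one surveyed household."""

    household_id: str
    region: str
    wealth_quintile: int
    members: tuple[IndividualProfile, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValidationError(f"household {self.household_id!r}: members must be non-empty")
        if self.region not in REGIONS:
            raise VocabularyError(f"household {self.household_id!r}: unknown region {self.region!r}")
        if self.wealth_quintile not in (1, 2, 3, 4, 5):
            raise ValidationError(
                f"household {self.household_id!r}: wealth_quintile must be in 1..5, "
                f"got {self.wealth_quintile}"
            )


@dataclass(frozen=True)
class ConsumptionRecord:
    """One row of the 24-h household food log: raw grams of one item."""

    household_id: str
    item_code: str
    grams_raw: float

    def __post_init__(self) -> None:
        if self.grams_raw < 0:
            raise ValidationError(
                f"household {self.household_id!r}, item {self.item_code!r}: "
                f"grams_raw must be >= 0, got {self.grams_raw}"
            )
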