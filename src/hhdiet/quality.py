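"""Diet-quality scoring: probability of adequacy, MPA and MDD-W diversity.

The probability of adequacy (PA) of a nutrient is the probability that the
observed intake exceeds a randomly drawn individual requirement.  Most
nutrients use a normal requirement distribution centred on the EAR with
SD = CV x EAR; iron uses a skewed (log-normal) absorbed-requirement
distribution with a bioavailability factor applied to intake; calcium is a
0/1 comparison against an adequate intake.  Intakes are standardized to a
2,000 kcal diet before scoring so the MPA reflects diet quality rather than
quantity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .afe import PerAFEIntake
from .exceptions import ConfigError, DegenerateInputError, ValidationError
from .model import DEFAULT_NUTRIENTS, MDDW_GROUPS

STANDARD_ENERGY_KCAL = 2000.0
MPA_CUTOFF = 0.5
DDS_GRAM_THRESHOLD = 15.0
DDS_CUTOFF = 5


@dataclass(frozen=True)
class NutrientRequirement:
    """Requirement model for one nutrient.

    Exactly one parameter block is populated, selected by ``kind``:

    ``normal_ear``
        ``ear`` (amount/day) and ``cv`` (SD = cv * ear).
    ``iron_full_probability``
        ``median_absorbed_req`` (mg/day absorbed), ``log_sd`` (SD on the log
        scale) and ``bioavailability`` (fraction of intake absorbed).
    ``ai_threshold``
        ``ai`` (amount/day).
    """

    nutrient: str
    kind: str
    ear: float | None = None
    cv: float | None = None
    ai: float | None = None
    median_absorbed_req: float | None = None
    log_sd: float | None = None
    bioavailability: float = 0.05

    def __post_init__(self) -> None:
        if self.kind == "normal_ear":
            if self.ear is None or self.cv is None:
                raise ConfigError(f"{self.nutrient}: normal_ear requires ear and cv")
            if self.ear <= 0:
                raise ValidationError(f"{self.nutrient}: ear must be > 0")
            if not 0 < self.cv <= 0.5:
                raise ValidationError(f"{self.nutrient}: cv must be in (0, 0.5]")
        elif self.kind == "iron_full_probability":
            if self.median_absorbed_req is None or self.log_sd is None:
                raise ConfigError(
                    f"{self.nutrient}: iron_full_probability requires "
                    "median_absorbed_req and log_sd"
                )
            if self.median_absorbed_req <= 0 or self.log_sd <= 0:
                raise ValidationError(f"{self.nutrient}: iron parameters must be > 0")
            if not 0 < self.bioavailability <= 1:
                raise ValidationError(f"{self.nutrient}: bioavailability must be in (0,1]")
        elif self.kind == "ai_threshold":
            if self.ai is None:
                raise ConfigError(f"{self.nutrient}: ai_threshold requires ai")
            if self.ai <= 0:
                raise ValidationError(f"{self.nutrient}: ai must be > 0")
        else:
            raise ConfigError(f"{self.nutrient}: unknown requirement kind {self.kind!r}")

    @classmethod
    def from_config(cls, nutrient: str, block: Mapping) -> "NutrientRequirement":
        fields = {k: v for k, v in block.items() if k not in ("unit",)}
        return cls(nutrient=nutrient, **fields)


def requirements_from_config(cfg: Mapping) -> dict[str, NutrientRequirement]:
    return {
        n: NutrientRequirement.from_config(n, cfg["requirements"][n])
        for n in cfg["nutrients"]
    }


# ---------------------------------------------------------------------------
# Probability of adequacy
# ---------------------------------------------------------------------------

def standardize_to_2000(nutrient_intake: float, energy: float) -> float:
    """Rescale an intake to a 2,000 kcal diet (nutrient-density scaling)."""
    if energy <= 0:
        raise DegenerateInputError(f"energy must be > 0 to standardize, got {energy}")
    return nutrient_intake * STANDARD_ENERGY_KCAL / energy


def pa_normal(intake: float, req: NutrientRequirement) -> float:
    """PA under a normal requirement distribution: Phi((intake - EAR) / SD)."""
    if req.kind != "normal_ear":
        raise ConfigError(f"pa_normal called with kind {req.kind!r}")
    sd = req.cv * req.ear
    return float(norm.cdf((intake - req.ear) / sd))


def pa_iron(intake: float, req: NutrientRequirement) -> float:
    """Full-probability PA for iron.

    The absorbed intake (intake x bioavailability) is compared against a
    log-normal absorbed-requirement distribution with the given median and
    log-scale SD, the standard parametric form for the skewed requirement of
    menstruating women.
    """
    if req.kind != "iron_full_probability":
        raise ConfigError(f"pa_iron called with kind {req.kind!r}")
    absorbed = intake * req.bioavailability
    if absorbed <= 0:
        return 0.0
    z = (np.log(absorbed) - np.log(req.median_absorbed_req)) / req.log_sd
    return float(norm.cdf(z))


def pa_ai(intake: float, req: NutrientRequirement) -> float:
    """Threshold PA: 1 if intake reaches the adequate intake, else 0."""
    if req.kind != "ai_threshold":
        raise ConfigError(f"pa_ai called with kind {req.kind!r}")
    return 1.0 if intake >= req.ai else 0.0


_PA_DISPATCH = {
    "normal_ear": pa_normal,
    "iron_full_probability": pa_iron,
    "ai_threshold": pa_ai,
}


def probability_of_adequacy(intake: float, req: NutrientRequirement) -> float:
    return _PA_DISPATCH[req.kind](intake, req)


def mpa(
    nutrient_intake: Mapping[str, float],
    energy: float,
    requirements: Mapping[str, NutrientRequirement],
    nutrients: Sequence[str] = DEFAULT_NUTRIENTS,
) -> dict:
    """Per-nutrient PA and their unweighted mean (MPA).

    Each intake is standardized to 2,000 kcal before scoring.  Returns a dict
    with ``pa`` (per-nutrient), ``mpa`` and ``low_mpa`` (mpa < 0.5).
    """
    missing = [n for n in nutrients if n not in requirements]
    if missing:
        raise ConfigError(f"nutrient(s) without a requirement: {missing}")
    missing_intake = [n for n in nutrients if n not in nutrient_intake]
    if missing_intake:
        raise ConfigError(f"nutrient(s) without an intake value: {missing_intake}")
    pa = {
        n: probability_of_adequacy(
            standardize_to_2000(nutrient_intake[n], energy), requirements[n]
        )
        for n in nutrients
    }
    mean_pa = float(np.mean(list(pa.values())))
    return {"pa": pa, "mpa": mean_pa, "low_mpa": mean_pa < MPA_CUTOFF}


# ---------------------------------------------------------------------------
# Dietary diversity
# ---------------------------------------------------------------------------

def dds(
    item_intake: Mapping[str, float],
    groupmap: pd.DataFrame,
    gram_threshold: float = DDS_GRAM_THRESHOLD,
) -> tuple[int, bool]:
    """Women's minimum dietary diversity score.

    Per-AFE grams are summed within each of the 10 MDD-W groups; a group
    scores 1 when its total reaches ``gram_threshold`` (15 g).  Items with no
    MDD-W group (oils, condiments, ...) contribute to no group.  Returns
    ``(score 0..10, score >= 5)``.
    """
    totals = dict.fromkeys(MDDW_GROUPS, 0.0)
    for code, grams in item_intake.items():
        group = groupmap.loc[code, "mddw_group"]
        if isinstance(group, str) and group:
            totals[group] += grams
    score = sum(1 for g in MDDW_GROUPS if totals[g] >= gram_threshold)
    return score, score >= DDS_CUTOFF


# ---------------------------------------------------------------------------
# Population wrapper
# ---------------------------------------------------------------------------

def quality_table(
    per_afe: pd.DataFrame,
    items: pd.DataFrame,
    groupmap: pd.DataFrame,
    requirements: Mapping[str, NutrientRequirement],
    nutrients: Sequence[str] = DEFAULT_NUTRIENTS,
) -> pd.DataFrame:
    """Score every household: per-nutrient PA, MPA, DDS and flags.

    ``per_afe`` and ``items`` are the outputs of
    :func:`hhdiet.afe.convert_population`.
    """
    mddw = groupmap["mddw_group"]
    item_groups = mddw.reindex(items["item_code"]).to_numpy(dtype=object)
    grams = items.assign(mddw_group=item_groups).dropna(subset=["mddw_group"])
    group_totals = grams.pivot_table(
        index="household_id",
        columns="mddw_group",
        values="grams_per_afe",
        aggfunc="sum",
        fill_value=0.0,
    ).reindex(index=per_afe["household_id"], columns=list(MDDW_GROUPS), fill_value=0.0)
    dds_scores = (group_totals.to_numpy() >= DDS_GRAM_THRESHOLD).sum(axis=1)

    rows = []
    for i, row in per_afe.iterrows():
        intakes = {n: row[f"nutrient_{n}"] for n in nutrients}
        res = mpa(intakes, row["energy"], requirements, nutrients)
        rec = {"household_id": row["household_id"], "energy": row["energy"]}
        rec.update({f"pa_{n}": res["pa"][n] for n in nutrients})
        rec["mpa"] = res["mpa"]
        rec["low_mpa"] = res["low_mpa"]
        rows.append(rec)
    out = pd.DataFrame(rows)
    out["dds"] = dds_scores.astype(int)
    out["mdd_met"] = out["dds"] >= DDS_CUTOFF
    return out
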