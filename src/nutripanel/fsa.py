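"""Front-of-pack traffic-light nutrient profiling (FSA scheme).

The UK Food Standards Agency front-of-pack scheme bands the per-100 g amount
of four macro-nutrients — fat, saturated fat, total sugars and sodium — as
green (healthy), amber, or red (unhealthy) against low/high cut points.
Assigning green=1, amber=2, red=3 and summing over the four nutrients yields
a composite healthiness score ranging from 4 (very healthy) to 12 (very
unhealthy).

Default cut points follow the 2007 FSA per-100 g guidance: fat 3.0/20.0 g,
saturated fat 1.5/5.0 g, total sugars 5.0/15.0 g, and salt 0.3/1.5 g.  Salt
cuts are converted to sodium by dividing by 2.5 (and expressed in mg), giving
120/600 mg sodium per 100 g.  All cuts, the salt-to-sodium factor, and the
boundary convention are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum
from typing import Mapping

import pandas as pd

__all__ = [
    "NUTRIENTS",
    "Band",
    "NutrientProfile",
    "BandThresholds",
    "DEFAULT_THRESHOLDS",
    "per_portion",
    "band",
    "fsa_score",
    "score_table",
]

#: The four nutrients of the scheme, in canonical order.  Amounts are per
#: 100 g of recipe: grams for the first three, milligrams for sodium.
NUTRIENTS = ("fat", "saturated_fat", "sugar", "sodium")


class ValidationError(ValueError):
    """Raised when a profile, threshold set, or argument is invalid."""


class Band(IntEnum):
    """Traffic-light band with its fixed integer value."""

    GREEN = 1
    AMBER = 2
    RED = 3


@dataclass(frozen=True)
class NutrientProfile:
    """Amounts of the four scored nutrients for one recipe.

    Amounts are interpreted per 100 g when banding; the same container also
    carries recipe totals (before :func:`per_portion`), in which case
    ``servings`` should be set.

    Parameters
    ----------
    fat, saturated_fat, sugar
        Grams (per 100 g, or recipe totals).
    sodium
        Milligrams (per 100 g, or recipe totals).
    servings
        Number of portions the recipe yields, if the amounts are totals.
    """

    fat: float
    saturated_fat: float
    sugar: float
    sodium: float
    servings: int | None = None

    def __post_init__(self) -> None:
        for name in NUTRIENTS:
            value = getattr(self, name)
            if value is None or not value >= 0:
                raise ValidationError(f"{name} must be a non-negative number, got {value!r}")
        if self.saturated_fat > self.fat + 1e-9:
            raise ValidationError(
                f"saturated_fat ({self.saturated_fat}) cannot exceed fat ({self.fat})"
            )
        if self.servings is not None:
            _check_servings(self.servings)

    def amounts(self) -> dict[str, float]:
        """Nutrient name -> amount mapping, in canonical order."""
        return {name: float(getattr(self, name)) for name in NUTRIENTS}


def _check_servings(servings: object) -> int:
    if isinstance(servings, bool) or not isinstance(servings, (int,)) or servings < 1:
        raise ValidationError(f"servings must be an integer >= 1, got {servings!r}")
    return int(servings)


def _default_cuts(salt_to_sodium: float = 2.5) -> dict[str, tuple[float, float]]:
    # FSA 2007 per-100 g cuts; salt cuts (0.3/1.5 g) expressed as mg sodium.
    return {
        "fat": (3.0, 20.0),
        "saturated_fat": (1.5, 5.0),
        "sugar": (5.0, 15.0),
        "sodium": (0.3 / salt_to_sodium * 1000.0, 1.5 / salt_to_sodium * 1000.0),
    }


@dataclass(frozen=True)
class BandThresholds:
    """Low/high cut points per nutrient plus the boundary convention.

    ``inclusive_low=True`` (default) means an amount exactly at a cut falls
    in the lower band: amount <= low -> green, low < amount <= high -> amber,
    amount > high -> red.  With ``inclusive_low=False`` the cuts themselves
    belong to the upper band.
    """

    cuts: Mapping[str, tuple[float, float]] = field(default_factory=_default_cuts)
    inclusive_low: bool = True

    def __post_init__(self) -> None:
        for name in NUTRIENTS:
            if name not in self.cuts:
                raise ValidationError(f"missing cut points for nutrient {name!r}")
            low, high = self.cuts[name]
            if not (0 < low < high):
                raise ValidationError(
                    f"cut points for {name!r} must satisfy 0 < low < high, got {(low, high)}"
                )

    @classmethod
    def fsa_2007(cls, salt_to_sodium: float = 2.5, inclusive_low: bool = True) -> "BandThresholds":
        """The 2007 FSA front-of-pack guidance with a configurable salt factor."""
        return cls(cuts=_default_cuts(salt_to_sodium), inclusive_low=inclusive_low)


DEFAULT_THRESHOLDS = BandThresholds()


def per_portion(totals: NutrientProfile, servings: int | None = None) -> NutrientProfile:
    """Convert recipe-total nutrient amounts to per-portion amounts.

    Divides every nutrient total by the number of portions the recipe
    yields.  ``servings`` defaults to ``totals.servings``.
    """
    if servings is None:
        servings = totals.servings
    if servings is None:
        raise ValidationError("servings must be given either in the profile or as an argument")
    n = _check_servings(servings)
    return NutrientProfile(
        fat=totals.fat / n,
        saturated_fat=totals.saturated_fat / n,
        sugar=totals.sugar / n,
        sodium=totals.sodium / n,
    )


def band(
    nutrient: str,
    amount: float,
    thresholds: BandThresholds = DEFAULT_THRESHOLDS,
) -> Band:
    """Band one nutrient's per-100 g amount as green, amber, or red."""
    if nutrient not in NUTRIENTS:
        raise ValidationError(f"unknown nutrient {nutrient!r}; expected one of {NUTRIENTS}")
    if not amount >= 0:
        raise ValidationError(f"amount must be non-negative, got {amount!r}")
    low, high = thresholds.cuts[nutrient]
    if thresholds.inclusive_low:
        if amount <= low:
            return Band.GREEN
        if amount <= high:
            return Band.AMBER
        return Band.RED
    if amount < low:
        return Band.GREEN
    if amount < high:
        return Band.AMBER
    return Band.RED


def fsa_score(
    profile: NutrientProfile,
    thresholds: BandThresholds = DEFAULT_THRESHOLDS,
) -> int:
    """Composite FSA health score of a complete per-100 g profile.

    Sums the band values (green=1, amber=2, red=3) of the four nutrients;
    the result is an integer between 4 (all green) and 12 (all red).
    """
    return int(sum(band(name, amount, thresholds) for name, amount in profile.amounts().items()))


def score_table(
    recipes: pd.DataFrame,
    thresholds: BandThresholds = DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """Batch-score a recipe table.

    ``recipes`` must contain the four nutrient columns (per 100 g).  Returns
    a copy with one ``<nutrient>_band`` column per nutrient and an
    ``fsa_score`` column.  Rows with missing or negative nutrient values are
    rejected, mirroring the exclusion of recipes without full nutrition
    information.
    """
    missing = [c for c in NUTRIENTS if c not in recipes.columns]
    if missing:
        raise ValidationError(f"recipe table lacks nutrient columns: {missing}")
    out = recipes.copy()
    bad = out[list(NUTRIENTS)].isna().any(axis=1) | (out[list(NUTRIENTS)] < 0).any(axis=1)
    if bad.any():
        raise ValidationError(
            f"{int(bad.sum())} recipe rows have missing or negative nutrient values"
        )
    score = pd.Series(0, index=out.index, dtype=int)
    for name in NUTRIENTS:
        low, high = thresholds.cuts[name]
        amount = out[name].to_numpy(dtype=float)
        if thresholds.inclusive_low:
            values = 1 + (amount > low).astype(int) + (amount > high).astype(int)
        else:
            values = 1 + (amount >= low).astype(int) + (amount >= high).astype(int)
        out[f"{name}_band"] = values
        score += values
    out["fsa_score"] = score
    return out
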