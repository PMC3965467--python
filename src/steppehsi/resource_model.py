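"""Species resource requirements and per-cover suitability.

A species' requirements are held as *categorical* preference levels
(``not_used`` / ``rare`` / ``preferred``) for the four sward-height
categories and the four food resources, per vital activity (nesting,
foraging) and management period.  Levels are resolved to numbers through a
:class:`ScoringScheme` at computation time, so re-running the model under an
alternative scheme is a pure re-parameterisation — the basis of the
sensitivity analysis.

Suitability of a cover type for an activity is the scalar product of the
availability vector and the requirement vector.  Food-based suitability is
truncated at 1 (different food types substitute for each other until the
diet is satisfied); foraging suitability is the product of the structural
and food components (both obligate); nesting suitability is structural
only and is defined only for species/months inside the nesting window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .availability import (
    FOOD_RESOURCES,
    HEIGHT_CATEGORIES,
    MONTHS,
    AvailabilityBundle,
    HeightScoreTable,
    ValidationError,
    period_of_month,
)

LEVELS: tuple[str, ...] = ("not_used", "rare", "preferred")
ACTIVITIES: tuple[str, ...] = ("nesting", "foraging")


@dataclass(frozen=True)
class ScoringScheme:
    """Numeric values for the three preference/probability levels."""

    not_used: float = 0.0
    rare: float = 0.5
    preferred: float = 1.0
    label: str = "default"

    def __post_init__(self) -> None:
        if not (0.0 <= self.not_used <= self.rare <= self.preferred <= 1.0):
            raise ValidationError(
                f"scheme values must satisfy 0 <= not_used <= rare <= preferred <= 1, "
                f"got {(self.not_used, self.rare, self.preferred)}"
            )

    def value(self, level: str) -> float:
        try:
            return {"not_used": self.not_used, "rare": self.rare, "preferred": self.preferred}[
                level
            ]
        except KeyError:
            raise ValidationError(f"unknown preference level {level!r}") from None


#: Default diet / height-probability scheme (not used 0, rare 0.5, usual 1).
DEFAULT_SCHEME = ScoringScheme(0.0, 0.5, 1.0, label="0/0.5/1")
#: Height *preferences* are binary: a category is either used or not.
BINARY_SCHEME = ScoringScheme(0.0, 0.0, 1.0, label="0/1")
#: Alternative schemes examined by the sensitivity analysis.
ALTERNATIVE_SCHEMES: tuple[ScoringScheme, ...] = (
    ScoringScheme(0.0, 0.0, 1.0, label="0/0/1"),
    ScoringScheme(0.0, 0.25, 1.0, label="0/0.25/1"),
    ScoringScheme(0.0, 0.75, 1.0, label="0/0.75/1"),
)


def score_height_levels(levels: pd.DataFrame, scheme: ScoringScheme) -> HeightScoreTable:
    """Resolve a categorical height-level table to numeric probability scores.

    *levels* has columns ``cover_type, month`` plus one column per height
    category holding a level from :data:`LEVELS`.
    """
    df = levels.copy()
    for cat in HEIGHT_CATEGORIES:
        df[cat] = [scheme.value(level) for level in df[cat]]
    return HeightScoreTable(df)


@dataclass(frozen=True)
class RequirementTable:
    """Categorical requirement levels per species, activity and period.

    ``levels`` columns: ``species, activity, period, resource_class,
    resource, level`` where ``resource_class`` is ``height`` or ``food``;
    nesting rows use period ``all`` (nesting height preferences do not vary
    within the season).  ``nesting_months`` maps species to the set of
    months with nesting activity; a species absent from the mapping (or
    mapped to an empty set) has no nesting component.
    """

    levels: pd.DataFrame
    nesting_months: Mapping[str, frozenset[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"species", "activity", "period", "resource_class", "resource", "level"}
        missing = required - set(self.levels.columns)
        if missing:
            raise ValidationError(f"requirement table missing columns {sorted(missing)}")
        bad = set(self.levels["level"]) - set(LEVELS)
        if bad:
            raise ValidationError(f"unknown preference levels {sorted(bad)}")
        nesting_species = set(self.levels.loc[self.levels["activity"] == "nesting", "species"])
        for sp in nesting_species:
            if not self.nesting_months.get(sp):
                raise ValidationError(
                    f"species {sp!r} has nesting requirement rows but no nesting window"
                )

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(self.levels["species"]))

    def nests(self, species: str, month: int | None = None) -> bool:
        months = self.nesting_months.get(species) or frozenset()
        if month is None:
            return bool(months)
        return month in months

    def vector(
        self,
        species: str,
        activity: str,
        period: str,
        resource_class: str,
        scheme: ScoringScheme,
    ) -> np.ndarray:
        """Numeric requirement vector over the 4 categories of *resource_class*."""
        names = HEIGHT_CATEGORIES if resource_class == "height" else FOOD_RESOURCES
        sub = self.levels[
            (self.levels["species"] == species)
            & (self.levels["activity"] == activity)
            & (self.levels["period"] == period)
            & (self.levels["resource_class"] == resource_class)
        ]
        if sub.empty:
            raise ValidationError(
                f"no {resource_class} requirements for {species!r}/{activity}/{period}"
            )
        by_resource = dict(zip(sub["resource"], sub["level"]))
        missing = set(names) - set(by_resource)
        if missing:
            raise ValidationError(
                f"requirements for {species!r}/{activity}/{period} missing {sorted(missing)}"
            )
        return np.array([scheme.value(by_resource[name]) for name in names], dtype=float)


# ---------------------------------------------------------------------------
# Elementary suitability operations
# ---------------------------------------------------------------------------


def _check4(vec: np.ndarray, name: str) -> np.ndarray:
    vec = np.asarray(vec, dtype=float)
    if vec.shape != (4,):
        raise ValidationError(f"{name} vector must have length 4, got shape {vec.shape}")
    return vec


def structural_suitability(height_frequencies, height_requirements) -> float:
    """Scalar product of height-frequency and height-preference vectors.

    Bounded by [0, 1] because the frequencies sum to 1 and preferences lie
    in [0, 1].
    """
    a = _check4(height_frequencies, "availability")
    r = _check4(height_requirements, "requirement")
    return float(a @ r)


def diet_suitability(food_availability, diet_requirements) -> float:
    """Scalar product of food availability and diet preference, capped at 1.

    The cap encodes substitutability: a species can satisfy its diet from
    several resources, but not beyond full satisfaction.
    """
    a = _check4(food_availability, "availability")
    r = _check4(diet_requirements, "requirement")
    return float(min(1.0, a @ r))


def foraging_suitability(structural: float, diet: float) -> float:
    """Product of structural accessibility and expected food abundance.

    Both components are obligate, hence multiplicative: a cover with perfect
    food but inaccessible sward (or vice versa) scores 0.
    """
    return float(structural) * float(diet)


def nesting_suitability(structural_nesting: float) -> float:
    """Nesting suitability is the structural component alone (identity)."""
    return float(structural_nesting)


def total_from_components(foraging: float, nesting: float | None) -> float:
    """Geometric mean of foraging and nesting; foraging alone if no nesting."""
    if nesting is None or (isinstance(nesting, float) and math.isnan(nesting)):
        return float(foraging)
    return math.sqrt(float(foraging) * float(nesting))


# ---------------------------------------------------------------------------
# Series construction
# ---------------------------------------------------------------------------


def build_suitability_series(
    requirements: RequirementTable,
    availability: AvailabilityBundle,
    diet_scheme: ScoringScheme = DEFAULT_SCHEME,
    height_pref_scheme: ScoringScheme = BINARY_SCHEME,
) -> pd.DataFrame:
    """Monthly suitability for every (species, cover type) pair.

    Returns one row per (species, cover_type, month 4-9) with columns
    ``structural_foraging, diet, foraging, nesting, monthly_total``.  The
    diet component is constant within each period (food preferences and
    expected abundance are period-level quantities).  ``nesting`` is NaN —
    absent, not zero — outside a species' nesting months; ``monthly_total``
    is the per-month geometric mean of foraging and nesting while nesting,
    and equals foraging otherwise (the reporting convention for monthly
    trajectories).
    """
    records = []
    for species in requirements.species:
        for cover in availability.cover_types:
            for month in MONTHS:
                period = period_of_month(month)
                hv = availability.height_vector(cover, month)
                fr = requirements.vector(species, "foraging", period, "height", height_pref_scheme)
                structural = structural_suitability(hv, fr)
                dr = requirements.vector(species, "foraging", period, "food", diet_scheme)
                fa = availability.food_vector(cover, period)
                diet = diet_suitability(fa, dr)
                forage = foraging_suitability(structural, diet)
                if requirements.nests(species, month):
                    nr = requirements.vector(species, "nesting", "all", "height", height_pref_scheme)
                    nest: float | None = nesting_suitability(structural_suitability(hv, nr))
                else:
                    nest = None
                records.append(
                    {
                        "species": species,
                        "cover_type": cover,
                        "month": month,
                        "structural_foraging": structural,
                        "diet": diet,
                        "foraging": forage,
                        "nesting": np.nan if nest is None else nest,
                        "monthly_total": total_from_components(forage, nest),
                    }
                )
    return pd.DataFrame.from_records(records)
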