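"""Resource availability in agricultural cover types.

Builds the availability matrix ``A = [a_kj]`` that the suitability model
multiplies against species requirement vectors.  Two resource families are
covered:

* **food resources** (seeds, plant material, invertebrates, vertebrates),
  whose expected abundance in a cover type is depressed by the agricultural
  practices applied there (agro-chemical inputs, irrigation, ploughing) and
  by the intensity of the production system, via ``a = 1 / (n * f + 1)``;
* **habitat structure**, expressed as relative frequencies of four sward
  height categories (0-25, 25-50, 50-100, >100 cm) per cover type and month,
  obtained by normalising qualitative presence scores.

All tables are plain :class:`pandas.DataFrame` objects with documented
columns so they round-trip through CSV unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping

import numpy as np
import pandas as pd

# ---------------------------------------------------------------------------
# Fixed vocabularies: four sward-height categories, four food resources,
# three impacting practices, breeding months April-September split into a
# spring (Apr-Jun) and a summer (Jul-Sep) management period.
# ---------------------------------------------------------------------------

HEIGHT_CATEGORIES: tuple[str, ...] = ("h0_25", "h25_50", "h50_100", "h100p")
FOOD_RESOURCES: tuple[str, ...] = ("seeds", "plants", "invertebrates", "vertebrates")
PRACTICES: tuple[str, ...] = ("agrochemical", "irrigation", "plough")
MONTHS: tuple[int, ...] = (4, 5, 6, 7, 8, 9)
SPRING_MONTHS: frozenset[int] = frozenset({4, 5, 6})
SUMMER_MONTHS: frozenset[int] = frozenset({7, 8, 9})
PERIODS: tuple[str, ...] = ("spring", "summer")

ScalingMode = Literal["yield", "unit", "coarse"]


def period_of_month(month: int) -> str:
    """Map a calendar month (4-9) to its management period."""
    if month in SPRING_MONTHS:
        return "spring"
    if month in SUMMER_MONTHS:
        return "summer"
    raise ValueError(f"month {month} outside the modelled season (4-9)")


class ConfigurationError(ValueError):
    """An input table references entities that are not configured."""


class ValidationError(ValueError):
    """An input table violates a structural constraint."""


# ---------------------------------------------------------------------------
# Input tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PracticeImpactTable:
    """Presence/absence of practice impacts on food resources.

    Parameters
    ----------
    flags
        DataFrame with columns ``cover_type, period, practice, resource,
        flag`` where ``flag`` is 0/1: practice *practice* removes resource
        *resource* in *cover_type* during *period*.
    exemptions
        Pairs ``(cover_type, resource)`` for which practice impacts are
        waived because the resource is the crop itself (e.g. alfalfa is
        consumable plant material), forcing a practice count of zero.
    """

    flags: pd.DataFrame
    exemptions: frozenset[tuple[str, str]] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        required = {"cover_type", "period", "practice", "resource", "flag"}
        missing = required - set(self.flags.columns)
        if missing:
            raise ValidationError(f"practice table missing columns {sorted(missing)}")
        bad_practice = set(self.flags["practice"]) - set(PRACTICES)
        if bad_practice:
            raise ValidationError(f"unknown practices {sorted(bad_practice)}")
        bad_resource = set(self.flags["resource"]) - set(FOOD_RESOURCES)
        if bad_resource:
            raise ValidationError(f"unknown food resources {sorted(bad_resource)}")
        bad_period = set(self.flags["period"]) - set(PERIODS)
        if bad_period:
            raise ValidationError(f"unknown periods {sorted(bad_period)}")
        if not self.flags["flag"].isin((0, 1, True, False)).all():
            raise ValidationError("practice flags must be boolean 0/1")

    @property
    def cover_types(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(self.flags["cover_type"]))

    def practice_count(self, cover_type: str, resource: str, period: str) -> int:
        """Number of distinct practices impacting *resource* (after exemptions)."""
        if (cover_type, resource) in self.exemptions:
            return 0
        sub = self.flags
        mask = (
            (sub["cover_type"] == cover_type)
            & (sub["resource"] == resource)
            & (sub["period"] == period)
            & (sub["flag"].astype(bool))
        )
        n = int(sub.loc[mask, "practice"].nunique())
        assert 0 <= n <= 3
        return n


@dataclass(frozen=True)
class IntensityTable:
    """Production-system intensity ``f`` per cover type.

    ``yield`` mode uses field yield in tonnes/ha (fallows fixed at 1),
    ``unit`` mode sets f = 1 everywhere, and ``coarse`` mode uses a
    qualitative two-level classification (1 low-intensive, 2 high-intensive).
    """

    yields_t_ha: Mapping[str, float]
    scaling_mode: ScalingMode = "yield"
    coarse_class: Mapping[str, int] = field(default_factory=dict)
    fallow_covers: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.scaling_mode not in ("yield", "unit", "coarse"):
            raise ConfigurationError(f"unknown scaling mode {self.scaling_mode!r}")
        for cover, cls in self.coarse_class.items():
            if cls not in (1, 2):
                raise ValidationError(f"coarse class for {cover!r} must be 1 or 2, got {cls}")

    def intensity(self, cover_type: str) -> float:
        if self.scaling_mode == "unit":
            return 1.0
        if self.scaling_mode == "coarse":
            try:
                return float(self.coarse_class[cover_type])
            except KeyError:
                raise ConfigurationError(
                    f"cover type {cover_type!r} has no declared coarse intensity class"
                ) from None
        # yield mode
        if cover_type in self.fallow_covers:
            return 1.0
        try:
            y = float(self.yields_t_ha[cover_type])
        except KeyError:
            raise ConfigurationError(f"cover type {cover_type!r} has no yield") from None
        if y <= 0:
            raise ValidationError(f"non-positive yield {y} for cover type {cover_type!r}")
        return y

    def with_mode(self, mode: ScalingMode) -> "IntensityTable":
        return IntensityTable(self.yields_t_ha, mode, self.coarse_class, self.fallow_covers)


@dataclass(frozen=True)
class HeightScoreTable:
    """Qualitative sward-height probability scores per cover type and month.

    ``scores`` has columns ``cover_type, month`` plus one column per height
    category; values come from a scoring scheme (default 0 / 0.5 / 1 for
    "not possible" / "rare" / "usual").
    """

    scores: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"cover_type", "month", *HEIGHT_CATEGORIES}
        missing = required - set(self.scores.columns)
        if missing:
            raise ValidationError(f"height-score table missing columns {sorted(missing)}")
        bad_months = set(self.scores["month"].astype(int)) - set(MONTHS)
        if bad_months:
            raise ValidationError(f"height scores outside months 4-9: {sorted(bad_months)}")


# ---------------------------------------------------------------------------
# Output bundle
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AvailabilityBundle:
    """The availability matrix A, split by resource family.

    ``food`` has columns ``cover_type, period`` plus one column per food
    resource, every value in (0, 1].  ``height`` has columns ``cover_type,
    month`` plus one column per height category, each row summing to 1.
    """

    food: pd.DataFrame
    height: pd.DataFrame

    def food_vector(self, cover_type: str, period: str) -> np.ndarray:
        row = self.food[
            (self.food["cover_type"] == cover_type) & (self.food["period"] == period)
        ]
        if row.empty:
            raise ValidationError(f"no food availability for ({cover_type!r}, {period!r})")
        return row.iloc[0][list(FOOD_RESOURCES)].to_numpy(dtype=float)

    def height_vector(self, cover_type: str, month: int) -> np.ndarray:
        row = self.height[
            (self.height["cover_type"] == cover_type) & (self.height["month"] == month)
        ]
        if row.empty:
            raise ValidationError(f"no height frequencies for ({cover_type!r}, month {month})")
        return row.iloc[0][list(HEIGHT_CATEGORIES)].to_numpy(dtype=float)

    @property
    def cover_types(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(self.height["cover_type"]))


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def food_availability_value(n: int, f: float) -> float:
    """Expected relative abundance of a food resource, ``1 / (n*f + 1)``.

    ``n`` is the number of practices that negatively affect the resource and
    ``f`` the production-system intensity; the ``+1`` keeps the value finite
    and in (0, 1], with 1 exactly when no practice applies.
    """
    if n < 0 or f <= 0:
        raise ValidationError(f"practice count must be >= 0 and intensity > 0 (n={n}, f={f})")
    return 1.0 / (n * f + 1.0)


def compute_food_availability(
    practices: PracticeImpactTable, intensity: IntensityTable
) -> pd.DataFrame:
    """Food part of the availability bundle, one row per (cover, period)."""
    records = []
    for cover in practices.cover_types:
        f = intensity.intensity(cover)  # raises ConfigurationError if unknown
        for period in PERIODS:
            rec: dict[str, object] = {"cover_type": cover, "period": period}
            for resource in FOOD_RESOURCES:
                n = practices.practice_count(cover, resource, period)
                rec[resource] = food_availability_value(n, f)
            records.append(rec)
    return pd.DataFrame.from_records(records)


def normalize_height_scores(scores: HeightScoreTable) -> pd.DataFrame:
    """Turn qualitative height scores into relative frequencies.

    Each (cover, month) score vector is divided by its sum so the four
    categories form a probability vector; a cell whose scores are all zero is
    a contradiction (some sward height must be possible) and is rejected.
    """
    df = scores.scores.copy()
    cats = list(HEIGHT_CATEGORIES)
    values = df[cats].to_numpy(dtype=float)
    if (values < 0).any():
        raise ValidationError("height scores must be non-negative")
    totals = values.sum(axis=1)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        row = df.iloc[zero[0]]
        raise ValidationError(
            f"all-zero height scores for cover {row['cover_type']!r}, month {int(row['month'])}"
        )
    df[cats] = values / totals[:, None]
    return df[["cover_type", "month", *cats]]


def build_availability(
    practices: PracticeImpactTable,
    intensity: IntensityTable,
    height_scores: HeightScoreTable,
) -> AvailabilityBundle:
    """Assemble the full availability bundle from raw input tables."""
    return AvailabilityBundle(
        food=compute_food_availability(practices, intensity),
        height=normalize_height_scores(height_scores),
    )


def round_half_even(values: Iterable[float], decimals: int = 2) -> np.ndarray:
    """Banker's rounding, used when comparing against printed tables."""
    return np.round(np.asarray(list(values), dtype=float), decimals)
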