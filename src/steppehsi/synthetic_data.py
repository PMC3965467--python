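"""Synthetic inputs with the statistical structure the pipeline assumes.

Field censuses behind the original study are not public, so this module
provides two substitutes:

* **simulators** producing phenology-consistent cover tables and survey
  transects: crop sward heights follow a sow → peak → harvest trajectory,
  transect compositions are Dirichlet draws scaled by a Beta-distributed
  unsuitable-area share, and presence/absence labels are Bernoulli with a
  logistic link on true total suitability (the link slope is the single
  signal-strength knob — slope 0 yields labels independent of habitat);
* **a packaged study fixture**: the four study species' requirement levels,
  the six cover types' practice flags, exemption and field yields, the
  printed landscape composition, and a *reconstructed* monthly sward-height
  profile (the original supplementary profiles are not reproduced in the
  main text; this reconstruction encodes winter-cereal growth to harvest,
  later irrigated-cereal harvest, maize's late tall growth, alfalfa cutting
  cycles and persistently short fallows).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .availability import (
    FOOD_RESOURCES,
    HEIGHT_CATEGORIES,
    MONTHS,
    HeightScoreTable,
    IntensityTable,
    PracticeImpactTable,
    ValidationError,
)
from .integration import FULL_SEASON, TransectRecord, integrate_transects
from .resource_model import DEFAULT_SCHEME, RequirementTable, ScoringScheme

# ---------------------------------------------------------------------------
# Packaged study fixture
# ---------------------------------------------------------------------------

SPECIES = ("little_bustard", "stone_curlew", "calandra_lark", "red_legged_partridge")
COVER_TYPES = (
    "no_till_fallow",
    "till_fallow",
    "dry_cereal",
    "irrigated_cereal",
    "alfalfa",
    "maize",
)

_N, _R, _P = "not_used", "rare", "preferred"

# species -> activity/period -> (4 height levels) or (4 diet levels)
_HEIGHT_REQUIREMENTS: dict[str, dict[str, tuple[str, ...]]] = {
    "little_bustard": {"spring": (_P, _P, _N, _N), "summer": (_P, _P, _N, _N)},
    "calandra_lark": {"spring": (_P, _P, _N, _N), "summer": (_P, _N, _N, _N)},
    "stone_curlew": {"spring": (_P, _N, _N, _N), "summer": (_P, _N, _N, _N)},
    "red_legged_partridge": {"spring": (_P, _P, _N, _N), "summer": (_P, _P, _N, _N)},
}
_DIET_REQUIREMENTS: dict[str, dict[str, tuple[str, ...]]] = {
    # order: seeds, plants, invertebrates, vertebrates
    "little_bustard": {"spring": (_R, _P, _R, _N), "summer": (_R, _P, _P, _N)},
    "calandra_lark": {"spring": (_P, _R, _P, _N), "summer": (_P, _R, _R, _N)},
    "stone_curlew": {"spring": (_N, _N, _P, _R), "summer": (_N, _N, _P, _R)},
    "red_legged_partridge": {"spring": (_R, _P, _R, _N), "summer": (_P, _P, _P, _N)},
}
_NESTING_HEIGHTS: dict[str, tuple[str, ...]] = {
    "calandra_lark": (_P, _P, _N, _N),
    "stone_curlew": (_P, _N, _N, _N),
    "red_legged_partridge": (_N, _P, _P, _P),
    # little_bustard: occurrence data cover displaying males only, which take
    # no part in nesting — no nesting component.
}
_NESTING_MONTHS: dict[str, frozenset[int]] = {
    "calandra_lark": frozenset({4, 5, 6}),
    "red_legged_partridge": frozenset({4, 5, 6}),
    "stone_curlew": frozenset({4, 5, 6, 7}),
}

# Practice flags: practice -> (impacted resources, {cover: (spring, summer)}).
_PRACTICE_FLAGS: dict[str, tuple[tuple[str, ...], dict[str, tuple[int, int]]]] = {
    "agrochemical": (
        ("plants", "seeds", "invertebrates"),
        {
            "no_till_fallow": (1, 0),  # herbicide weed control in spring
            "till_fallow": (0, 0),
            "dry_cereal": (1, 1),
            "irrigated_cereal": (1, 1),
            "alfalfa": (1, 1),
            "maize": (1, 1),
        },
    ),
    "irrigation": (
        ("plants", "invertebrates"),
        {
            "no_till_fallow": (0, 0),
            "till_fallow": (0, 0),
            "dry_cereal": (0, 0),
            "irrigated_cereal": (1, 0),
            "alfalfa": (1, 1),
            "maize": (1, 1),
        },
    ),
    "plough": (
        ("invertebrates", "plants", "seeds", "vertebrates"),
        {
            "no_till_fallow": (0, 0),
            "till_fallow": (1, 1),
            "dry_cereal": (0, 1),  # post-harvest plough
            "irrigated_cereal": (0, 1),
            "alfalfa": (0, 0),
            "maize": (0, 0),
        },
    ),
}

_YIELDS_T_HA = {"dry_cereal": 2.0, "irrigated_cereal": 7.0, "alfalfa": 14.0, "maize": 12.0}
_FALLOW_COVERS = frozenset({"no_till_fallow", "till_fallow"})
_COARSE_CLASS = {
    "dry_cereal": 1,
    "till_fallow": 1,
    "no_till_fallow": 1,
    "irrigated_cereal": 2,
    "alfalfa": 2,
    "maize": 2,
}

#: Study-area cover composition at survey time (area proportions).
LANDSCAPE_COMPOSITION: dict[str, float] = {
    "dry_cereal": 0.71,
    "till_fallow": 0.03,
    "no_till_fallow": 0.07,
    "maize": 0.01,
    "irrigated_cereal": 0.09,
    "alfalfa": 0.04,
    "other": 0.05,  # remainder to 1: shrub, urban, orchards
}

# Reconstructed monthly sward-height levels, cover -> month -> 4 levels.
# Not ground truth: a phenology-consistent stand-in for the study's expert
# height profiles.
_HEIGHT_LEVELS: dict[str, dict[int, tuple[str, ...]]] = {
    "no_till_fallow": {
        4: (_P, _R, _N, _N), 5: (_P, _R, _N, _N), 6: (_P, _R, _N, _N),
        7: (_P, _N, _N, _N), 8: (_P, _N, _N, _N), 9: (_P, _N, _N, _N),
    },
    "till_fallow": {
        4: (_P, _R, _N, _N), 5: (_P, _R, _N, _N), 6: (_P, _R, _N, _N),
        7: (_P, _N, _N, _N), 8: (_P, _N, _N, _N), 9: (_P, _N, _N, _N),
    },
    "dry_cereal": {
        4: (_N, _P, _R, _N), 5: (_N, _R, _P, _N), 6: (_R, _R, _P, _N),
        7: (_P, _N, _R, _N), 8: (_P, _N, _N, _N), 9: (_P, _N, _N, _N),
    },
    "irrigated_cereal": {
        4: (_N, _P, _R, _N), 5: (_N, _R, _P, _N), 6: (_N, _N, _P, _R),
        7: (_R, _N, _P, _N), 8: (_P, _N, _N, _N), 9: (_P, _N, _N, _N),
    },
    "alfalfa": {m: (_P, _P, _R, _N) for m in MONTHS},
    "maize": {
        4: (_P, _N, _N, _N), 5: (_P, _R, _N, _N), 6: (_R, _P, _R, _N),
        7: (_N, _R, _P, _R), 8: (_N, _N, _R, _P), 9: (_N, _N, _N, _P),
    },
}


def _requirement_rows() -> pd.DataFrame:
    rows = []
    for sp in SPECIES:
        for period in ("spring", "summer"):
            for cat, level in zip(HEIGHT_CATEGORIES, _HEIGHT_REQUIREMENTS[sp][period]):
                rows.append((sp, "foraging", period, "height", cat, level))
            for res, level in zip(FOOD_RESOURCES, _DIET_REQUIREMENTS[sp][period]):
                rows.append((sp, "foraging", period, "food", res, level))
        if sp in _NESTING_HEIGHTS:
            for cat, level in zip(HEIGHT_CATEGORIES, _NESTING_HEIGHTS[sp]):
                rows.append((sp, "nesting", "all", "height", cat, level))
    return pd.DataFrame(
        rows, columns=["species", "activity", "period", "resource_class", "resource", "level"]
    )


def _practice_rows(flags=_PRACTICE_FLAGS, covers=COVER_TYPES) -> pd.DataFrame:
    rows = []
    for practice, (resources, per_cover) in flags.items():
        for cover in covers:
            sp, su = per_cover[cover]
            for resource in resources:
                rows.append((cover, "spring", practice, resource, sp))
                rows.append((cover, "summer", practice, resource, su))
    return pd.DataFrame(rows, columns=["cover_type", "period", "practice", "resource", "flag"])


def height_levels_frame(levels: Mapping[str, Mapping[int, tuple[str, ...]]]) -> pd.DataFrame:
    rows = []
    for cover, months in levels.items():
        for month, tup in months.items():
            rows.append((cover, month, *tup))
    return pd.DataFrame(rows, columns=["cover_type", "month", *HEIGHT_CATEGORIES])


@dataclass(frozen=True)
class StudyFixture:
    """Complete model input bundle for the six-cover, four-species study."""

    species: tuple[str, ...]
    cover_types: tuple[str, ...]
    requirements: RequirementTable
    practices: PracticeImpactTable
    intensity: IntensityTable
    height_levels: pd.DataFrame
    landscape: dict[str, float]
    metadata: dict[str, str]


def packaged_study_fixture() -> StudyFixture:
    """The packaged four-species / six-cover study parameterisation.

    Requirement levels, practice flags, the alfalfa plant-material
    exemption, field yields and the landscape composition are encoded from
    the published study tables; the monthly height profiles are a
    documented *reconstruction* (``metadata["height_profiles"]``).
    """
    return StudyFixture(
        species=SPECIES,
        cover_types=COVER_TYPES,
        requirements=RequirementTable(_requirement_rows(), dict(_NESTING_MONTHS)),
        practices=PracticeImpactTable(
            _practice_rows(), exemptions=frozenset({("alfalfa", "plants")})
        ),
        intensity=IntensityTable(
            dict(_YIELDS_T_HA),
            scaling_mode="yield",
            coarse_class=dict(_COARSE_CLASS),
            fallow_covers=_FALLOW_COVERS,
        ),
        height_levels=height_levels_frame(_HEIGHT_LEVELS),
        landscape=dict(LANDSCAPE_COMPOSITION),
        metadata={"height_profiles": "reconstructed", "tables": "encoded from publication"},
    )


# ---------------------------------------------------------------------------
# Simulators
# ---------------------------------------------------------------------------

#: Crop phenology archetypes: (sow month, peak month, harvest month, peak
#: height category index).  ``None`` months mean "outside the season".
PHENOLOGY_ARCHETYPES: dict[str, dict] = {
    # permanently short sward, no crop cycle
    "fallow_like": {"sow": None, "peak": None, "harvest": None, "peak_cat": 0},
    # autumn-sown cereal: already grown in April, harvested mid-season
    "tall_cereal": {"sow": None, "peak": 6, "harvest": 7, "peak_cat": 3},
    # spring-sown row crop growing tall late in the season (maize-like)
    "spring_sown_tall": {"sow": 4, "peak": 9, "harvest": None, "peak_cat": 3},
    # forage crop on a cutting cycle, never exceeding mid heights
    "cutting_forage": {"sow": None, "peak": None, "harvest": None, "peak_cat": 1},
    # short spring crop harvested early
    "short_crop": {"sow": 4, "peak": 6, "harvest": 8, "peak_cat": 2},
}
_ARCHETYPE_CYCLE = tuple(PHENOLOGY_ARCHETYPES)


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic study generator.

    ``dirichlet_alpha`` controls transect heterogeneity: the default 0.3
    makes most transects dominated by one or two covers, matching surveys
    where the dominant cover averages about three quarters of the surface.
    ``unsuitable_beta`` draws the unsuitable-area share (default mean 0.2,
    so modelled covers hold ~80% of a transect).  The occurrence link is
    ``logit P(presence) = intercept + slope * total_suitability``; slope 0
    severs labels from habitat entirely.
    """

    n_cover_types: int = 6
    n_transects: int = 150
    n_species: int = 4
    dirichlet_alpha: float = 0.3
    unsuitable_beta: tuple[float, float] = (1.0, 4.0)
    occurrence_intercept: float = -1.5
    occurrence_slope: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_cover_types, self.n_transects, self.n_species) <= 0:
            raise ValidationError("all counts must be positive")
        if self.dirichlet_alpha <= 0 or min(self.unsuitable_beta) <= 0:
            raise ValidationError("Dirichlet/Beta parameters must be positive")
        if self.occurrence_slope < 0:
            raise ValidationError("occurrence slope is a signal strength, must be >= 0")

    def rng(self, stream: int = 0) -> np.random.Generator:
        # independent per-stage substreams derived from the one seed
        return np.random.default_rng(np.random.SeedSequence(self.seed).spawn(stream + 1)[stream])


def _phenology_levels(
    archetype: str, sow: int | None, peak: int | None, harvest: int | None
) -> dict[int, tuple[str, ...]]:
    """Monthly height levels for one cover following its crop calendar."""
    spec = PHENOLOGY_ARCHETYPES[archetype]
    peak_cat = spec["peak_cat"]
    out: dict[int, tuple[str, ...]] = {}
    for m in MONTHS:
        if harvest is not None and m >= harvest:
            dom = 0  # post-harvest short sward / stubble
        elif sow is None:
            # no spring sowing: crop present all season (autumn-sown or
            # permanent); grows toward its peak month if it has one
            if peak is None:
                dom = peak_cat
            else:
                frac = min(1.0, max(0.0, (m - MONTHS[0]) / max(1, peak - MONTHS[0])))
                dom = max(1, round(1 + frac * (peak_cat - 1))) if peak_cat >= 1 else 0
        elif m < sow:
            dom = 0  # bare ground before sowing
        else:
            frac = min(1.0, (m - sow) / max(1, (peak or MONTHS[-1]) - sow))
            dom = round(frac * peak_cat)
        levels = [_N, _N, _N, _N]
        levels[dom] = _P
        if dom > 0:
            levels[dom - 1] = _R  # transition months mix with the class below
        elif archetype in ("fallow_like", "cutting_forage") and m in (4, 5, 6):
            levels[1] = _R  # spring flush on otherwise short swards
        out[m] = tuple(levels)
    return out


def simulate_cover_tables(
    config: SimulationConfig,
) -> tuple[HeightScoreTable, PracticeImpactTable, IntensityTable, pd.DataFrame]:
    """Generate height scores, practice flags and intensities for synthetic covers.

    Covers cycle through the phenology archetypes; practice flags are drawn
    consistently with each cover's intensity class (high-intensive covers
    carry agro-chemical plus irrigation, low-intensive at most ploughing).
    Returns the scored height table, practices, intensities and the raw
    categorical height-level frame (for scheme re-scoring).  Deterministic
    given ``config.seed``.
    """
    rng = config.rng(0)
    covers = [f"cover_{i:02d}" for i in range(config.n_cover_types)]
    archetypes = {c: _ARCHETYPE_CYCLE[i % len(_ARCHETYPE_CYCLE)] for i, c in enumerate(covers)}

    levels: dict[str, dict[int, tuple[str, ...]]] = {}
    for cover in covers:
        spec = PHENOLOGY_ARCHETYPES[archetypes[cover]]
        jitter = int(rng.integers(-1, 2))
        sow = spec["sow"] and int(np.clip(spec["sow"] + jitter, MONTHS[0], MONTHS[-1]))
        peak = spec["peak"] and int(np.clip(spec["peak"] + jitter, MONTHS[0], MONTHS[-1]))
        harvest = spec["harvest"] and int(
            np.clip(spec["harvest"] + jitter, (sow or MONTHS[0]) + 1, MONTHS[-1] + 1)
        )
        if sow is not None and peak is not None and peak <= sow:
            peak = sow + 1
        levels[cover] = _phenology_levels(archetypes[cover], sow, peak, harvest)
    level_frame = height_levels_frame(levels)

    flag_rows, yields, coarse, fallows = [], {}, {}, set()
    for cover in covers:
        tall = PHENOLOGY_ARCHETYPES[archetypes[cover]]["peak_cat"] >= 2
        if tall:  # high-intensive cropping
            coarse[cover] = 2
            yields[cover] = float(rng.uniform(5.0, 15.0))
            practice_plan = {
                "agrochemical": (("plants", "seeds", "invertebrates"), (1, 1)),
                "irrigation": (("plants", "invertebrates"), (1, 1)),
                "plough": (("plants", "seeds", "invertebrates", "vertebrates"), (0, 0)),
            }
        else:  # low-intensive: at most weed control by ploughing
            coarse[cover] = 1
            yields[cover] = float(rng.uniform(1.0, 3.0))
            ploughed = bool(rng.integers(2))
            practice_plan = {
                "agrochemical": (("plants", "seeds", "invertebrates"), (0, 0)),
                "irrigation": (("plants", "invertebrates"), (0, 0)),
                "plough": (
                    ("plants", "seeds", "invertebrates", "vertebrates"),
                    (int(ploughed), int(ploughed)),
                ),
            }
            if archetypes[cover] == "fallow_like":
                fallows.add(cover)
        for practice, (resources, (sp_flag, su_flag)) in practice_plan.items():
            for resource in resources:
                flag_rows.append((cover, "spring", practice, resource, sp_flag))
                flag_rows.append((cover, "summer", practice, resource, su_flag))

    practices = PracticeImpactTable(
        pd.DataFrame(
            flag_rows, columns=["cover_type", "period", "practice", "resource", "flag"]
        )
    )
    intensity = IntensityTable(
        yields, scaling_mode="yield", coarse_class=coarse, fallow_covers=frozenset(fallows)
    )
    scored = level_frame.copy()
    for cat in HEIGHT_CATEGORIES:
        scored[cat] = [DEFAULT_SCHEME.value(v) for v in scored[cat]]
    return HeightScoreTable(scored), practices, intensity, level_frame


def synthetic_requirements(n_species: int) -> RequirementTable:
    """Requirement archetypes for synthetic species (cycling the four study
    species' preference patterns under generic names)."""
    base = _requirement_rows()
    nesting: dict[str, frozenset[int]] = {}
    frames = []
    for i in range(n_species):
        src = SPECIES[i % len(SPECIES)]
        name = f"species_{i:02d}"
        sub = base[base["species"] == src].copy()
        sub["species"] = name
        frames.append(sub)
        if src in _NESTING_MONTHS:
            nesting[name] = _NESTING_MONTHS[src]
    return RequirementTable(pd.concat(frames, ignore_index=True), nesting)


def simulate_transects(
    config: SimulationConfig,
    series: pd.DataFrame,
    nesting_months: Mapping[str, frozenset[int]] | None = None,
) -> list[TransectRecord]:
    """Draw survey transects with presence labels linked to true suitability.

    Compositions are ``Dirichlet(alpha) * (1 - unsuitable share)`` over the
    modelled covers; for each species, presence is Bernoulli with logit
    ``intercept + slope * S`` where ``S`` is the season-integrated total
    suitability the pipeline itself assigns to the transect (the ground
    truth of the simulation).  Deterministic given ``config.seed``.
    """
    rng = config.rng(1)
    covers = list(dict.fromkeys(series["cover_type"]))
    n = config.n_transects
    unsuitable = rng.beta(*config.unsuitable_beta, size=n)
    raw = rng.dirichlet(np.full(len(covers), config.dirichlet_alpha), size=n)
    comps = raw * (1.0 - unsuitable)[:, None]
    transects = [
        TransectRecord(f"t{i:04d}", 2010, dict(zip(covers, comps[i])), {}) for i in range(n)
    ]
    integrated = integrate_transects(
        series, transects, windows=[FULL_SEASON], nesting_months=nesting_months
    )
    totals = integrated.pivot_table(
        index="transect_id", columns="species", values="total", sort=False
    ).reindex([t.transect_id for t in transects])
    labelled = []
    for i, t in enumerate(transects):
        labels = {}
        for sp in totals.columns:
            logit = config.occurrence_intercept + config.occurrence_slope * totals.iloc[i][sp]
            labels[sp] = bool(rng.random() < 1.0 / (1.0 + np.exp(-logit)))
        labelled.append(TransectRecord(t.transect_id, t.year, t.composition, labels))
    return labelled
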