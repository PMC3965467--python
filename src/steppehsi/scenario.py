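"""Landscape-scale projection of fallow-to-cereal conversion scenarios.

Fallow land (till and no-till) is the most suitable cover for the study
species; its loss to dry cereal — the agronomic scenario expected after
set-aside support removal — is modelled by moving a fraction ``p`` of each
fallow type's area into dry cereal, leaving all other covers unchanged.
Landscape suitability under each scenario reuses the transect integration
machinery with area proportions as weights; transect-level predictions are
re-classified at the thresholds frozen from baseline model validation.
Scenario outputs are only reported for species whose validation AUC meets
a robustness floor (0.6 by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .availability import MONTHS, ValidationError
from .integration import (
    FULL_SEASON,
    TimeWindow,
    TransectRecord,
    check_composition,
    integrate_transects,
    spatial_integrate,
    temporal_integrate,
    total_suitability,
)

#: Minimum validation AUC for a species' model to drive scenario output.
ROBUST_AUC = 0.6


@dataclass(frozen=True)
class ScenarioSpec:
    """Fractional conversion of fallow covers into a cereal sink."""

    conversion_fraction: float
    source_covers: tuple[str, ...] = ("till_fallow", "no_till_fallow")
    sink_cover: str = "dry_cereal"

    def __post_init__(self) -> None:
        if not 0.0 <= self.conversion_fraction <= 1.0:
            raise ValidationError(
                f"conversion fraction must be in [0, 1], got {self.conversion_fraction}"
            )


def shift_fallow(base: Mapping[str, float], spec: ScenarioSpec) -> dict[str, float]:
    """Move fraction ``p`` of each source cover's area into the sink cover.

    Each fallow type loses the same *fraction* of its own area (so a 30%
    scenario removes 30% of total fallow and neither source can go
    negative); the sink gains exactly the area removed, conserving total
    area.
    """
    for cover in (*spec.source_covers, spec.sink_cover):
        if cover not in base:
            raise ValidationError(f"scenario cover {cover!r} absent from composition")
    p = spec.conversion_fraction
    out = dict(base)
    moved = 0.0
    for cover in spec.source_covers:
        delta = out[cover] * p
        out[cover] -= delta
        moved += delta
    out[spec.sink_cover] += moved
    return out


def landscape_suitability(
    series: pd.DataFrame,
    composition: Mapping[str, float],
    species: str,
    window: TimeWindow = FULL_SEASON,
    nesting_months: frozenset[int] | None = None,
) -> dict[str, object]:
    """Season-integrated and monthly suitability of a whole landscape.

    The landscape is treated as one big transect: covers are weighted by
    their area proportions, the "other" / unsuitable share contributes 0.
    Returns ``foraging``, ``nesting`` (NaN if no nesting component),
    ``total`` and per-month trajectories.
    """
    modelled = set(series["cover_type"])
    weights = {k: v for k, v in composition.items() if k in modelled}
    check_composition(
        {**weights, "other": 1.0 - sum(weights.values())}, where="landscape composition"
    )
    monthly_f: dict[int, float] = {}
    monthly_n: dict[int, float] = {}
    for month in MONTHS:
        f, n = spatial_integrate(series, weights, species, month)
        monthly_f[month] = f
        if not np.isnan(n):
            monthly_n[month] = n
    f_int = temporal_integrate(monthly_f, window)
    if monthly_n:
        months = nesting_months if nesting_months is not None else frozenset(monthly_n)
        n_int = temporal_integrate({**dict.fromkeys(MONTHS, np.nan), **monthly_n}, window, months)
    else:
        n_int = np.nan
    return {
        "foraging": f_int,
        "nesting": n_int,
        "total": total_suitability(f_int, n_int),
        "monthly_foraging": monthly_f,
        "monthly_nesting": monthly_n,
        "monthly_total": {
            m: total_suitability(monthly_f[m], monthly_n.get(m, np.nan)) for m in MONTHS
        },
    }


def scenario_presence_fraction(
    transects: Sequence[TransectRecord],
    series: pd.DataFrame,
    spec: ScenarioSpec,
    threshold: float,
    species: str,
    window: TimeWindow = FULL_SEASON,
    nesting_months: Mapping[str, frozenset[int]] | None = None,
) -> float:
    """Fraction of transects predicted present after fallow conversion.

    Each transect's composition is shifted by the scenario, total
    suitability is recomputed, and presence is declared at the threshold
    frozen from baseline validation (``score >= threshold``).
    """
    if threshold is None or not np.isfinite(threshold):
        raise ValidationError("scenario classification requires a validation threshold")
    shifted = [
        TransectRecord(t.transect_id, t.year, shift_fallow(t.composition, spec), t.labels)
        for t in transects
    ]
    integrated = integrate_transects(
        series, shifted, windows=[window], nesting_months=nesting_months
    )
    totals = integrated.loc[integrated["species"] == species, "total"].to_numpy(dtype=float)
    return float(np.mean(totals >= threshold))


@dataclass(frozen=True)
class ScenarioConfig:
    """Base landscape composition and the conversion fractions to project."""

    base_composition: Mapping[str, float]
    fractions: tuple[float, ...] = (0.3, 0.5, 1.0)
    source_covers: tuple[str, ...] = ("till_fallow", "no_till_fallow")
    sink_cover: str = "dry_cereal"
    min_auc: float = ROBUST_AUC

    def spec(self, p: float) -> ScenarioSpec:
        return ScenarioSpec(p, self.source_covers, self.sink_cover)


def project_scenarios(
    series: pd.DataFrame,
    config: ScenarioConfig,
    validation: pd.DataFrame,
    transects: Sequence[TransectRecord] | None = None,
    window: TimeWindow = FULL_SEASON,
    nesting_months: Mapping[str, frozenset[int]] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Scenario summary and monthly trajectories for robust species.

    *validation* must hold one row per species for *window* with ``auc``
    and ``threshold`` columns; species below ``config.min_auc`` are
    filtered out.  Returns ``(summary, monthly)`` frames: the summary has
    one row per (species, fraction incl. baseline 0.0) with landscape
    foraging/nesting/total suitability, percent change of total versus
    baseline and — when *transects* are given — the fraction of transects
    predicted present at the frozen threshold.
    """
    val = validation[validation["window"] == window.label]
    robust = val[val["auc"] >= config.min_auc]
    thresholds = dict(zip(robust["species"], robust["threshold"]))
    summary_rows = []
    monthly_rows = []
    for species in robust["species"]:
        nm = (nesting_months or {}).get(species)
        base = landscape_suitability(series, config.base_composition, species, window, nm)
        for p in (0.0, *config.fractions):
            comp = shift_fallow(dict(config.base_composition), config.spec(p))
            res = landscape_suitability(series, comp, species, window, nm)
            row = {
                "species": species,
                "fraction": p,
                "foraging": res["foraging"],
                "nesting": res["nesting"],
                "total": res["total"],
                "pct_change_total": (
                    100.0 * (res["total"] - base["total"]) / base["total"]
                    if base["total"] > 0
                    else np.nan
                ),
            }
            if transects is not None:
                row["presence_fraction"] = scenario_presence_fraction(
                    transects,
                    series,
                    config.spec(p),
                    thresholds[species],
                    species,
                    window,
                    nesting_months,
                )
            summary_rows.append(row)
            for m in MONTHS:
                monthly_rows.append(
                    {
                        "species": species,
                        "fraction": p,
                        "month": m,
                        "foraging": res["monthly_foraging"][m],
                        "nesting": res["monthly_nesting"].get(m, np.nan),
                        "total": res["monthly_total"][m],
                    }
                )
    return pd.DataFrame(summary_rows), pd.DataFrame(monthly_rows)
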