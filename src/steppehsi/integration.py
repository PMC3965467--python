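"""Spatial and temporal integration of suitability estimates.

Monthly per-cover suitabilities are aggregated to the transect (or
landscape) scale as weighted averages over cover-type composition, with
unsuitable area (shrub, urban, orchards, "other") contributing suitability
0.  Monthly transect values are then averaged over a time window, and the
foraging and nesting components are combined into a single total
suitability as their geometric mean — zero whenever either component is
zero, and equal to foraging for species with no nesting component.

The default order of operations is: spatial integration per month, then
temporal averaging per activity, then the geometric mean.  A per-month
geometric mean followed by temporal averaging is available for monthly
trajectory reporting (``monthly_order=True``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .availability import MONTHS, ValidationError

COMPOSITION_TOL = 1e-9
#: Cover label holding area not usable by any modelled species.
UNSUITABLE = "unsuitable"


@dataclass(frozen=True)
class TimeWindow:
    """A set of months over which monthly suitabilities are averaged."""

    label: str
    months: frozenset[int]

    def __post_init__(self) -> None:
        if not self.months:
            raise ValidationError(f"time window {self.label!r} is empty")
        outside = set(self.months) - set(MONTHS)
        if outside:
            raise ValidationError(f"window {self.label!r} has months outside 4-9: {outside}")


FULL_SEASON = TimeWindow("full_season", frozenset(MONTHS))
#: Windows examined around the May bird surveys, plus the whole season.
STANDARD_WINDOWS: tuple[TimeWindow, ...] = (
    FULL_SEASON,
    TimeWindow("may", frozenset({5})),
    TimeWindow("apr_may", frozenset({4, 5})),
    TimeWindow("may_jun", frozenset({5, 6})),
    TimeWindow("apr_jun", frozenset({4, 5, 6})),
)


def window_by_label(label: str) -> TimeWindow:
    for w in STANDARD_WINDOWS:
        if w.label == label:
            return w
    raise ValidationError(f"unknown time window {label!r}")


@dataclass(frozen=True)
class TransectRecord:
    """Cover composition and species presence/absence of one survey transect.

    ``composition`` maps modelled cover types to their proportion of the
    *total* transect surface; any remainder up to 1 is unsuitable habitat
    and contributes zero suitability.  ``labels`` maps species to observed
    presence.
    """

    transect_id: str
    year: int
    composition: Mapping[str, float]
    labels: Mapping[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        total = float(sum(self.composition.values()))
        if any(v < -COMPOSITION_TOL for v in self.composition.values()):
            raise ValidationError(f"transect {self.transect_id!r}: negative cover proportion")
        if total > 1.0 + 1e-6:
            raise ValidationError(
                f"transect {self.transect_id!r}: cover proportions sum to {total:.6f} > 1"
            )

    @property
    def unsuitable(self) -> float:
        return max(0.0, 1.0 - float(sum(self.composition.values())))


def check_composition(composition: Mapping[str, float], *, where: str = "composition") -> None:
    """Validate a full composition (must sum to 1 within tolerance)."""
    total = float(sum(composition.values()))
    if any(v < -COMPOSITION_TOL for v in composition.values()):
        raise ValidationError(f"{where}: negative proportion")
    if abs(total - 1.0) > 1e-6:
        raise ValidationError(f"{where}: proportions sum to {total:.6f}, expected 1")


# ---------------------------------------------------------------------------
# Elementary integration steps
# ---------------------------------------------------------------------------


def spatial_integrate(
    series: pd.DataFrame,
    composition: Mapping[str, float],
    species: str,
    month: int,
) -> tuple[float, float]:
    """Composition-weighted foraging and nesting suitability for one month.

    *composition* maps modelled cover types to proportions of total surface;
    the shortfall to 1 is unsuitable area with suitability 0 for both
    activities.  The nesting value is NaN when the month is outside the
    species' nesting window.
    """
    weights = {k: v for k, v in composition.items() if k != UNSUITABLE}
    total = sum(weights.values()) + composition.get(UNSUITABLE, 0.0)
    if total > 1.0 + 1e-6:
        raise ValidationError(f"composition sums to {total:.6f} > 1")
    sub = series[(series["species"] == species) & (series["month"] == month)]
    sf = dict(zip(sub["cover_type"], sub["foraging"]))
    sn = dict(zip(sub["cover_type"], sub["nesting"]))
    missing = set(weights) - set(sf)
    if missing:
        raise ValidationError(f"no suitability series for cover types {sorted(missing)}")
    foraging = float(sum(w * sf[k] for k, w in weights.items()))
    if sub["nesting"].isna().all():
        nesting = math.nan
    else:
        nesting = float(sum(w * sn[k] for k, w in weights.items()))
    return foraging, nesting


def temporal_integrate(
    monthly: Mapping[int, float],
    window: TimeWindow,
    nesting_months: Iterable[int] | None = None,
) -> float:
    """Arithmetic mean of monthly values over a window.

    For nesting, pass the species' nesting months: only window months
    inside the nesting period enter the mean, and NaN (absent) is returned
    when the intersection is empty.
    """
    months = set(window.months)
    if nesting_months is not None:
        months &= set(nesting_months)
    if not months:
        return math.nan
    values = [monthly[m] for m in sorted(months)]
    return float(np.mean(values))


def total_suitability(foraging: float, nesting: float) -> float:
    """Geometric mean of the two components; foraging alone if nesting absent.

    Zero if either component is zero — both activities are essential for
    population viability, so neither can compensate for the other.
    """
    if nesting is None or (isinstance(nesting, float) and math.isnan(nesting)):
        return float(foraging)
    return math.sqrt(float(foraging) * float(nesting))


# ---------------------------------------------------------------------------
# Bulk transect integration
# ---------------------------------------------------------------------------


def integrate_transects(
    series: pd.DataFrame,
    transects: Sequence[TransectRecord],
    windows: Sequence[TimeWindow] = STANDARD_WINDOWS,
    nesting_months: Mapping[str, frozenset[int]] | None = None,
    monthly_order: bool = False,
) -> pd.DataFrame:
    """Integrated suitability per (transect, species, window).

    Vectorised over transects.  Returns columns ``transect_id, year,
    species, window, foraging, nesting, total``; ``nesting`` is NaN for
    species without a nesting component.  With ``monthly_order=True`` the
    geometric mean is taken per month before temporal averaging instead of
    after (trajectory-style reporting).
    """
    if not transects:
        raise ValidationError("no transects supplied")
    species_list = list(dict.fromkeys(series["species"]))
    covers = list(dict.fromkeys(series["cover_type"]))
    w = np.array(
        [[t.composition.get(k, 0.0) for k in covers] for t in transects], dtype=float
    )  # (n_transects, n_covers)

    frames = []
    for species in species_list:
        sub = series[series["species"] == species]
        sf = sub.pivot(index="cover_type", columns="month", values="foraging")
        sf = sf.reindex(index=covers, columns=list(MONTHS))
        if sf.isna().any().any():
            raise ValidationError(f"incomplete suitability series for {species!r}")
        ft = w @ sf.to_numpy()  # (n_transects, n_months)
        sn = (
            sub.pivot(index="cover_type", columns="month", values="nesting")
            .reindex(index=covers, columns=list(MONTHS))
            .to_numpy()
        )
        if nesting_months is not None:
            nest_months = sorted(nesting_months.get(species) or ())
        else:
            nest_months = [m for j, m in enumerate(MONTHS) if not np.isnan(sn[:, j]).all()]
        nt = w @ np.nan_to_num(sn) if nest_months else None

        if monthly_order:
            tot = np.array(ft)  # per-month totals default to foraging
            if nest_months:
                for j, m in enumerate(MONTHS):
                    if m in nest_months:
                        tot[:, j] = np.sqrt(ft[:, j] * nt[:, j])
        month_index = {m: j for j, m in enumerate(MONTHS)}
        for window in windows:
            cols = [month_index[m] for m in sorted(window.months)]
            f_int = ft[:, cols].mean(axis=1)
            n_cols = [month_index[m] for m in sorted(set(window.months) & set(nest_months))]
            n_int = nt[:, n_cols].mean(axis=1) if (nest_months and n_cols) else None
            if monthly_order:
                total = tot[:, cols].mean(axis=1)
            elif n_int is not None:
                total = np.sqrt(f_int * n_int)
            else:
                total = f_int
            frames.append(
                pd.DataFrame(
                    {
                        "transect_id": [t.transect_id for t in transects],
                        "year": [t.year for t in transects],
                        "species": species,
                        "window": window.label,
                        "foraging": f_int,
                        "nesting": n_int if n_int is not None else np.nan,
                        "total": total,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)
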