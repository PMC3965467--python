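"""Validation against presence/absence surveys and sensitivity analysis.

Predicted transect suitabilities are compared with observed species
presence/absence through threshold-independent discrimination (AUC) and
through a confusion table at the threshold maximising sensitivity +
specificity (a Youden-type optimal operating point).  The sensitivity
analysis re-runs the whole suitability pipeline under alternative scoring
schemes and intensity scalings and reports, per alternative: the signed
percentage change of the mean suitability index, the Pearson correlation
with baseline transect suitabilities, and the percentage of transects
whose predicted presence/absence flips.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

from .availability import (
    AvailabilityBundle,
    HeightScoreTable,
    IntensityTable,
    PracticeImpactTable,
    ValidationError,
    compute_food_availability,
    normalize_height_scores,
)
from .integration import (
    FULL_SEASON,
    STANDARD_WINDOWS,
    TimeWindow,
    TransectRecord,
    integrate_transects,
)
from .resource_model import (
    ALTERNATIVE_SCHEMES,
    DEFAULT_SCHEME,
    RequirementTable,
    ScoringScheme,
    build_suitability_series,
    score_height_levels,
)


class UndefinedMetricError(ValueError):
    """A discrimination metric is undefined (e.g. single-class labels)."""


def _as_arrays(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if s.shape != y.shape or s.ndim != 1:
        raise ValidationError("scores and labels must be 1-D and equal length")
    if s.size == 0:
        raise ValidationError("empty scores/labels")
    return s, y


def auc(scores, labels) -> float:
    """Probability that a random presence outscores a random absence (ties ½)."""
    s, y = _as_arrays(scores, labels)
    if y.all() or not y.any():
        raise UndefinedMetricError("AUC undefined: labels contain a single class")
    return float(roc_auc_score(y, s))


def classification_metrics(scores, labels, threshold: float) -> tuple[float, float, float]:
    """(success %, sensitivity %, specificity %) at rule ``score >= threshold``."""
    s, y = _as_arrays(scores, labels)
    if not np.isfinite(threshold):
        raise ValidationError(f"threshold must be finite, got {threshold}")
    pred = s >= threshold
    success = float(np.mean(pred == y)) * 100.0
    sens = float(np.mean(pred[y])) * 100.0 if y.any() else np.nan
    spec = float(np.mean(~pred[~y])) * 100.0 if (~y).any() else np.nan
    return success, sens, spec


def optimal_threshold(scores, labels) -> float:
    """Observed score maximising sensitivity + specificity (rule ``>=``).

    Candidates are the unique observed scores; ties in the objective are
    broken toward the lowest threshold, favouring sensitivity.
    """
    s, y = _as_arrays(scores, labels)
    if y.all() or not y.any():
        raise UndefinedMetricError("optimal threshold undefined: single-class labels")
    best_t, best_obj = None, -np.inf
    for t in np.unique(s):  # ascending, so ties keep the lowest threshold
        pred = s >= t
        obj = np.mean(pred[y]) + np.mean(~pred[~y])
        if obj > best_obj + 1e-12:
            best_obj, best_t = obj, float(t)
    return best_t


# ---------------------------------------------------------------------------
# Transect de-duplication and validation reports
# ---------------------------------------------------------------------------


def deduplicate_transects(
    transects: Sequence[TransectRecord], seed: int
) -> list[TransectRecord]:
    """One record per transect id, chosen by a seeded random draw.

    Transects surveyed in both years would otherwise be pseudo-replicated in
    validation; suitability computation keeps all records.
    """
    rng = np.random.default_rng(seed)
    by_id: dict[str, list[TransectRecord]] = {}
    for t in transects:
        by_id.setdefault(t.transect_id, []).append(t)
    return [group[rng.integers(len(group))] for group in by_id.values()]


@dataclass(frozen=True)
class ValidationReport:
    """Discrimination and confusion-table metrics for one species/window."""

    species: str
    window: str
    auc: float
    threshold: float
    success_pct: float
    sensitivity_pct: float
    specificity_pct: float
    n_transects: int


def validate_predictions(
    transect_suitability: pd.DataFrame,
    transects: Sequence[TransectRecord],
    windows: Sequence[TimeWindow] = STANDARD_WINDOWS,
) -> pd.DataFrame:
    """Validation report per (species, window) from integrated suitabilities.

    *transect_suitability* is the output of
    :func:`steppehsi.integration.integrate_transects` computed on
    de-duplicated transects; labels are taken from the transect records.
    """
    labels_by_key = {(t.transect_id, t.year): t.labels for t in transects}
    rows = []
    for (species, window), sub in transect_suitability.groupby(["species", "window"], sort=False):
        if window not in {w.label for w in windows}:
            continue
        keys = list(zip(sub["transect_id"], sub["year"]))
        mask = [species in labels_by_key.get(k, {}) for k in keys]
        sub = sub[mask]
        y = np.array(
            [labels_by_key[k][species] for k in zip(sub["transect_id"], sub["year"])], dtype=bool
        )
        s = sub["total"].to_numpy(dtype=float)
        t = optimal_threshold(s, y)
        success, sens, spec = classification_metrics(s, y, t)
        rows.append(
            ValidationReport(
                species=species,
                window=window,
                auc=auc(s, y),
                threshold=t,
                success_pct=success,
                sensitivity_pct=sens,
                specificity_pct=spec,
                n_transects=len(sub),
            )
        )
    return pd.DataFrame([r.__dict__ for r in rows])


# ---------------------------------------------------------------------------
# End-to-end scoring and sensitivity analysis
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PipelineVariant:
    """One parameterisation of the suitability pipeline."""

    height_scheme: ScoringScheme = DEFAULT_SCHEME
    diet_scheme: ScoringScheme = DEFAULT_SCHEME
    scaling_mode: str = "yield"
    label: str = "baseline"


def compute_transect_scores(
    practices: PracticeImpactTable,
    intensity: IntensityTable,
    height_levels: pd.DataFrame,
    requirements: RequirementTable,
    transects: Sequence[TransectRecord],
    variant: PipelineVariant = PipelineVariant(),
    window: TimeWindow = FULL_SEASON,
) -> pd.DataFrame:
    """Run availability → suitability → integration for one parameterisation.

    Returns total suitability per (transect, species) for *window*, in
    transect order, one column per species.
    """
    bundle = AvailabilityBundle(
        food=compute_food_availability(practices, intensity.with_mode(variant.scaling_mode)),
        height=normalize_height_scores(score_height_levels(height_levels, variant.height_scheme)),
    )
    series = build_suitability_series(requirements, bundle, diet_scheme=variant.diet_scheme)
    integrated = integrate_transects(
        series, transects, windows=[window], nesting_months=requirements.nesting_months
    )
    wide = integrated.pivot_table(
        index=["transect_id", "year"], columns="species", values="total", sort=False
    )
    order = pd.MultiIndex.from_tuples([(t.transect_id, t.year) for t in transects])
    return wide.reindex(order)


#: Alternatives examined by default: three schemes per scoring family and
#: two intensity re-scalings.
def default_alternatives() -> list[PipelineVariant]:
    alts = []
    for scheme in ALTERNATIVE_SCHEMES:
        alts.append(PipelineVariant(height_scheme=scheme, label=f"vegetation_height:{scheme.label}"))
    for scheme in ALTERNATIVE_SCHEMES:
        alts.append(PipelineVariant(diet_scheme=scheme, label=f"diet_preferences:{scheme.label}"))
    alts.append(PipelineVariant(scaling_mode="unit", label="intensification:unit"))
    alts.append(PipelineVariant(scaling_mode="coarse", label="intensification:coarse"))
    return alts


def sensitivity_analysis(
    practices: PracticeImpactTable,
    intensity: IntensityTable,
    height_levels: pd.DataFrame,
    requirements: RequirementTable,
    transects: Sequence[TransectRecord],
    baseline: PipelineVariant = PipelineVariant(),
    alternatives: Sequence[PipelineVariant] | None = None,
    window: TimeWindow = FULL_SEASON,
    refit_threshold: bool = True,
) -> pd.DataFrame:
    """Robustness of transect predictions to the scoring parameterisation.

    For each alternative parameterisation and species, reports the signed %
    change of the mean transect suitability, the Pearson r with baseline
    suitabilities (NaN with a warning state when a run is constant), and
    the % of transects whose presence/absence classification flips.  With
    ``refit_threshold`` each run is classified at its own re-derived optimal
    threshold (making the metric invariant to monotone transforms of the
    scores); otherwise the baseline threshold is reused.
    """
    if alternatives is None:
        alternatives = default_alternatives()
    base_scores = compute_transect_scores(
        practices, intensity, height_levels, requirements, transects, baseline, window
    )
    labels = {
        sp: np.array([bool(t.labels[sp]) for t in transects], dtype=bool)
        for sp in base_scores.columns
        if all(sp in t.labels for t in transects)
    }
    rows = []
    for variant in alternatives:
        alt_scores = compute_transect_scores(
            practices, intensity, height_levels, requirements, transects, variant, window
        )
        family, _, scheme_label = variant.label.partition(":")
        for sp in base_scores.columns:
            b = base_scores[sp].to_numpy(dtype=float)
            a = alt_scores[sp].to_numpy(dtype=float)
            index_change = (
                100.0 * (a.mean() - b.mean()) / b.mean() if b.mean() > 0 else np.nan
            )
            if np.std(a) == 0 or np.std(b) == 0:
                r = np.nan  # degenerate variance: correlation undefined
            else:
                r = float(stats.pearsonr(b, a).statistic)
            if sp in labels:
                y = labels[sp]
                t_base = optimal_threshold(b, y)
                t_alt = optimal_threshold(a, y) if refit_threshold else t_base
                flips = float(np.mean((b >= t_base) != (a >= t_alt))) * 100.0
            else:
                flips = np.nan
            rows.append(
                {
                    "family": family,
                    "scheme": scheme_label,
                    "species": sp,
                    "index_change_pct": index_change,
                    "pearson_r": r,
                    "prediction_change_pct": flips,
                }
            )
    return pd.DataFrame(rows)
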