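"""Discrimination metrics, optimal thresholds and the sensitivity analysis."""

import numpy as np
import pandas as pd
import pytest

import steppehsi as sh
from steppehsi.evaluation import (
    PipelineVariant,
    UndefinedMetricError,
    auc,
    classification_metrics,
    deduplicate_transects,
    optimal_threshold,
    sensitivity_analysis,
)
from steppehsi.integration import TransectRecord
from steppehsi.resource_model import ScoringScheme


def brute_force_auc(scores, labels):
    """All-pairs concordance count, ties counted half."""
    pos = [s for s, y in zip(scores, labels) if y]
    neg = [s for s, y in zip(scores, labels) if not y]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


@pytest.mark.parametrize(
    "scores, labels, expected",
    [
        ((0.9, 0.8, 0.2, 0.1), (1, 1, 0, 0), 1.0),
        ((0.9, 0.5, 0.3, 0.4), (1, 0, 1, 0), 0.5),
        ((0.9, 0.1, 0.8, 0.4), (1, 0, 1, 0), 1.0),
    ],
)
def test_auc_examples(scores, labels, expected):
    assert auc(scores, labels) == pytest.approx(expected)


def test_auc_agrees_with_all_pairs_counting():
    rng = np.random.default_rng(3)
    for _ in range(50):
        n = int(rng.integers(4, 50))
        scores = rng.choice(np.linspace(0, 1, 11), size=n)  # many ties
        labels = rng.integers(0, 2, size=n).astype(bool)
        if labels.all() or not labels.any():
            continue
        assert auc(scores, labels) == pytest.approx(brute_force_auc(scores, labels))


def test_single_class_labels_undefined():
    with pytest.raises(UndefinedMetricError):
        auc((0.1, 0.9), (1, 1))
    with pytest.raises(UndefinedMetricError):
        optimal_threshold((0.1, 0.9), (0, 0))


def test_optimal_threshold_examples():
    # perfectly separated: smallest threshold achieving sens + spec = 2
    assert optimal_threshold((0.9, 0.8, 0.2, 0.1), (1, 1, 0, 0)) == pytest.approx(0.8)
    # tie between thresholds 0.6 (sens 1, spec .5) and 0.8 (sens .5, spec 1):
    # broken toward the lowest, favouring sensitivity
    assert optimal_threshold((0.8, 0.6, 0.6, 0.2), (1, 1, 0, 0)) == pytest.approx(0.6)
    # degenerate: all scores equal -> that value (sens 1, spec 0)
    assert optimal_threshold((0.4, 0.4, 0.4), (1, 0, 1)) == pytest.approx(0.4)


def test_optimal_threshold_exhaustive_over_observed_scores():
    rng = np.random.default_rng(5)
    for _ in range(50):
        n = int(rng.integers(4, 40))
        scores = rng.choice(np.linspace(0, 1, 7), size=n)
        labels = rng.integers(0, 2, size=n).astype(bool)
        if labels.all() or not labels.any():
            continue
        t = optimal_threshold(scores, labels)
        _, sens, spec = classification_metrics(scores, labels, t)
        best = sens + spec
        for cand in np.unique(scores):
            _, s, p = classification_metrics(scores, labels, cand)
            assert best >= s + p - 1e-9


def test_classification_metrics_confusion_table():
    # threshold at the minimum score: everything predicted present
    success, sens, spec = classification_metrics((0.9, 0.5, 0.3, 0.4), (1, 0, 1, 0), 0.3)
    assert (success, sens, spec) == (pytest.approx(50.0), pytest.approx(100.0), pytest.approx(0.0))
    # threshold separating one false positive
    success, sens, spec = classification_metrics((0.9, 0.5, 0.2, 0.4), (1, 0, 1, 0), 0.4)
    assert (success, sens, spec) == (pytest.approx(25.0), pytest.approx(50.0), pytest.approx(0.0))
    # threshold above the maximum score: everything predicted absent
    _, sens, spec = classification_metrics((0.9, 0.5, 0.3, 0.4), (1, 0, 1, 0), 2.0)
    assert sens == 0.0 and spec == 100.0
    success, *_ = classification_metrics((0.9, 0.1), (1, 0), 0.5)
    assert success == 100.0


def test_threshold_classification_invariant_to_monotone_transforms():
    """Re-deriving the optimal threshold after any strictly increasing
    transform of the scores leaves every classification unchanged."""
    rng = np.random.default_rng(9)
    transforms = [np.square, np.sqrt, lambda s: 1 / (1 + np.exp(-5 * s))]
    for _ in range(30):
        n = int(rng.integers(5, 60))
        scores = rng.random(n)
        labels = rng.integers(0, 2, size=n).astype(bool)
        if labels.all() or not labels.any():
            continue
        base_pred = scores >= optimal_threshold(scores, labels)
        for g in transforms:
            t = optimal_threshold(g(scores), labels)
            assert ((g(scores) >= t) == base_pred).all()


def test_deduplication_keeps_one_seeded_record_per_transect():
    records = [
        TransectRecord("a", 2010, {}, {"sp": True}),
        TransectRecord("a", 2011, {}, {"sp": False}),
        TransectRecord("b", 2010, {}, {"sp": True}),
    ]
    out = deduplicate_transects(records, seed=4)
    assert sorted(t.transect_id for t in out) == ["a", "b"]
    again = deduplicate_transects(records, seed=4)
    assert [t.year for t in out] == [t.year for t in again]


def test_sensitivity_identity_alternative_is_neutral(study, series):
    rng = np.random.default_rng(21)
    covers = list(series["cover_type"].unique())
    transects = []
    for i in range(25):
        w = rng.dirichlet(np.ones(len(covers))) * (1 - rng.uniform(0, 0.3))
        labels = {sp: bool(rng.integers(2)) for sp in study.species}
        transects.append(TransectRecord(f"t{i}", 2010, dict(zip(covers, w)), labels))
    out = sensitivity_analysis(
        study.practices,
        study.intensity,
        study.height_levels,
        study.requirements,
        transects,
        alternatives=[PipelineVariant(label="identity:baseline")],
    )
    assert np.allclose(out["index_change_pct"], 0.0, atol=1e-9)
    assert np.allclose(out["pearson_r"], 1.0, atol=1e-9)
    assert np.allclose(out["prediction_change_pct"], 0.0)


def test_strict_diet_scheme_shrinks_mean_index(study, series):
    """All study species have 'rare' diet entries, so scoring rare as 0
    strictly lowers mean transect suitability."""
    rng = np.random.default_rng(22)
    covers = list(series["cover_type"].unique())
    transects = [
        TransectRecord(
            f"t{i}", 2010,
            dict(zip(covers, rng.dirichlet(np.ones(len(covers))) * 0.9)),
            {sp: bool(rng.integers(2)) for sp in study.species},
        )
        for i in range(20)
    ]
    out = sensitivity_analysis(
        study.practices,
        study.intensity,
        study.height_levels,
        study.requirements,
        transects,
        alternatives=[
            PipelineVariant(diet_scheme=ScoringScheme(0, 0, 1, label="0/0/1"),
                            label="diet_preferences:0/0/1")
        ],
    )
    assert (out["index_change_pct"] < 0).all()
    assert out["family"].unique().tolist() == ["diet_preferences"]
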