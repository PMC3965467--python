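"""Synthetic cover/transect generators and the packaged study fixture."""

import numpy as np
import pandas as pd
import pytest

import steppehsi as sh
from steppehsi.availability import ValidationError
from steppehsi.synthetic_data import (
    PHENOLOGY_ARCHETYPES,
    SimulationConfig,
    packaged_study_fixture,
    simulate_cover_tables,
    simulate_transects,
    synthetic_requirements,
)

# Printed expected food availabilities (4 resources x 6 covers x 2 periods).
PRINTED_AVAILABILITY = {
    # cover: {resource: (spring, summer)}
    "no_till_fallow": {"seeds": (0.5, 1.0), "plants": (0.5, 1.0),
                       "invertebrates": (0.5, 1.0), "vertebrates": (1.0, 1.0)},
    "till_fallow": {"seeds": (0.5, 0.5), "plants": (0.5, 0.5),
                    "invertebrates": (0.5, 0.5), "vertebrates": (0.5, 0.5)},
    "dry_cereal": {"seeds": (0.33, 0.2), "plants": (0.33, 0.2),
                   "invertebrates": (0.33, 0.2), "vertebrates": (1.0, 0.33)},
    "irrigated_cereal": {"seeds": (0.12, 0.07), "plants": (0.07, 0.07),
                         "invertebrates": (0.07, 0.07), "vertebrates": (1.0, 0.12)},
    "alfalfa": {"seeds": (0.07, 0.07), "plants": (1.0, 1.0),
                "invertebrates": (0.03, 0.03), "vertebrates": (1.0, 1.0)},
    "maize": {"seeds": (0.08, 0.08), "plants": (0.04, 0.04),
              "invertebrates": (0.04, 0.04), "vertebrates": (1.0, 1.0)},
}


def test_fixture_shape_and_landscape(study):
    assert len(study.species) == 4
    assert len(study.cover_types) == 6
    assert sum(study.landscape.values()) == pytest.approx(1.0)
    assert study.landscape["dry_cereal"] == 0.71
    assert study.landscape["other"] == pytest.approx(0.05)
    assert study.metadata["height_profiles"] == "reconstructed"


def test_fixture_reproduces_printed_availability_cells(study):
    food = sh.compute_food_availability(study.practices, study.intensity).set_index(
        ["cover_type", "period"]
    )
    for cover, resources in PRINTED_AVAILABILITY.items():
        for resource, (spring, summer) in resources.items():
            assert round(food.loc[(cover, "spring"), resource], 2) == pytest.approx(spring)
            assert round(food.loc[(cover, "summer"), resource], 2) == pytest.approx(summer)


def test_fixture_requirement_vectors(study):
    req = study.requirements
    np.testing.assert_allclose(
        req.vector("calandra_lark", "foraging", "spring", "food", sh.DEFAULT_SCHEME),
        [1.0, 0.5, 1.0, 0.0],
    )
    np.testing.assert_allclose(
        req.vector("stone_curlew", "nesting", "all", "height", sh.ScoringScheme(0, 0, 1)),
        [1.0, 0.0, 0.0, 0.0],
    )
    assert not req.nests("little_bustard")
    assert req.nests("stone_curlew", 7) and not req.nests("stone_curlew", 8)


def test_simulated_tables_deterministic():
    a = simulate_cover_tables(SimulationConfig(seed=13))
    b = simulate_cover_tables(SimulationConfig(seed=13))
    pd.testing.assert_frame_equal(a[0].scores, b[0].scores)
    pd.testing.assert_frame_equal(a[1].flags, b[1].flags)
    assert a[2].yields_t_ha == b[2].yields_t_ha
    c = simulate_cover_tables(SimulationConfig(seed=14))
    assert not a[0].scores.equals(c[0].scores)


def test_simulated_phenology_contracts():
    height, practices, intensity, levels = simulate_cover_tables(SimulationConfig(seed=3))
    archetypes = list(PHENOLOGY_ARCHETYPES)
    covers = list(dict.fromkeys(levels["cover_type"]))
    for i, cover in enumerate(covers):
        arch = archetypes[i % len(archetypes)]
        sub = levels[levels["cover_type"] == cover]
        if arch == "fallow_like":
            # short sward dominates most of the season
            assert (sub["h0_25"] == "preferred").sum() >= 4
        if arch == "tall_cereal":
            assert (sub["h100p"] == "preferred").any()  # usual at peak
    # scores always admit normalisation (no all-zero month)
    normalized = sh.normalize_height_scores(height)
    assert np.allclose(
        normalized[["h0_25", "h25_50", "h50_100", "h100p"]].sum(axis=1), 1.0
    )


def test_simulated_practices_match_intensity_class():
    _, practices, intensity, _ = simulate_cover_tables(SimulationConfig(seed=3))
    for cover in practices.cover_types:
        n_practices = practices.flags[
            (practices.flags["cover_type"] == cover) & (practices.flags["flag"] == 1)
        ]["practice"].nunique()
        if intensity.coarse_class[cover] == 2:
            assert n_practices >= 2
        else:
            assert n_practices <= 1


def test_simulated_transects_compositions_and_determinism(simulated):
    transects = simulated["transects"]
    assert len(transects) == simulated["config"].n_transects
    for t in transects:
        assert sum(t.composition.values()) <= 1 + 1e-9
        assert min(t.composition.values()) >= 0
        assert set(t.labels) == set(simulated["requirements"].species)
    again = simulate_transects(
        simulated["config"], simulated["series"], simulated["requirements"].nesting_months
    )
    assert [t.labels for t in again] == [t.labels for t in transects]
    np.testing.assert_allclose(
        [list(t.composition.values()) for t in again],
        [list(t.composition.values()) for t in transects],
    )


def test_null_link_prevalence_matches_intercept():
    """With slope 0 the label probability is logistic(intercept) everywhere."""
    cfg = SimulationConfig(n_transects=400, occurrence_slope=0.0,
                           occurrence_intercept=0.0, seed=5)
    height, practices, intensity, _ = simulate_cover_tables(cfg)
    req = synthetic_requirements(2)
    b = sh.build_availability(practices, intensity, height)
    series = sh.build_suitability_series(req, b)
    transects = simulate_transects(cfg, series, req.nesting_months)
    prevalence = np.mean([t.labels["species_00"] for t in transects])
    assert prevalence == pytest.approx(0.5, abs=0.08)


def test_config_validation():
    with pytest.raises(ValidationError):
        SimulationConfig(n_transects=0)
    with pytest.raises(ValidationError):
        SimulationConfig(occurrence_slope=-1.0)
    with pytest.raises(ValidationError):
        SimulationConfig(dirichlet_alpha=0.0)
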