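import pytest

import steppehsi as sh
from steppehsi.resource_model import DEFAULT_SCHEME


@pytest.fixture(scope="session")
def study():
    return sh.packaged_study_fixture()


@pytest.fixture(scope="session")
def bundle(study):
    return sh.build_availability(
        study.practices,
        study.intensity,
        sh.score_height_levels(study.height_levels, DEFAULT_SCHEME),
    )


@pytest.fixture(scope="session")
def series(study, bundle):
    return sh.build_suitability_series(study.requirements, bundle)


@pytest.fixture(scope="session")
def simulated():
    """A small synthetic study: covers, species, series and labelled transects."""
    cfg = sh.SimulationConfig(n_transects=80, seed=7)
    height, practices, intensity, levels = sh.simulate_cover_tables(cfg)
    requirements = sh.synthetic_requirements(cfg.n_species)
    b = sh.build_availability(practices, intensity, height)
    ser = sh.build_suitability_series(requirements, b)
    transects = sh.simulate_transects(cfg, ser, requirements.nesting_months)
    return {
        "config": cfg,
        "height": height,
        "levels": levels,
        "practices": practices,
        "intensity": intensity,
        "requirements": requirements,
        "bundle": b,
        "series": ser,
        "transects": transects,
    }
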