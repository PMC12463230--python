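import pytest

from hetile.config import RunConfig
from hetile.pipeline import build_cohort, tile_cohort, trait_scheme

PLANTED_TRAIT = {"name": "Ki67", "kind": "continuous",
                 "signal_strength": 1.0, "noise_sd": 0.05}


@pytest.fixture(scope="session")
def planted_config():
    """42-slide cohort with a strongly planted density signal for Ki67."""
    return RunConfig(n_patients=14, master_seed=1, clf_epochs=10,
                     traits=[dict(PLANTED_TRAIT)])


@pytest.fixture(scope="session")
def planted_cohort(planted_config):
    return build_cohort(planted_config)


@pytest.fixture(scope="session")
def planted_tiles(planted_config, planted_cohort):
    records, _ = planted_cohort
    return tile_cohort(records, planted_config)


@pytest.fixture(scope="session")
def ki67_scheme(planted_config, planted_cohort):
    _, table = planted_cohort
    return trait_scheme(table, "Ki67", "continuous", planted_config)
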