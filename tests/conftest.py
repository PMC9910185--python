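import pytest

from eelid import (
    classify_manifest,
    default_config,
    make_reference_panel,
    retail_survey_fixture,
)
from eelid.simulate import AssayTruthConfig


@pytest.fixture(scope="session")
def cfg():
    return default_config()


@pytest.fixture(scope="session")
def panel(cfg):
    return make_reference_panel(AssayTruthConfig.default(seed=1234), cfg)


@pytest.fixture(scope="session")
def manifest():
    """The bundled 137-sample retail survey, classified."""
    return classify_manifest(retail_survey_fixture())


@pytest.fixture
def hinfi(cfg):
    return cfg.enzymes["HinfI"]


@pytest.fixture
def paui(cfg):
    return cfg.enzymes["PauI"]
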