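import numpy as np
import pytest

from nbpanel.actionability import load_rules
from nbpanel.panel_io import PipelineConfig, default_panel
from nbpanel.variant_filter import (
    annotation_lookup,
    load_default_annotation,
    load_default_resources,
)


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def resources():
    return load_default_resources()


@pytest.fixture(scope="session")
def annotation():
    return load_default_annotation()


@pytest.fixture(scope="session")
def annotation_map(annotation):
    return annotation_lookup(annotation)


@pytest.fixture(scope="session")
def rules():
    return load_rules()


@pytest.fixture(scope="session")
def config():
    return PipelineConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
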