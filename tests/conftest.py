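import numpy as np
import pytest

from pumpscribe import PipelineConfig, TemplateOcrEngine
from pumpscribe.synthetic import render_suite


@pytest.fixture(scope="session")
def config() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def engine() -> TemplateOcrEngine:
    return TemplateOcrEngine()


@pytest.fixture(scope="session")
def clean_suite():
    """Shared 50-frame clean synthetic suite (seeded)."""
    return render_suite(50, seed=20, difficulty="clean")


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(99)
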