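import pytest

from panelcnv import build_counsyl36
from panelcnv.config import PipelineConfig


@pytest.fixture(scope="session")
def panel():
    return build_counsyl36()


@pytest.fixture()
def config():
    return PipelineConfig()
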