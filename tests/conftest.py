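import pytest

from levercage import DEFAULT_CONFIG


@pytest.fixture
def config():
    return DEFAULT_CONFIG
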