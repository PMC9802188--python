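import pytest

from cfpscan import default_marker_sets, load_catalog


@pytest.fixture(scope="session")
def catalog():
    return load_catalog()


@pytest.fixture(scope="session")
def markers():
    return default_marker_sets()
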