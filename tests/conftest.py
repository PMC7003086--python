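import pytest

from splitdrive.genetics import load_default_registry


@pytest.fixture(scope="session")
def registry():
    reg, _ = load_default_registry()
    return reg


@pytest.fixture(scope="session")
def observed():
    _, obs = load_default_registry()
    return obs
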