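import pytest

from hexamask.duplex_space import enumerate_duplexes
from hexamask.synthetic_data import load_fixtures


@pytest.fixture(scope="session")
def hexamer_duplexes():
    """The full 2080-element double-stranded hexamer space."""
    return enumerate_duplexes(6)


@pytest.fixture(scope="session")
def fixtures():
    """Packaged reference tables (per-mask summaries + occurrence counts)."""
    return load_fixtures()
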