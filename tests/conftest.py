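import pytest

from ivoryid import build_reference_panel


@pytest.fixture(scope="session")
def panel():
    """Default reference panel (115 comparable sites)."""
    return build_reference_panel()


@pytest.fixture(scope="session")
def panel_full():
    """Panel with a fully concrete 116-site background."""
    return build_reference_panel(excluded_site=None)
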