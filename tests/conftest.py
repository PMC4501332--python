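import pytest

from sterolflux.isotopes import FragmentFormula
from sterolflux.registry import default_registry


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def c30():
    """Lanosterol fragment ion (carbon skeleton)."""
    return FragmentFormula(30, 49, 0)


@pytest.fixture(scope="session")
def c27():
    """Cholesterol-class fragment ion (carbon skeleton)."""
    return FragmentFormula(27, 43, 0)
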