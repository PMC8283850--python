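import pytest

from vesselbench.errors import build_error_catalogue
from vesselbench.phantom import generate_phantom
from vesselbench.simulator import generate_variation_set


@pytest.fixture(scope="session")
def gt():
    """Default 96^3 phantom, shared across the suite (realised masks are cached on it)."""
    return generate_phantom(1)


@pytest.fixture(scope="session")
def catalogue(gt):
    return build_error_catalogue(gt)


@pytest.fixture(scope="session")
def catalogue_by_id(catalogue):
    return {d.error_id: d for d in catalogue}


@pytest.fixture(scope="session")
def variation_set(catalogue):
    """One default-constraint variation set for the session phantom."""
    return generate_variation_set(catalogue, seed=1)
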