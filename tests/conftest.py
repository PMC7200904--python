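import pytest

from feedval import load_reference_diets, load_reference_ingredients
from feedval.simulate import NO_NOISE, default_scenario


@pytest.fixture(scope="session")
def ingredients():
    """Packaged as-fed composition table (FW, SMW, FVW, corn)."""
    return load_reference_ingredients()


@pytest.fixture(scope="session")
def diets():
    """Packaged diet formulations of the three trials."""
    return load_reference_diets()


@pytest.fixture(scope="session")
def clean_scenario():
    """Default three-trial scenario with all assay noise switched off."""
    return default_scenario(seed=7, noise=NO_NOISE)
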