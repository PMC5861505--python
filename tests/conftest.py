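import pytest

from dcaflux import toy_model
from dcaflux.fba import ConditionConstraints
from dcaflux.toys import TOY_MANIFEST

MAX_DDDA = TOY_MANIFEST.optima["max_ddda_glc10"]  # 120/47
MAX_DDDA_LEU = TOY_MANIFEST.optima["max_ddda_glc10_leu"]  # 150/47
MAX_DDDA_SWAP = TOY_MANIFEST.optima["max_ddda_glc10_swap"]  # 120/41
MAX_GROWTH = TOY_MANIFEST.optima["max_growth_glc10"]  # 2.0


@pytest.fixture
def toy():
    """A fresh toy network per test (mutations stay local)."""
    return toy_model()


@pytest.fixture
def glc10():
    """Glucose uptake limited to 10 mmol/gDCW/h."""
    return ConditionConstraints(
        exchange_bounds={"EX_glc": (-10.0, 0.0)}, biomass_id="BIOMASS"
    )


@pytest.fixture
def glc10_fixed():
    """Glucose uptake fixed at exactly 10 mmol/gDCW/h."""
    return ConditionConstraints(
        exchange_bounds={"EX_glc": (-10.0, -10.0)}, biomass_id="BIOMASS"
    )
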