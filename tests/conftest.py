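import pytest

from netreturn import EconomicParams, ReplacementModel, SyntheticConfig, generate


@pytest.fixture
def econ():
    """2012 study defaults: $5.05/kg, 1.3 g, 1268 nuts/tree, 250 trees/ha."""
    return EconomicParams()


@pytest.fixture
def handpole_5min():
    return ReplacementModel.handpole(minutes_per_tree=5.0)


@pytest.fixture
def mechanical():
    return ReplacementModel.mechanical()


@pytest.fixture
def default_records():
    """One seeded two-phase experiment at the default study conditions."""
    return generate(SyntheticConfig(seed=0))
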