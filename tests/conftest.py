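import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from nnmelt.fixtures import FixtureSpec, make_fixture_set
from nnmelt.paramstore import ParameterSet, ThermoResult, key


@pytest.fixture(scope="session")
def uniform_set() -> ParameterSet:
    """Fixture set valuing every entry at (-8000, -22)."""
    return make_fixture_set(FixtureSpec(
        defects=("single_mismatch", "tandem_mismatch", "internal_loop",
                 "single_bulge", "long_bulge", "modified",
                 "modified_mismatch"),
        dangling="polyA"))


@pytest.fixture()
def tiny_neighbor_set() -> ParameterSet:
    """Hand-written two-stack store used by the worked examples."""
    pset = ParameterSet(id="tiny", hybridization_scope="dnadna",
                        metadata={"initiation-rule": "per_terminal"})
    pset.entries[key("neighbor", sequence="AA/TT")] = ThermoResult(-7900, -22.2)
    pset.entries[key("neighbor", sequence="AT/TA")] = ThermoResult(-7200, -20.4)
    pset.entries[key("initiation", type="per_AT")] = ThermoResult(2300, 4.1)
    pset.entries[key("initiation", type="per_GC")] = ThermoResult(100, -2.8)
    pset.entries[key("symmetry")] = ThermoResult(0.0, -1.4)
    return pset
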