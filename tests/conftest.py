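import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles helper

from isoformid.formula import parse_formula  # noqa: E402


@pytest.fixture(scope="session")
def parent():
    """Neutral 3-MeO-PCP."""
    return parse_formula("C18H27NO")


@pytest.fixture(scope="session")
def urine_scenario():
    """Reference-panel urine peak table at study conditions, fixed seed."""
    from isoformid.simulate import simulate_urine_table
    return simulate_urine_table(seed=1)
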