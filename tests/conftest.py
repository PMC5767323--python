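import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from itclink import LinkageParameters, get_preset


@pytest.fixture
def mit9313_truth() -> LinkageParameters:
    """Fitted constants for the highest-affinity strain (wild-type promoter)."""
    return get_preset("MIT9313").truth


@pytest.fixture
def wild_type_presets():
    return [get_preset(n) for n in ("MIT9313", "SS120", "MED4")]
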