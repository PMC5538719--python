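import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from braingraph.atlas import BrainAtlas, RegionDef


@pytest.fixture
def rng():
    # fresh, fixed-seed generator per test so results don't depend on test order
    return np.random.default_rng(20250920)


@pytest.fixture
def tiny_atlas():
    return BrainAtlas(
        [
            RegionDef("A", "region alpha", (0.0, 1.0, 2.0)),
            RegionDef("B", "region beta", (3.0, 4.0, 5.0)),
            RegionDef("C", "region gamma", (-1.5, 0.25, 7.0)),
        ]
    )
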