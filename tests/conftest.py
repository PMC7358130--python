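"""Shared fixtures: desk-scale geometry and seeded RNG."""

from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

import granuleloc as g


@pytest.fixture(scope="session")
def desk_geometry():
    cfg = g.desk_config(seed=11)
    return cfg, g.make_geometry(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
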