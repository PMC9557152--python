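"""Shared fixtures: small geometries and fast synthetic configurations.

Unit tests run on a reduced 56-lead vest (two 4 x 7 panels) and short
segments so the whole suite stays fast; acceptance tests use the canonical
252-lead, 60-s conditions where required.
"""

import numpy as np
import pytest

from bspmaf.geometry import default_geometry, grid_geometry
from bspmaf.synthetic import SynthConfig, generate_aa_segment


@pytest.fixture(scope="session")
def small_geometry():
    return grid_geometry(4, 7)  # 56 leads


@pytest.fixture(scope="session")
def full_geometry():
    return default_geometry()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def small_synth_cfg(**kw):
    """A fast 56-lead, 15-s configuration with test-friendly defaults."""
    kw.setdefault("n_leads", 56)
    kw.setdefault("duration_s", 15.0)
    kw.setdefault("seed", 0)
    return SynthConfig(**kw)


@pytest.fixture(scope="session")
def organized_segment():
    """A 56-lead organized-regime AA segment (3 whole 5-s windows)."""
    return generate_aa_segment(
        SynthConfig(n_leads=56, duration_s=15.0, regime="organized", seed=42)
    )
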