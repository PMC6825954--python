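import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

from silgait import ResolutionSpec, SPECIES_PROFILES
from silgait.synthdata import SyntheticRodentSpec, render_run


@pytest.fixture(scope="session")
def rat_render():
    """One rendered rat-like run with ground truth (session-cached)."""
    spec = SyntheticRodentSpec()
    return render_run(spec, n_frames=4, seed=11)


@pytest.fixture(scope="session")
def mouse_render():
    spec = SyntheticRodentSpec(
        body_length_mm=90.0,
        body_width_mm=18.0,
        tail_length_mm=75.0,
        resolution=ResolutionSpec(0.7, 0.7),
        species_profile=SPECIES_PROFILES["mouse"],
    )
    return render_run(spec, n_frames=4, seed=12)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260923)
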