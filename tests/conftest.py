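import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from scnkit import CohortConfig, generate_baseline_reference


@pytest.fixture(scope="session")
def small_config() -> CohortConfig:
    """Toy cohort: 2 modules over 12 regions, short series, fixed seed."""
    return CohortConfig(n_roi=12, n_modules=2, n_timepoints_ts=60, seed=42)


@pytest.fixture(scope="session")
def small_reference(small_config):
    return generate_baseline_reference(small_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
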