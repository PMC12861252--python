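import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from mushdry.config import default_config
from mushdry.solver import AmbientSchedule, DryingModel


@pytest.fixture(scope="session")
def default_model():
    """One shared drying model at the default configuration."""
    return DryingModel(default_config())


@pytest.fixture(scope="session")
def ha35_schedule():
    return AmbientSchedule.constant(308.15, 0.30, 0.3, 200 * 3600.0)


@pytest.fixture(scope="session")
def short_drying_result(default_model, ha35_schedule):
    """A 30 h drying run shared by several tests (expensive)."""
    return default_model.simulate(
        ha35_schedule, 30 * 3600.0, t_eval=np.linspace(0.0, 30 * 3600.0, 61)
    )
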