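import numpy as np
import pytest

from aggresim import (
    SchedulerSettings,
    SimulationConfig,
    build_ecology_preset,
)
from aggresim.reaction_diffusion import GridSpec


@pytest.fixture
def small_grid():
    return GridSpec(nx=41, ny=41, h=2.0, boundary_layer_thickness=10.0)


@pytest.fixture
def neutral_ecology():
    return build_ecology_preset(
        "neutralism", {"A": 2e-4, "B": 2e-4, "C": 2e-4}
    )


@pytest.fixture
def commensal_ecology():
    return build_ecology_preset("commensalism", {"A": 1e-4})


def tiny_config(ecology, seed=1, end_time=3.0, **overrides) -> SimulationConfig:
    """A fast configuration for scheduler-level tests."""
    defaults = dict(
        ecology=ecology,
        grid=GridSpec(nx=41, ny=41, h=2.0, boundary_layer_thickness=10.0),
        scheduler=SchedulerSettings(),
        seed=seed,
        end_time=end_time,
        n_cells=12,
        snapshot_interval=1.0,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
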