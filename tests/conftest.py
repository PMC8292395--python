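import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cyclostretch import (
    ExperimentConfig,
    compare_conditions,
    detect_grid,
    make_initial_cell,
    make_micropattern,
    run_experiment,
)

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture
def disc_mask():
    """Ideal disc, radius 25 µm at 0.5 µm/pixel in a 512×512 frame."""
    return make_initial_cell(radius=25.0, irregularity=0.0, pixel_size=0.5, seed=0)


@pytest.fixture(scope="session")
def grid_pair():
    """Reference and (0.15, −0.0225)-strained micropattern grid fits."""
    ref = detect_grid(make_micropattern(seed=0))
    stretched = detect_grid(
        make_micropattern(eps_ax=0.15, eps_tr=-0.15 * 0.15, seed=0)
    )
    return ref, stretched


@pytest.fixture(scope="session")
def control_bundle():
    """One full control-condition experiment (6 cells, compressed schedule)."""
    return run_experiment(ExperimentConfig(condition="control", n_cells=6, seed=0))


@pytest.fixture(scope="session")
def condition_endpoints():
    """End-of-run population means for the three main drug conditions."""
    tab = compare_conditions(
        [
            ExperimentConfig(condition=c, n_cells=6, seed=42)
            for c in ("control", "nocodazole", "blebbistatin")
        ]
    )
    end = tab[tab.time_s == tab.time_s.max()]
    return {
        row.condition: row.orientation_index_mean for row in end.itertuples()
    }
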