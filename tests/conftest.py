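import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import augerdose as ad

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def series_scheme():
    return ad.build_scheme("Pd103_series")


@pytest.fixture(scope="session")
def series_profile(series_scheme):
    """Shared radial profile of the combined spectrum (point source)."""
    return ad.radial_profile(series_scheme, 4000, shell_width_nm=20.0, seed=90)


@pytest.fixture(scope="session")
def cluster_tally():
    """Shared uniformly labeled cluster run (cell-surface source)."""
    cfg = ad.ScenarioConfig(nuclide="Pd103_series", geometry="cluster",
                            distribution="cell_surface", histories=400, seed=91)
    return ad.run_scenario(cfg)


@pytest.fixture(scope="session")
def sphere_tally_10():
    cfg = ad.ScenarioConfig(nuclide="Pd103_series", geometry="sphere",
                            distribution="uniform_sphere", diameter=10.0,
                            histories=3000, seed=92)
    return ad.run_scenario(cfg)
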