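import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from lamsal.design import make_block_design
from lamsal.synth import ColumnModel, ScenarioSpec, build_column_model

settings.register_profile(
    "suite", deadline=None, derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def column_model():
    return build_column_model(n_voxels_per_region=24, seed=0)


@pytest.fixture(scope="session")
def design_two_runs():
    return make_block_design(2)


@pytest.fixture()
def noiseless_v1sh():
    return ScenarioSpec.default("v1sh", noise_sd=0.0, drift_amp=0.0)


@pytest.fixture()
def single_voxel_model():
    """One pure-superficial V1 voxel (weights exactly (0,0,0,0,1))."""
    vox = pd.DataFrame([{"region": "V1", "ix": 0, "iy": 0, "x": 0.0, "y": 0.0,
                         "radius": 1.9, "w_wm": 0.0, "w_csf": 0.0,
                         "w_deep": 0.0, "w_middle": 0.0, "w_superficial": 1.0}])
    vert = pd.DataFrame({"region": ["V1"], "depth": [0.9], "x0": [3.0],
                         "y0": [-3.0], "sigma": [1.0]})
    return ColumnModel(vox, vert, wm_radius=1.0, pial_radius=2.0)
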