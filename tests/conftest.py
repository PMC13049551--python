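import numpy as np
import pytest

from gboldcsf import SimulationConfig
from gboldcsf.config import AnalysisConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    """Fast test-scale configuration: small grid, short run, tiny cohort."""
    return SimulationConfig(
        grid_dims=(16, 16, 8),
        n_timepoints=96,
        n_hc=3,
        n_psa=3,
        n_treated=2,
        seed=11,
    )


@pytest.fixture
def analysis_config():
    return AnalysisConfig()


@pytest.fixture
def clean_subject():
    """Noise-free, motion-free phantom with unit gains: GM voxels equal u(t)."""
    cfg = SimulationConfig(
        grid_dims=(16, 16, 8),
        n_timepoints=96,
        noise_sd_bold=0.0,
        noise_sd_csf=0.0,
        motion_amp_mm=0.0,
        network_gains={"LN": 1.0, "SN": 1.0, "DAN": 1.0, "DMN": 1.0},
        gm_other_gain=1.0,
        seed=3,
    )
    from gboldcsf.simulate import generate_subject

    vol, labels, motion = generate_subject(cfg, "HC", np.random.default_rng(3))
    return cfg, vol, labels, motion
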