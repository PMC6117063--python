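import dataclasses

import pytest

from psegrowth.config import PipelineConfig, default_config
from psegrowth.synthetic import generate_stage_table


@pytest.fixture(scope="session")
def config() -> PipelineConfig:
    return default_config(seed=1)


@pytest.fixture(scope="session")
def control_table(config):
    """Calibrated control stage table, 10 embryos per stage, seed 1."""
    return generate_stage_table(config, "control", n_embryos=10, seed=1)


@pytest.fixture(scope="session")
def noise_free_config(config) -> PipelineConfig:
    """Reference calibration with every noise parameter at zero."""
    cals = {
        s: cal.replace(
            volume_cv=0.0, thickness_cv=0.0, count_cv=0.0, diameter_cv=0.0,
            area_noise_cv=0.0, nuclear_size_cv=0.0, cell_cycle_cv=0.0,
            profile_noise_sd=0.0,
        )
        for s, cal in config.calibrations.items()
    }
    return PipelineConfig(
        seed=config.seed,
        stages=list(config.stages),
        analysis=dataclasses.replace(config.analysis),
        calibrations=cals,
    )
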