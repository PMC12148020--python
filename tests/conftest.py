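import numpy as np
import pandas as pd
import pytest

from humidistat.arena import ArenaSpec, HumidityField
from humidistat.synthstudy import StudyConfig, simulate_study_tables


@pytest.fixture(scope="session")
def arena():
    return ArenaSpec()


@pytest.fixture(scope="session")
def linear_field_17():
    """Exactly linear 50->90% RH field at 17 degC (no fit noise)."""
    return HumidityField(
        nominal_temperature_C=17.0,
        intercept_pct=50.0,
        slope_pct_per_deg=40.0 / 180.0,
        fit_r2=1.0,
        residual_sd_pct=0.0,
    )


@pytest.fixture(scope="session")
def fast_config():
    """Reduced-resolution study: 200 frames per 12 h trial (216 s interval).

    Keeps the trial duration and the 3 h / 9 h period split while cutting the
    per-trial frame count for quick end-to-end runs.
    """
    return StudyConfig(n_frames=200, frame_interval_s=216.0)


@pytest.fixture(scope="session")
def default_study():
    """One full-resolution synthetic study (44 animals x 2 temperatures)."""
    return simulate_study_tables(StudyConfig(), seed=11)


@pytest.fixture(scope="session")
def fast_study(fast_config):
    return simulate_study_tables(fast_config, seed=12)
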