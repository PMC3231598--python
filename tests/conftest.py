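from dataclasses import replace

import numpy as np
import pytest

from etongue.activity import ActivityModelParams
from etongue.design import DEFAULT_IONS, generate_design
from etongue.io import load_panel

TRUTH = {
    # generating parameters of the shipped reference panel:
    # sensor -> (slope mV/decade, detection limit M, {interferent: log k})
    "P1": (-57.7, 5.2e-6, {"S": -1.96}),
    "S1": (-33.3, 1.3e-5, {"ClO4": -2.68}),
    "S2": (-30.9, 9.8e-6, {"ClO4": -3.23}),
    "S3": (-28.9, 9.9e-6, {"ClO4": -3.75}),
    "G": (-60.1, 7.5e-6, {"S": -1.25}),
}


@pytest.fixture(scope="session")
def panel():
    return load_panel()


@pytest.fixture(scope="session")
def clean_panel(panel):
    return panel.with_noise(0.0, drift_sd=0.0)


@pytest.fixture(scope="session")
def ions(panel):
    return tuple(panel.ions)


@pytest.fixture(scope="session")
def mix_params(panel):
    """Activity model for unbuffered mixture measurements."""
    return replace(panel.activity, fixed_background_ionic_strength=0.0)


@pytest.fixture(scope="session")
def cal_params(panel):
    """Activity model for calibrations in the 0.05 M background electrolyte."""
    return replace(panel.activity, fixed_background_ionic_strength=0.05)


@pytest.fixture(scope="session")
def ideal_params():
    return ActivityModelParams(formalism="ideal")


@pytest.fixture(scope="session")
def design():
    return generate_design(ions=DEFAULT_IONS)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260922)
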