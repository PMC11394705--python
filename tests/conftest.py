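import numpy as np
import pytest

from quenchbind.synthetic import SyncBandTruth, TitrationTruth, simulate_titration_series


@pytest.fixture
def clean_titration_truth():
    return TitrationTruth(p_ka=6.7420, n=1.4409, noise_sd_fraction=0.0, peak_drift_nm=0.0)


@pytest.fixture
def clean_series(clean_titration_truth):
    return simulate_titration_series(clean_titration_truth)


@pytest.fixture
def sync_truth_pair():
    ladder = (0.0, 4e-6, 8e-6, 1.2e-5, 1.6e-5, 2.0e-5)
    t15 = SyncBandTruth(
        delta_lambda_nm=15.0, center_nm=293.0, quench_fraction=0.4, drift_nm=-2.0, conc_ladder_M=ladder
    )
    t60 = SyncBandTruth(
        delta_lambda_nm=60.0, center_nm=279.0, quench_fraction=0.6, drift_nm=0.0, conc_ladder_M=ladder
    )
    return t15, t60


def gaussian_spectrum_arrays(center=338.0, height=100.0, width=20.0, start=300.0, stop=450.0, step=1.0):
    grid = np.arange(start, stop + step / 2, step)
    return grid, height * np.exp(-((grid - center) ** 2) / (2 * width**2))
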