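import numpy as np
import pytest

from microecg import (AnalysisConfig, FieldPotentialModel, SimConfig,
                      simulate_recording)


def geometry_config(bp: float, fpd: float, **overrides) -> AnalysisConfig:
    return AnalysisConfig.for_geometry(bp, fpd, **overrides)


@pytest.fixture(scope="session")
def default_sim():
    """A 60 s baseline-condition recording (BP 1.9 s, FPD 0.69 s, SNR 25 dB)."""
    return simulate_recording(SimConfig(duration=60.0, seed=0))


@pytest.fixture(scope="session")
def default_fit(default_sim):
    rec, gt = default_sim
    return FieldPotentialModel(rec).fit(), gt


@pytest.fixture(scope="session")
def clean_sim():
    """Noise-free variant of the default conditions."""
    return simulate_recording(
        SimConfig(duration=60.0, seed=0, noise_snr_db=None, bp_cv_pct=0.0,
                  fpd_cv_pct=0.0))


def relerr(estimate: float, truth: float) -> float:
    return 100.0 * abs(estimate - truth) / abs(truth)
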