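import numpy as np
import pandas as pd
import pytest

import icpulse as ip
from icpulse.config import PipelineConfig


def minute_index_series(patient: ip.SimPatient,
                        config: PipelineConfig | None = None) -> pd.DataFrame:
    """Full chain: waveforms -> 10-s windows -> minute index table."""
    summ = ip.summarize_recording(patient.recordings["ABP"],
                                  patient.recordings["ICP"],
                                  patient.recordings.get("PBTO2"))
    return ip.compute_indices(summ, config or PipelineConfig())


@pytest.fixture(scope="session")
def quiet_patient():
    """Noise-free single patient with known HR, pulse amplitudes and flat ICP
    at the amplitude model's reference pressure (so AMP == amp_baseline)."""
    cfg = ip.SimConfig(duration_s=600.0, noise_sd=0.0, slow_wave_amplitude=0.0,
                       icp_slow_amplitude=0.0, heart_rate=72.0,
                       icp_trajectory=17.5, amp_baseline=2.0, seed=1)
    abp = ip.generate_abp(cfg)
    icp = ip.generate_icp(cfg, abp)
    return cfg, abp, icp


@pytest.fixture(scope="session")
def mixed_cohort():
    """Small cohort containing every phenotype at default noise (3 h each)."""
    mix = {"upper_breakpoint": 0.25, "rightward_deflection": 0.25,
           "monotonic_increase": 0.25, "monotonic_decrease": 0.25}
    return ip.generate_cohort(8, mix, seed=21, duration_s=3 * 3600.0)
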