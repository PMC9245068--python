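import numpy as np
import pytest

from gaitrel.synthetic import STP_PRIMITIVES, SyntheticCohortConfig, zero_error_config
from gaitrel.trial import ANGLE_KEYS, LANDMARK_KEYS, MotionTrial

ZERO_STP = {k: 0.0 for k in STP_PRIMITIVES}


@pytest.fixture
def tiny_config():
    """Small cohort with the default variance hierarchy."""
    return SyntheticCohortConfig(
        n_subjects=3, passes_per_session=2, strides_per_pass=3, seed=42
    )


@pytest.fixture
def noise_free_config():
    """Zero session- and stride-level variance (subject effects remain)."""
    return zero_error_config(
        n_subjects=2, passes_per_session=2, strides_per_pass=3, seed=9
    )


@pytest.fixture
def aligned_zero_config():
    """Zero-variance config whose stride geometry is sample-aligned.

    Stride time 1.43/1.3 = 1.1 s = 66 samples at 60 Hz, stance 2/3 s = 40
    samples, double supports 0.2 s = 12 samples, so every stride covers an
    identical sample pattern and discretization is bit-identical across
    strides.
    """
    return zero_error_config(
        n_subjects=2, passes_per_session=2, strides_per_pass=3, seed=4,
        stp_means={"gait_speed": 1.3, "stride_length": 1.43,
                   "stance_time": 2.0 / 3.0, "dls1_time": 0.2,
                   "dls2_time": 0.2, "step_width": 0.19},
        var_between_subject={**ZERO_STP, "angles": 0.0},
    )


def make_trial(heel_ap, toe_ap, sacrum_ap, sampling_rate=60.0, progression_sign=1,
               side="L", **kwargs):
    """Minimal trial with prescribed AP channels on one side (rest zeros)."""
    n = len(heel_ap)
    zeros = np.zeros(n)
    angles = {key: zeros.copy() for key in ANGLE_KEYS}
    landmarks = {key: zeros.copy() for key in LANDMARK_KEYS}
    landmarks[(side, "heel", "AP")] = np.asarray(heel_ap, dtype=float)
    landmarks[(side, "toe", "AP")] = np.asarray(toe_ap, dtype=float)
    landmarks[("pelvis", "sacrum", "AP")] = np.asarray(sacrum_ap, dtype=float)
    defaults = dict(subject_id="T01", session=1, task="SSWS",
                    sampling_rate=sampling_rate, progression_sign=progression_sign)
    defaults.update(kwargs)
    return MotionTrial(angles=angles, landmarks=landmarks, **defaults)
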