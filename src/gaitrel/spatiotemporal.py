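"""Spatiotemporal gait parameters per stride.

Temporal parameters come straight from event sample indices, so the
partition identities

    stride_time == stance_time + swing_time
    stance_time == dls1_time + sls_time + dls2_time

hold exactly on every stride (swing and single-limb-support times are
computed as the closing differences).  Spatial parameters come from heel and
sacrum trajectories at the event samples.  Gait speed is measured from the
sacrum AP displacement over the stride rather than as stride length over
stride time, so speed and length are independent measurements and their
ratio is a useful diagnostic.  Cadence is 120 / stride_time, i.e. steps per
minute under step symmetry.  ``_ll`` variants divide by leg length and are
dimensionless multiples of it.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .events import Stride
from .trial import MotionTrial, other_side

#: all spatiotemporal variables with output units
STP_UNITS: dict[str, str] = {
    "gait_speed": "m/s",
    "gait_speed_ll": "leg-lengths/s",
    "cadence": "steps/min",
    "stride_time": "s",
    "stance_time": "s",
    "dls1_time": "s",
    "dls2_time": "s",
    "sls_time": "s",
    "swing_time": "s",
    "stride_length": "m",
    "stride_length_ll": "leg-lengths",
    "step_time": "s",
    "step_length": "m",
    "step_length_ll": "leg-lengths",
    "step_width": "m",
}

STP_VARIABLES: tuple[str, ...] = tuple(STP_UNITS)


def compute_stp(
    trial: MotionTrial,
    side: str,
    strides: list[Stride],
) -> pd.DataFrame:
    """Per-stride spatiotemporal record for the analysis ``side``.

    Step-level fields (step_time, step_length, step_width and normalized
    variants) are NaN for strides lacking a contralateral IC; stride-level
    fields are always present.
    """
    fs = trial.sampling_rate
    contra = other_side(side)
    sign = trial.progression_sign if trial.progression_sign in (1, -1) else 1
    heel_ap = trial.landmark(side, "heel", "AP")
    heel_ml = trial.landmark(side, "heel", "ML")
    c_heel_ap = trial.landmark(contra, "heel", "AP")
    c_heel_ml = trial.landmark(contra, "heel", "ML")
    sac_ap = trial.landmark("pelvis", "sacrum", "AP")
    ll = trial.leg_length

    rows = []
    for s in strides:
        stride_time = (s.end - s.start) / fs
        stance_time = (s.to - s.start) / fs
        swing_time = stride_time - stance_time
        stride_length = abs(heel_ap[s.end] - heel_ap[s.start])
        displacement = abs(sac_ap[s.end] - sac_ap[s.start])
        gait_speed = displacement / stride_time
        row = {
            "stride_time": stride_time,
            "stance_time": stance_time,
            "swing_time": swing_time,
            "stride_length": stride_length,
            "stride_length_ll": stride_length / ll,
            "gait_speed": gait_speed,
            "gait_speed_ll": gait_speed / ll,
            "cadence": 120.0 / stride_time,
        }
        if s.contra_ic is not None and s.contra_to is not None:
            dls1 = (s.contra_to - s.start) / fs
            dls2 = (s.to - s.contra_ic) / fs
            sls = stance_time - dls1 - dls2
            step_time = (s.end - s.contra_ic) / fs
            step_length = sign * (heel_ap[s.end] - c_heel_ap[s.end])
            step_width = abs(heel_ml[s.end] - c_heel_ml[s.end])
            row.update({
                "dls1_time": dls1,
                "dls2_time": dls2,
                "sls_time": sls,
                "step_time": step_time,
                "step_length": step_length,
                "step_length_ll": step_length / ll,
                "step_width": step_width,
            })
        else:
            row.update({k: np.nan for k in (
                "dls1_time", "dls2_time", "sls_time", "step_time",
                "step_length", "step_length_ll", "step_width")})
        rows.append(row)

    df = pd.DataFrame(rows, columns=list(STP_VARIABLES), dtype=float)
    return df
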