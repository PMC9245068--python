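"""Core container for a single walking pass.

A :class:`MotionTrial` bundles the synchronized lower-limb joint-angle and
landmark time series of one pass along a walkway, together with the metadata
needed downstream (sampling rate, leg length, dominant side, direction of
progression).

Conventions
-----------
Angles are in degrees with flexion/dorsiflexion, adduction, inversion/varus
and internal rotation positive; their opposites are negative.  Landmark
positions are in meters along the anteroposterior (AP), mediolateral (ML)
and vertical axes.  Sample indices are 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

SIDES = ("L", "R")
JOINTS = ("hip", "knee", "ankle")
PLANES = ("sagittal", "frontal", "transverse")
AXES = ("AP", "ML", "vertical")
FOOT_LANDMARKS = ("heel", "toe")
TASKS = ("SSWS", "FCWS")

#: all (side, joint, plane) angle channel keys, in canonical order
ANGLE_KEYS = tuple(
    (s, j, p) for s in SIDES for j in JOINTS for p in PLANES
)

#: all (segment, landmark, axis) landmark channel keys, in canonical order
LANDMARK_KEYS = tuple(
    [(s, lm, ax) for s in SIDES for lm in FOOT_LANDMARKS for ax in AXES]
    + [("pelvis", "sacrum", ax) for ax in AXES]
)


def other_side(side: str) -> str:
    if side not in SIDES:
        raise ValueError(f"unknown side {side!r}; expected one of {SIDES}")
    return "R" if side == "L" else "L"


@dataclass
class MotionTrial:
    """One walking pass: synchronized signals plus subject metadata.

    All signals must share one length; ``progression_sign`` is +1 when the
    subject walks toward increasing AP coordinates, -1 on the return pass,
    and 0 when unknown (event detection then infers it from the net sacrum
    AP displacement).
    """

    subject_id: str
    session: int
    task: str
    sampling_rate: float
    angles: dict[tuple[str, str, str], np.ndarray]
    landmarks: dict[tuple[str, str, str], np.ndarray]
    progression_sign: int = 0
    leg_length: float = 0.84
    dominant_side: str = "R"
    pass_index: int = 0
    extra: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.session not in (1, 2):
            raise ValueError(f"session must be 1 or 2, got {self.session}")
        if self.dominant_side not in SIDES:
            raise ValueError(f"dominant_side must be in {SIDES}")
        lengths = {arr.shape[0] for arr in self.angles.values()}
        lengths |= {arr.shape[0] for arr in self.landmarks.values()}
        if len(lengths) > 1:
            raise ValueError(f"signals have mismatched lengths: {sorted(lengths)}")
        for key, arr in list(self.angles.items()) + list(self.landmarks.items()):
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"channel {key} contains non-finite samples")

    @property
    def n_samples(self) -> int:
        return next(iter(self.landmarks.values())).shape[0]

    @property
    def duration(self) -> float:
        """Trial duration in seconds, (n_samples - 1) / sampling_rate."""
        return (self.n_samples - 1) / self.sampling_rate

    @property
    def trial_id(self) -> str:
        return f"{self.subject_id}-s{self.session}-p{self.pass_index}"

    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate

    def angle(self, side: str, joint: str, plane: str) -> np.ndarray:
        key = (side, joint, plane)
        if key not in self.angles:
            raise KeyError(f"missing angle channel {key}")
        return self.angles[key]

    def landmark(self, segment: str, name: str, axis: str) -> np.ndarray:
        key = (segment, name, axis)
        if key not in self.landmarks:
            raise KeyError(f"missing landmark channel {key}")
        return self.landmarks[key]

    def copy(self) -> "MotionTrial":
        return MotionTrial(
            subject_id=self.subject_id,
            session=self.session,
            task=self.task,
            sampling_rate=self.sampling_rate,
            angles={k: v.copy() for k, v in self.angles.items()},
            landmarks={k: v.copy() for k, v in self.landmarks.items()},
            progression_sign=self.progression_sign,
            leg_length=self.leg_length,
            dominant_side=self.dominant_side,
            pass_index=self.pass_index,
            extra={k: v.copy() for k, v in self.extra.items()},
        )
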