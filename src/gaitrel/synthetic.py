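"""Synthetic two-session gait cohorts with known ground truth.

This module emulates the structure of a test-retest gait study: ``n``
subjects each perform several walkway passes per session on two separate
days, for a self-selected (SSWS) or fastest-comfortable (FCWS) walking-speed
task.  Joint-angle curves are truncated Fourier templates shaped like normal
adult gait; landmark trajectories are built so that the coordinate-based
event detector has well-defined extrema exactly at the ground-truth initial
contacts and toe-offs.

Variance model
--------------
Every variable follows an additive Gaussian hierarchy

    value = population mean + subject effect + session effect + stride effect

with independent effects at each level.  Both sessions receive independent
session effects, so ``sqrt(var_between_session)`` is the ground-truth
standard error of measurement that the reliability pipeline must recover.
Angle-curve errors at each level are low-order harmonic random curves with
stationary pointwise standard deviation (see :func:`draw_error_curve`), so
the injected sigma applies to every discrete variable including ranges of
motion.

All randomness flows from ``config.seed`` through named per-subject /
per-session / per-pass streams, so adding subjects to a cohort does not
perturb the subjects already generated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
import pandas as pd

from .trial import ANGLE_KEYS, JOINTS, MotionTrial, PLANES, SIDES, TASKS

# ---------------------------------------------------------------------------
# Joint-angle templates
# ---------------------------------------------------------------------------

#: Default per-(joint, plane) templates: (constant offset, [(amplitude_deg,
#: phase_rad) for harmonics 1..H]).  Coefficients were fit once to keypoint
#: sketches of normal adult gait so that ranges of motion and extremum
#: locations match the magnitudes reported for overground walking (e.g. knee
#: sagittal swing peak ~64 deg near 75% cycle, ankle plantarflexion trough
#: ~-28 deg just after toe-off).
DEFAULT_TEMPLATES: dict[tuple[str, str], tuple[float, list[tuple[float, float]]]] = {
    ("hip", "sagittal"): (5.573, [(22.760, 1.5931), (3.569, -2.5670), (0.698, -1.3598), (0.375, -0.8527)]),
    ("knee", "sagittal"): (21.894, [(21.805, 3.0128), (16.139, -1.4114), (5.624, -0.4329), (0.311, -0.6286)]),
    ("ankle", "sagittal"): (-3.430, [(10.554, -0.2477), (8.156, 2.6351), (5.391, -1.6279), (2.697, 0.7748)]),
    ("hip", "frontal"): (2.853, [(2.847, 0.2245), (0.756, -0.4087), (0.319, -0.6409), (0.211, -1.1639)]),
    ("knee", "frontal"): (0.717, [(3.312, 2.9861), (0.860, -1.5992), (0.118, -0.0012), (0.086, 0.7087)]),
    ("ankle", "frontal"): (3.176, [(7.373, 3.0338), (1.201, 3.0899), (0.646, 3.0489), (0.190, 2.0278)]),
    ("hip", "transverse"): (0.253, [(5.312, 0.8724), (1.018, -1.3386), (0.159, -1.6400), (0.160, -1.5138)]),
    ("knee", "transverse"): (-5.565, [(5.217, -2.7046), (4.649, -0.2564), (3.293, 1.0802), (2.269, 1.7017)]),
    ("ankle", "transverse"): (-2.019, [(8.027, 0.1856), (2.363, 0.7354), (1.163, 0.9677), (0.713, 0.5357)]),
}


#: stance fraction the default templates were sketched at; generated curves
#: are time-warped so this maps onto each session's actual stance fraction,
#: keeping curve features (e.g. the plantarflexion trough just after
#: toe-off) locked to the gait events as they are physiologically
TEMPLATE_STANCE_FRACTION = 0.65


def warp_phase(phase, stance_fraction: float, template_stance_fraction: float = TEMPLATE_STANCE_FRACTION):
    """Piecewise-linear warp mapping actual stance [0, f] onto template stance.

    Stance [0, f] maps linearly onto [0, F0] and swing [f, 1] onto [F0, 1],
    so event-locked template features stay at fixed offsets from IC and TO
    whatever the stance fraction.
    """
    phase = np.asarray(phase, dtype=float)
    f, f0 = float(stance_fraction), float(template_stance_fraction)
    if not (0.0 < f < 1.0):
        raise ValueError(f"stance_fraction must be in (0, 1), got {f}")
    out = np.where(phase <= f, phase * (f0 / f), f0 + (phase - f) * ((1 - f0) / (1 - f)))
    return out if out.ndim else float(out)


def joint_angle_template(joint: str, plane: str, gait_phase, coefficients=None):
    """Evaluate the template angle at ``gait_phase`` (fraction of cycle).

    ``coefficients`` is ``(offset, [(amplitude, phase_rad), ...])`` where the
    i-th pair is the i-th harmonic; the value is

        offset + sum_h A_h * sin(2 pi h phase + theta_h)

    which is smooth and exactly periodic (template(0) == template(1)).
    """
    if coefficients is None:
        key = (joint, plane)
        if key not in DEFAULT_TEMPLATES:
            raise ValueError(
                f"unknown joint/plane {key!r}; expected joint in {JOINTS} and plane in {PLANES}"
            )
        coefficients = DEFAULT_TEMPLATES[key]
    offset, pairs = coefficients
    phase = np.asarray(gait_phase, dtype=float)
    if not np.all(np.isfinite(phase)):
        raise ValueError("gait_phase must be finite")
    value = np.full_like(phase, float(offset))
    for h, (amp, theta) in enumerate(pairs, start=1):
        if not (math.isfinite(amp) and math.isfinite(theta)):
            raise ValueError("template coefficients must be finite")
        value = value + amp * np.sin(2 * np.pi * h * phase + theta)
    return value if value.ndim else float(value)


# ---------------------------------------------------------------------------
# Structured random error curves
# ---------------------------------------------------------------------------

#: variance weights on (constant, 1st harmonic, 2nd harmonic)
_ERROR_WEIGHTS = (0.5, 0.3, 0.2)


def draw_error_curve(rng: np.random.Generator, sd: float) -> np.ndarray:
    """Draw coefficients of a random periodic error curve.

    The curve ``e(phi) = c0 + c1 sin(2 pi phi) + c2 cos(2 pi phi)
    + c3 sin(4 pi phi) + c4 cos(4 pi phi)`` has pointwise standard deviation
    exactly ``sd`` at every phase, so an error of this form injected at the
    session level is, by construction, the measurement-error SD of every
    discrete variable read off the curve.
    """
    w0, w1, w2 = _ERROR_WEIGHTS
    z = rng.standard_normal(5)
    return sd * np.array(
        [math.sqrt(w0) * z[0],
         math.sqrt(w1) * z[1], math.sqrt(w1) * z[2],
         math.sqrt(w2) * z[3], math.sqrt(w2) * z[4]]
    )


def eval_error_curve(coeffs: np.ndarray, phase) -> np.ndarray:
    phase = np.asarray(phase, dtype=float)
    return (
        coeffs[0]
        + coeffs[1] * np.sin(2 * np.pi * phase)
        + coeffs[2] * np.cos(2 * np.pi * phase)
        + coeffs[3] * np.sin(4 * np.pi * phase)
        + coeffs[4] * np.cos(4 * np.pi * phase)
    )


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

#: drawn spatiotemporal primitives (everything else is derived from these)
STP_PRIMITIVES = (
    "gait_speed", "stride_length", "stance_time",
    "dls1_time", "dls2_time", "step_width",
)

_DEFAULT_STP_MEANS = {
    # population means per task (m/s, m, s, s, s, m)
    "SSWS": {"gait_speed": 1.35, "stride_length": 1.43, "stance_time": 0.74,
             "dls1_time": 0.18, "dls2_time": 0.18, "step_width": 0.19},
    "FCWS": {"gait_speed": 1.95, "stride_length": 1.68, "stance_time": 0.58,
             "dls1_time": 0.13, "dls2_time": 0.13, "step_width": 0.22},
}

# Default variance components (squared units).  Subject-level SDs follow the
# between-subject spread of healthy adult cohorts; session-level SDs are of
# the order of reported between-day measurement errors; stride-level SDs
# reflect within-pass variability of steady-state walking.  The key "angles"
# applies to every joint-angle channel (degrees^2); "<joint>.<plane>" keys
# override it.
_DEFAULT_VAR_SUBJECT = {
    "gait_speed": 0.25 ** 2, "stride_length": 0.18 ** 2, "stance_time": 0.08 ** 2,
    "dls1_time": 0.03 ** 2, "dls2_time": 0.03 ** 2, "step_width": 0.05 ** 2,
    "angles": 3.0 ** 2,
}
_DEFAULT_VAR_SESSION = {
    "gait_speed": 0.06 ** 2, "stride_length": 0.05 ** 2, "stance_time": 0.03 ** 2,
    "dls1_time": 0.015 ** 2, "dls2_time": 0.015 ** 2, "step_width": 0.015 ** 2,
    "angles": 2.0 ** 2,
}
_DEFAULT_VAR_STRIDE = {
    "gait_speed": 0.04 ** 2, "stride_length": 0.04 ** 2, "stance_time": 0.015 ** 2,
    "dls1_time": 0.01 ** 2, "dls2_time": 0.01 ** 2, "step_width": 0.02 ** 2,
    "angles": 0.5 ** 2,
}

#: bounded-retry count for truncated (rejection-sampled) stride draws
MAX_REJECTION_RETRIES = 100


@dataclass
class SyntheticCohortConfig:
    """Parameters of a synthetic two-session cohort.

    ``strides_per_pass`` defaults to 4: within-session stride counts per pass
    are not reported for overground protocols of this kind, so this is an
    explicit guess, not a measured value.  ``var_between_session`` holds the
    ground-truth squared measurement error the reliability pipeline must
    recover.  Variance dicts use spatiotemporal primitive names
    (:data:`STP_PRIMITIVES`) plus the key ``"angles"`` for all joint-angle
    channels (optionally overridden per ``"<joint>.<plane>"``).
    """

    n_subjects: int = 21
    passes_per_session: int = 7
    strides_per_pass: int = 4
    sampling_rate: float = 60.0
    task: str = "SSWS"
    leg_length: float = 0.84
    seed: int = 0
    stp_means: dict[str, float] = field(default_factory=dict)
    var_between_subject: dict[str, float] = field(default_factory=dict)
    var_between_session: dict[str, float] = field(default_factory=dict)
    var_between_stride: dict[str, float] = field(default_factory=dict)
    template_coefficients: dict[tuple[str, str], tuple[float, list[tuple[float, float]]]] | None = None

    def __post_init__(self) -> None:
        if self.task not in TASKS:
            raise ValueError(f"task must be one of {TASKS}")
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.strides_per_pass < 1 or self.passes_per_session < 1:
            raise ValueError("strides_per_pass and passes_per_session must be >= 1")
        for name, d in (
            ("var_between_subject", self.var_between_subject),
            ("var_between_session", self.var_between_session),
            ("var_between_stride", self.var_between_stride),
        ):
            for k, v in d.items():
                if v < 0:
                    raise ValueError(f"{name}[{k!r}] must be >= 0, got {v}")
        self.stp_means = {**_DEFAULT_STP_MEANS[self.task], **self.stp_means}
        self.var_between_subject = {**_DEFAULT_VAR_SUBJECT, **self.var_between_subject}
        self.var_between_session = {**_DEFAULT_VAR_SESSION, **self.var_between_session}
        self.var_between_stride = {**_DEFAULT_VAR_STRIDE, **self.var_between_stride}

    def angle_sd(self, level: str, joint: str, plane: str) -> float:
        d = getattr(self, f"var_between_{level}")
        var = d.get(f"{joint}.{plane}", d["angles"])
        return math.sqrt(var)

    def stp_sd(self, level: str, var: str) -> float:
        return math.sqrt(getattr(self, f"var_between_{level}")[var])

    def template(self, joint: str, plane: str):
        if self.template_coefficients and (joint, plane) in self.template_coefficients:
            return self.template_coefficients[(joint, plane)]
        return DEFAULT_TEMPLATES[(joint, plane)]


def zero_error_config(**kwargs) -> SyntheticCohortConfig:
    """A config with all session- and stride-level variances set to zero."""
    zeros = {k: 0.0 for k in list(STP_PRIMITIVES) + ["angles"]}
    kwargs.setdefault("var_between_session", dict(zeros))
    kwargs.setdefault("var_between_stride", dict(zeros))
    return SyntheticCohortConfig(**kwargs)


# ---------------------------------------------------------------------------
# Hierarchy draws
# ---------------------------------------------------------------------------

def draw_subject_session_values(
    n_subjects: int,
    mean: float,
    sd_between_subject: float,
    sd_between_session: float,
    rng: np.random.Generator,
    n_sessions: int = 2,
) -> np.ndarray:
    """Draw an (n_subjects, n_sessions) matrix from the additive hierarchy.

    Each cell is ``mean + subject_effect + session_effect`` with independent
    Gaussian effects; this is exactly the quantity the SEM estimator sees
    after within-session stride averaging (when stride noise is zero).
    """
    subj = rng.normal(0.0, sd_between_subject, size=(n_subjects, 1))
    sess = rng.normal(0.0, sd_between_session, size=(n_subjects, n_sessions))
    return mean + subj + sess


def _subject_rng(seed: int, subject: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(subject,)))


def _session_rng(seed: int, subject: int, session: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(subject, session)))


def _pass_rng(seed: int, subject: int, session: int, pass_index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(subject, session, pass_index))
    )


# ---------------------------------------------------------------------------
# Ground truth record
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """What the generator injected, for recovery checks downstream.

    ``events[trial_id][side]`` holds ground-truth IC/TO sample indices.
    ``session_values`` has one row per subject x session x variable with the
    session-true value (population mean + subject + session effects, before
    stride noise); angle variables are keyed ``"<joint>.<plane>.<name>"``.
    ``stride_draws`` records every per-stride spatiotemporal draw.
    """

    events: dict[str, dict[str, dict[str, np.ndarray]]]
    session_values: pd.DataFrame
    stride_draws: pd.DataFrame


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def _draw_stride_primitives(
    rng: np.random.Generator,
    session_true: dict[str, float],
    config: SyntheticCohortConfig,
) -> dict[str, float]:
    """One stride's spatiotemporal draw, rejection-sampled to plausibility.

    Bounds: positive speed/length, stride time in (0.3, 3) s, stance fraction
    in (0.45, 0.78), each double-support interval positive and below 40% of
    stance.  Draws are retried up to :data:`MAX_REJECTION_RETRIES` times.
    """
    for _ in range(MAX_REJECTION_RETRIES):
        d = {
            var: session_true[var] + config.stp_sd("stride", var) * rng.standard_normal()
            for var in STP_PRIMITIVES
        }
        v, L, st = d["gait_speed"], d["stride_length"], d["stance_time"]
        d1, d2, w = d["dls1_time"], d["dls2_time"], d["step_width"]
        if v <= 0.05 or L <= 0.05:
            continue
        T = L / v
        if not (0.3 < T < 3.0):
            continue
        if not (0.45 < st / T < 0.78):
            continue
        if d1 <= 0.01 or d2 <= 0.01 or d1 > 0.4 * st or d2 > 0.4 * st:
            continue
        if not (0.01 < w < 0.6):
            continue
        d["stride_time"] = T
        return d
    raise RuntimeError(
        "could not draw a plausible stride after "
        f"{MAX_REJECTION_RETRIES} retries; check configured means/variances"
    )


def _session_true_stp(
    subject_eff: dict[str, float],
    session_eff: dict[str, float],
    config: SyntheticCohortConfig,
) -> dict[str, float]:
    true = {
        var: config.stp_means[var] + subject_eff[var] + session_eff[var]
        for var in STP_PRIMITIVES
    }
    # same plausibility bounds as stride draws, enforced on the session level
    # by clipping toward the mean (session effects are small in practice)
    true["gait_speed"] = max(true["gait_speed"], 0.1)
    true["stride_length"] = max(true["stride_length"], 0.1)
    T = true["stride_length"] / true["gait_speed"]
    true["stance_time"] = float(np.clip(true["stance_time"], 0.47 * T, 0.76 * T))
    for k in ("dls1_time", "dls2_time"):
        true[k] = float(np.clip(true[k], 0.02, 0.38 * true["stance_time"]))
    true["step_width"] = float(np.clip(true["step_width"], 0.02, 0.55))
    return true


def _derived_stp(true: dict[str, float], leg_length: float) -> dict[str, float]:
    """Session-true values of the full spatiotemporal variable set."""
    T = true["stride_length"] / true["gait_speed"]
    stance = true["stance_time"]
    d1, d2 = true["dls1_time"], true["dls2_time"]
    step_time = T - stance + d2  # contralateral IC to ipsilateral IC
    amp = true["stride_length"] / 4.0  # heel AP oscillation amplitude
    step_length = amp * (1.0 - math.cos(2 * math.pi * step_time / T))
    out = {
        "gait_speed": true["gait_speed"],
        "stride_length": true["stride_length"],
        "stride_time": T,
        "stance_time": stance,
        "swing_time": T - stance,
        "dls1_time": d1,
        "dls2_time": d2,
        "sls_time": stance - d1 - d2,
        "step_time": step_time,
        "step_length": step_length,
        "step_width": true["step_width"],
        "cadence": 120.0 / T,
        "gait_speed_ll": true["gait_speed"] / leg_length,
        "stride_length_ll": true["stride_length"] / leg_length,
        "step_length_ll": step_length / leg_length,
    }
    return out


def _piecewise_phase(t: np.ndarray, anchors: np.ndarray) -> np.ndarray:
    """Phase clock that is k at ``anchors[k]`` and piecewise linear between.

    Outside the anchor range the first/last segment slope is extrapolated.
    """
    k = np.arange(len(anchors), dtype=float)
    phase = np.interp(t, anchors, k)
    # linear extrapolation at both ends
    left = t < anchors[0]
    right = t > anchors[-1]
    if np.any(left):
        slope = 1.0 / (anchors[1] - anchors[0])
        phase[left] = (t[left] - anchors[0]) * slope
    if np.any(right):
        slope = 1.0 / (anchors[-1] - anchors[-2])
        phase[right] = (len(anchors) - 1) + (t[right] - anchors[-1]) * slope
    return phase


def _generate_pass(
    config: SyntheticCohortConfig,
    subject_idx: int,
    subject_id: str,
    session: int,
    pass_index: int,
    session_true: dict[str, float],
    angle_curves: dict[tuple[str, str], np.ndarray],
    stride_rows: list,
) -> tuple[MotionTrial, dict[str, dict[str, np.ndarray]]]:
    """Build one pass: signals plus ground-truth event indices."""
    rng = _pass_rng(config.seed, subject_idx, session, pass_index)
    fs = config.sampling_rate
    n_cyc = config.strides_per_pass + 1  # one spare cycle for contralateral windows

    draws = []
    for cycle in range(n_cyc + 1):  # one extra draw supplies the trailing dls1
        d = _draw_stride_primitives(rng, session_true, config)
        draws.append(d)
        if cycle < n_cyc:
            stride_rows.append(
                {"subject_id": subject_id, "session": session, "pass_index": pass_index,
                 "cycle": cycle, **d}
            )

    T = np.array([d["stride_time"] for d in draws[:n_cyc]])
    stance = np.array([d["stance_time"] for d in draws[:n_cyc]])
    d1 = np.array([d["dls1_time"] for d in draws[: n_cyc + 1]])
    d2 = np.array([d["dls2_time"] for d in draws[:n_cyc]])
    speed = np.array([d["gait_speed"] for d in draws[:n_cyc]])
    width = np.array([d["step_width"] for d in draws[:n_cyc]])

    # Event times (seconds).  The dominant (analysis) side carries the
    # reference clock, so its measured stance/dls windows reproduce the
    # drawn parameters; the contralateral side is derived from the
    # double-support draws and absorbs any residual timing asymmetry.
    dominant = "R" if subject_idx % 2 == 0 else "L"
    contra_side = "L" if dominant == "R" else "R"
    ic_d = np.concatenate([[0.1 * T[0]], 0.1 * T[0] + np.cumsum(T)])
    to_d = ic_d[:n_cyc] + stance
    ic_c = ic_d[:n_cyc] + stance - d2
    to_c = ic_d[: n_cyc + 1] + d1  # k-th contra TO ends double support after IC_k

    t_end = ic_d[-1] + 0.25 * T[-1]
    n_samples = int(math.floor(t_end * fs)) + 1
    t = np.arange(n_samples) / fs

    # phase clocks anchored at each event train (n_cyc >= 2 always)
    phi_heel = {dominant: _piecewise_phase(t, ic_d), contra_side: _piecewise_phase(t, ic_c)}
    phi_toe = {dominant: _piecewise_phase(t, to_d), contra_side: _piecewise_phase(t, to_c)}

    # sacrum AP: piecewise-constant per-stride speed, integrated exactly so
    # the displacement over stride k equals the drawn stride_length_k
    sac_ap = 0.5 + _integrate_piecewise_speed(t, ic_d, speed)

    amp = session_true["stride_length"] / 4.0
    heel_ap = {s: sac_ap + amp * np.cos(2 * np.pi * phi_heel[s]) for s in SIDES}
    toe_ap = {s: sac_ap + 0.12 - amp * np.cos(2 * np.pi * phi_toe[s]) for s in SIDES}

    w_t = np.interp(t, ic_d[:-1], width, left=width[0], right=width[-1])
    heel_ml = {"L": -w_t / 2.0, "R": w_t / 2.0}
    sac_ml = 0.02 * np.sin(2 * np.pi * phi_heel[dominant])
    heel_v = {
        s: 0.03 + 0.05 * np.maximum(0.0, -np.cos(2 * np.pi * phi_heel[s])) ** 2
        for s in SIDES
    }
    toe_v = {
        s: 0.02 + 0.06 * np.maximum(0.0, -np.cos(2 * np.pi * phi_toe[s] + 0.6)) ** 2
        for s in SIDES
    }
    sac_v = 0.95 + 0.01 * np.cos(4 * np.pi * phi_heel[dominant])

    sign = 1 if pass_index % 2 == 0 else -1

    def ap(x: np.ndarray) -> np.ndarray:
        return x if sign > 0 else 10.0 - x

    landmarks = {
        ("L", "heel", "AP"): ap(heel_ap["L"]), ("R", "heel", "AP"): ap(heel_ap["R"]),
        ("L", "toe", "AP"): ap(toe_ap["L"]), ("R", "toe", "AP"): ap(toe_ap["R"]),
        ("L", "heel", "ML"): heel_ml["L"], ("R", "heel", "ML"): heel_ml["R"],
        ("L", "toe", "ML"): heel_ml["L"].copy(), ("R", "toe", "ML"): heel_ml["R"].copy(),
        ("L", "heel", "vertical"): heel_v["L"], ("R", "heel", "vertical"): heel_v["R"],
        ("L", "toe", "vertical"): toe_v["L"], ("R", "toe", "vertical"): toe_v["R"],
        ("pelvis", "sacrum", "AP"): ap(sac_ap),
        ("pelvis", "sacrum", "ML"): sac_ml,
        ("pelvis", "sacrum", "vertical"): sac_v,
    }

    # joint angles: template + hierarchical error curves, per side phase,
    # warped so template features stay locked to this session's events
    session_f = session_true["stance_time"] * session_true["gait_speed"] / session_true["stride_length"]
    angles = {}
    phase_by_side = phi_heel
    for joint in JOINTS:
        for plane in PLANES:
            sd_stride = config.angle_sd("stride", joint, plane)
            stride_coeffs = [draw_error_curve(rng, sd_stride) for _ in range(n_cyc + 2)]
            base_coeffs = angle_curves[(joint, plane)]
            for side in SIDES:
                phi = phase_by_side[side]
                cyc = np.clip(np.floor(phi).astype(int) + 1, 0, n_cyc + 1)
                frac = warp_phase(phi - np.floor(phi), session_f)
                value = joint_angle_template(joint, plane, frac, config.template(joint, plane))
                value = value + eval_error_curve(base_coeffs, frac)
                # per-stride error curve, indexed by the side's own cycle
                stride_err = np.empty_like(value)
                for c in np.unique(cyc):
                    m = cyc == c
                    stride_err[m] = eval_error_curve(stride_coeffs[c], frac[m])
                angles[(side, joint, plane)] = value + stride_err

    trial = MotionTrial(
        subject_id=subject_id,
        session=session,
        task=config.task,
        sampling_rate=fs,
        angles=angles,
        landmarks=landmarks,
        progression_sign=sign,
        leg_length=config.leg_length,
        dominant_side=dominant,
        pass_index=pass_index,
    )

    def to_idx(times: np.ndarray) -> np.ndarray:
        idx = np.round(times * fs).astype(int)
        return idx[(idx >= 1) & (idx <= n_samples - 2)]

    gt_events = {
        dominant: {"ic": to_idx(ic_d), "to": to_idx(to_d)},
        contra_side: {"ic": to_idx(ic_c), "to": to_idx(to_c)},
    }
    return trial, gt_events


def _integrate_piecewise_speed(t: np.ndarray, anchors: np.ndarray, speed: np.ndarray) -> np.ndarray:
    """Displacement of a piecewise-constant speed profile, exact per segment."""
    knots = anchors
    # cumulative displacement at each knot
    seg_disp = np.concatenate([[0.0], np.cumsum(speed * np.diff(knots))])
    disp = np.interp(t, knots, seg_disp)
    left = t < knots[0]
    right = t > knots[-1]
    disp[left] = speed[0] * (t[left] - knots[0])
    disp[right] = seg_disp[-1] + speed[-1] * (t[right] - knots[-1])
    return disp


def _session_true_angle_values(
    angle_curves: dict[tuple[str, str], np.ndarray],
    config: SyntheticCohortConfig,
    session_true_stp: dict[str, float],
) -> dict[str, float]:
    """Extract every registry variable from the session-true curves."""
    from .features import REGISTRY, build_phase_windows, extract_discrete

    T = session_true_stp["stride_length"] / session_true_stp["gait_speed"]
    to_phase = session_true_stp["stance_time"] / T
    contra_to_phase = session_true_stp["dls1_time"] / T
    contra_ic_phase = (session_true_stp["stance_time"] - session_true_stp["dls2_time"]) / T
    windows = build_phase_windows(to_phase, contra_ic_phase, contra_to_phase)
    grid = warp_phase(np.arange(101) / 100.0, to_phase)
    out = {}
    for spec in REGISTRY:
        curve = joint_angle_template(
            spec.joint, spec.plane, grid, config.template(spec.joint, spec.plane)
        ) + eval_error_curve(angle_curves[(spec.joint, spec.plane)], grid)
        out[spec.key] = extract_discrete(curve, spec, windows)
    return out


def generate_cohort(config: SyntheticCohortConfig) -> tuple[list[MotionTrial], GroundTruth]:
    """Generate all trials of a two-session cohort plus the ground truth.

    Identical config and seed give bit-identical output.
    """
    trials: list[MotionTrial] = []
    events: dict[str, dict] = {}
    session_rows = []
    stride_rows: list[dict] = []

    for i in range(config.n_subjects):
        subject_id = f"S{i + 1:02d}"
        srng = _subject_rng(config.seed, i)
        subj_stp_eff = {
            var: config.stp_sd("subject", var) * srng.standard_normal()
            for var in STP_PRIMITIVES
        }
        subj_angle = {
            (j, p): draw_error_curve(srng, config.angle_sd("subject", j, p))
            for j in JOINTS for p in PLANES
        }
        for session in (1, 2):
            rng = _session_rng(config.seed, i, session)
            sess_stp_eff = {
                var: config.stp_sd("session", var) * rng.standard_normal()
                for var in STP_PRIMITIVES
            }
            sess_angle = {
                key: subj_angle[key] + draw_error_curve(rng, config.angle_sd("session", *key))
                for key in subj_angle
            }
            session_true = _session_true_stp(subj_stp_eff, sess_stp_eff, config)
            derived = _derived_stp(session_true, config.leg_length)
            for var, val in derived.items():
                session_rows.append(
                    {"subject_id": subject_id, "session": session, "task": config.task,
                     "variable": var, "value": val}
                )
            for var, val in _session_true_angle_values(sess_angle, config, session_true).items():
                session_rows.append(
                    {"subject_id": subject_id, "session": session, "task": config.task,
                     "variable": var, "value": val}
                )
            for pass_index in range(config.passes_per_session):
                trial, gt = _generate_pass(
                    config, i, subject_id, session, pass_index,
                    session_true, sess_angle, stride_rows,
                )
                trials.append(trial)
                events[trial.trial_id] = gt

    ground_truth = GroundTruth(
        events=events,
        session_values=pd.DataFrame(session_rows),
        stride_draws=pd.DataFrame(stride_rows),
    )
    return trials, ground_truth
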