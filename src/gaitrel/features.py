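"""Discrete kinematic variables from normalized gait-cycle curves.

Each variable is a reducer (max, min, value-at-point, or range) applied to a
phase window of the 101-point normalized curve.  The registry covers the
standard clinical set: 12 sagittal, 11 frontal and 9 transverse variables
across hip, knee and ankle.

Sign conventions follow the angle conventions of :mod:`gaitrel.trial`:
extension / abduction / eversion / external-rotation / plantarflexion
extrema are signed minima of the curve (no absolute values are taken), so a
curve that never crosses zero still reports its signed extremum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .events import NormalizedStrideSet

#: phase grid of the normalized gait cycle (1% steps)
PHASE_GRID = np.arange(101) / 100.0
_EPS = 1e-9


class StrideRejectedError(ValueError):
    """Contralateral events are out of order for this stride."""


class EmptyWindowError(ValueError):
    """A phase window contains no normalized samples."""


@dataclass(frozen=True)
class PhaseWindows:
    """Phase landmarks and windows of one stride (fractions of the cycle).

    ``dls1 + sls + dls2`` partitions stance exactly; ``midstance`` is the
    midpoint of [0, TO] and ``midswing`` the midpoint of [TO, 1].  The
    stance-to-swing (ST/SW) window, used for the plantarflexion extremum
    whose peak sits at/just after toe-off, runs from midstance to
    TO + 20% of swing.
    """

    to: float
    contra_ic: float
    contra_to: float

    def __post_init__(self) -> None:
        if not (0.0 < self.contra_to < self.contra_ic < self.to < 1.0):
            raise StrideRejectedError(
                "contralateral events out of order: expected "
                f"0 < contra_TO ({self.contra_to:.3f}) < contra_IC ({self.contra_ic:.3f})"
                f" < TO ({self.to:.3f}) < 1"
            )

    @property
    def midstance(self) -> float:
        return self.to / 2.0

    @property
    def midswing(self) -> float:
        return (self.to + 1.0) / 2.0

    @property
    def stance(self) -> tuple[float, float]:
        return (0.0, self.to)

    @property
    def swing(self) -> tuple[float, float]:
        return (self.to, 1.0)

    @property
    def st1(self) -> tuple[float, float]:
        return (0.0, self.midstance)

    @property
    def st2(self) -> tuple[float, float]:
        return (self.midstance, self.to)

    @property
    def dls1(self) -> tuple[float, float]:
        return (0.0, self.contra_to)

    @property
    def sls(self) -> tuple[float, float]:
        return (self.contra_to, self.contra_ic)

    @property
    def dls2(self) -> tuple[float, float]:
        return (self.contra_ic, self.to)

    @property
    def stsw(self) -> tuple[float, float]:
        return (self.midstance, self.to + 0.2 * (1.0 - self.to))

    @property
    def full(self) -> tuple[float, float]:
        return (0.0, 1.0)

    def window(self, name: str) -> tuple[float, float]:
        try:
            lo, hi = getattr(self, name)
        except AttributeError:
            raise KeyError(f"unknown phase window {name!r}")
        return lo, hi

    def point(self, name: str) -> float:
        points = {"ic": 0.0, "midstance": self.midstance, "midswing": self.midswing}
        if name not in points:
            raise KeyError(f"unknown phase point {name!r}")
        return points[name]


def build_phase_windows(
    to_phase: float, contra_ic_phase: float, contra_to_phase: float
) -> PhaseWindows:
    """Validate event phases and build the stride's :class:`PhaseWindows`."""
    return PhaseWindows(to=to_phase, contra_ic=contra_ic_phase, contra_to=contra_to_phase)


@dataclass(frozen=True)
class KinematicVariableSpec:
    """One discrete variable: a reducer over a phase window of a curve."""

    name: str
    joint: str
    plane: str
    reducer: str  # "max" | "min" | "value_at" | "range"
    window: str   # window name for max/min, point name for value_at, "full" for range
    sign_interpretation: str = ""

    @property
    def key(self) -> str:
        return f"{self.joint}.{self.plane}.{self.name}"


def _spec(name, joint, plane, reducer, window, sign=""):
    return KinematicVariableSpec(name, joint, plane, reducer, window, sign)


#: the full discrete-variable registry: 12 sagittal + 11 frontal + 9 transverse.
#: Note: ankle frontal "MaxExt_Swing" has no standard definition in the
#: clinical variable set; it is implemented as the signed minimum over swing
#: (eversion-direction extremum) and kept under its reported name rather than
#: silently renamed.
REGISTRY: tuple[KinematicVariableSpec, ...] = (
    # sagittal (flexion/dorsiflexion positive)
    _spec("RoM", "hip", "sagittal", "range", "full"),
    _spec("MaxFlex_Stance", "hip", "sagittal", "max", "stance", "flexion+"),
    _spec("MaxFlex_Swing", "hip", "sagittal", "max", "swing", "flexion+"),
    _spec("MaxExt_Stance", "hip", "sagittal", "min", "stance", "extension-"),
    _spec("RoM", "knee", "sagittal", "range", "full"),
    _spec("MaxFlex_ST1", "knee", "sagittal", "max", "st1", "flexion+"),
    _spec("MaxFlex_Swing", "knee", "sagittal", "max", "swing", "flexion+"),
    _spec("MaxExt_Stance", "knee", "sagittal", "min", "stance", "extension-"),
    _spec("RoM", "ankle", "sagittal", "range", "full"),
    _spec("InitialContact", "ankle", "sagittal", "value_at", "ic", "dorsiflexion+"),
    _spec("MaxDorsiflexion_ST2", "ankle", "sagittal", "max", "st2", "dorsiflexion+"),
    _spec("MaxPlantarflexion_STSW", "ankle", "sagittal", "min", "stsw", "plantarflexion-"),
    # frontal (adduction/varus/inversion positive)
    _spec("RoM", "hip", "frontal", "range", "full"),
    _spec("MaxAdd_DLS1", "hip", "frontal", "max", "dls1", "adduction+"),
    _spec("MaxAbd_Swing", "hip", "frontal", "min", "swing", "abduction-"),
    _spec("RoM", "knee", "frontal", "range", "full"),
    _spec("MidStance", "knee", "frontal", "value_at", "midstance"),
    _spec("MaxVarus_Swing", "knee", "frontal", "max", "swing", "varus+"),
    _spec("RoM", "ankle", "frontal", "range", "full"),
    _spec("InitialContact", "ankle", "frontal", "value_at", "ic", "inversion+"),
    _spec("MaxInv_Swing", "ankle", "frontal", "max", "swing", "inversion+"),
    _spec("MaxEv_ST1", "ankle", "frontal", "min", "st1", "eversion-"),
    _spec("MaxExt_Swing", "ankle", "frontal", "min", "swing", "eversion-direction extremum (ambiguous source definition)"),
    # transverse (internal rotation positive)
    _spec("RoM", "hip", "transverse", "range", "full"),
    _spec("MaxIntRot_ST1", "hip", "transverse", "max", "st1", "internal+"),
    _spec("MaxExtRot_ST2", "hip", "transverse", "min", "st2", "external-"),
    _spec("RoM", "knee", "transverse", "range", "full"),
    _spec("MidStance", "knee", "transverse", "value_at", "midstance"),
    _spec("MidSwing", "knee", "transverse", "value_at", "midswing"),
    _spec("RoM", "ankle", "transverse", "range", "full"),
    _spec("MaxIntRot_ST1", "ankle", "transverse", "max", "st1", "internal+"),
    _spec("MaxExtRot_Swing", "ankle", "transverse", "min", "swing", "external-"),
)

REGISTRY_KEYS: tuple[str, ...] = tuple(s.key for s in REGISTRY)


def registry_to_yaml() -> str:
    """Serialize the registry (for user extension/inspection)."""
    import yaml

    return yaml.safe_dump(
        [
            {"name": s.name, "joint": s.joint, "plane": s.plane,
             "reducer": s.reducer, "window": s.window,
             "sign_interpretation": s.sign_interpretation}
            for s in REGISTRY
        ],
        sort_keys=False,
    )


def extract_discrete(
    curve: np.ndarray, spec: KinematicVariableSpec, windows: PhaseWindows
) -> float:
    """Apply ``spec``'s reducer to the curve samples in its phase window.

    Window endpoints are included; ``value_at`` takes the sample nearest the
    named phase point (the phase grid is 1% steps, so no second
    interpolation); ``range`` is max minus min over the full cycle.
    """
    curve = np.asarray(curve, dtype=float)
    if curve.shape[0] != 101:
        raise ValueError(f"curve must have 101 points, got {curve.shape[0]}")
    if spec.reducer == "range":
        return float(curve.max() - curve.min())
    if spec.reducer == "value_at":
        idx = int(round(windows.point(spec.window) * 100))
        return float(curve[min(max(idx, 0), 100)])
    lo, hi = windows.window(spec.window)
    mask = (PHASE_GRID >= lo - _EPS) & (PHASE_GRID <= hi + _EPS)
    if not mask.any():
        raise EmptyWindowError(
            f"phase window {spec.window!r} = [{lo:.3f}, {hi:.3f}] contains no samples"
            f" for variable {spec.key}"
        )
    segment = curve[mask]
    if spec.reducer == "max":
        return float(segment.max())
    if spec.reducer == "min":
        return float(segment.min())
    raise ValueError(f"unknown reducer {spec.reducer!r}")


def feature_table(
    curve_sets: dict[tuple[str, str], NormalizedStrideSet],
    registry: tuple[KinematicVariableSpec, ...] = REGISTRY,
) -> pd.DataFrame:
    """Per-stride values of every registry variable (strides x variables).

    ``curve_sets`` maps (joint, plane) to the normalized curves of the
    analysis side.  Strides whose contralateral phases are missing or out of
    order are skipped (their rows are absent) and counted in the table's
    ``attrs["n_rejected"]``.
    """
    any_set = next(iter(curve_sets.values()))
    n = any_set.n_strides
    rows = {}
    n_rejected = 0
    for i in range(n):
        try:
            windows = build_phase_windows(
                float(any_set.to_phase[i]),
                float(any_set.contra_ic_phase[i]),
                float(any_set.contra_to_phase[i]),
            )
        except (StrideRejectedError, ValueError):
            n_rejected += 1
            continue
        row = {}
        for spec in registry:
            curve = curve_sets[(spec.joint, spec.plane)].curves[i]
            row[spec.key] = extract_discrete(curve, spec, windows)
        rows[i] = row
    df = pd.DataFrame.from_dict(rows, orient="index", dtype=float)
    if df.empty:
        df = pd.DataFrame(columns=[s.key for s in registry], dtype=float)
    df.attrs["n_rejected"] = n_rejected
    return df
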