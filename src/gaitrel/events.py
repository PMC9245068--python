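"""Coordinate-based gait event detection, stride segmentation, normalization.

Initial contact (IC) is detected at local maxima of the progression-aligned
heel-minus-sacrum AP distance; toe-off (TO) at local minima of the
toe-minus-sacrum AP distance.  Strides are the windows between consecutive
ipsilateral ICs, carry the ipsilateral TO and the contralateral IC/TO that
fall inside them, and are time-normalized to 101 points (0-100% of the gait
cycle).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, filtfilt

from .trial import JOINTS, MotionTrial, PLANES, other_side

logger = logging.getLogger("gaitrel")


class InsufficientStridesError(ValueError):
    """Fewer than two initial contacts were detected."""


@dataclass
class GaitEventSet:
    """Per-side IC and TO sample indices, temporally ordered and alternating."""

    side: str
    ic: np.ndarray
    to: np.ndarray

    def __post_init__(self) -> None:
        self.ic = np.asarray(self.ic, dtype=int)
        self.to = np.asarray(self.to, dtype=int)
        if np.any(np.diff(self.ic) <= 0) or np.any(np.diff(self.to) <= 0):
            raise ValueError("event indices must be strictly increasing")


@dataclass(frozen=True)
class Stride:
    """One gait cycle on the analysis side, bounded by consecutive ICs."""

    start: int
    end: int
    to: int
    sampling_rate: float
    contra_ic: int | None = None
    contra_to: int | None = None

    @property
    def n_samples(self) -> int:
        return self.end - self.start

    @property
    def stride_time(self) -> float:
        return self.n_samples / self.sampling_rate

    def phase(self, index: int) -> float:
        return (index - self.start) / self.n_samples

    @property
    def stance_fraction(self) -> float:
        return self.phase(self.to)

    @property
    def to_phase(self) -> float:
        return self.phase(self.to)

    @property
    def contra_ic_phase(self) -> float | None:
        return None if self.contra_ic is None else self.phase(self.contra_ic)

    @property
    def contra_to_phase(self) -> float | None:
        return None if self.contra_to is None else self.phase(self.contra_to)


@dataclass(frozen=True)
class DroppedStride:
    start: int
    end: int
    reason: str


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

def lowpass(x: np.ndarray, sampling_rate: float, cutoff: float = 6.0, order: int = 4) -> np.ndarray:
    """Zero-lag low-pass Butterworth filter (applied forward and backward)."""
    b, a = butter(order, cutoff / (sampling_rate / 2.0), btype="low")
    return filtfilt(b, a, x)


def filter_trial(trial: MotionTrial, cutoff: float = 6.0, order: int = 4) -> MotionTrial:
    """Return a copy with all angle and landmark channels low-pass filtered."""
    out = trial.copy()
    for key, arr in out.angles.items():
        out.angles[key] = lowpass(arr, trial.sampling_rate, cutoff, order)
    for key, arr in out.landmarks.items():
        out.landmarks[key] = lowpass(arr, trial.sampling_rate, cutoff, order)
    return out


# ---------------------------------------------------------------------------
# Peak finding
# ---------------------------------------------------------------------------

def _local_maxima(x: np.ndarray) -> np.ndarray:
    """Strict interior local maxima; plateaus count once at their first index."""
    n = len(x)
    out = []
    i = 1
    while i < n - 1:
        if x[i] > x[i - 1]:
            j = i
            while j < n - 1 and x[j + 1] == x[j]:
                j += 1
            if j < n - 1 and x[j + 1] < x[j]:
                out.append(i)
            i = j + 1
        else:
            i += 1
    return np.array(out, dtype=int)


def find_extrema(x: np.ndarray, refractory_fraction: float = 0.4) -> np.ndarray:
    """Local maxima with refractory suppression.

    Candidates closer than ``refractory_fraction`` times the median
    inter-candidate interval are suppressed keeping the larger-magnitude one;
    ties break toward the earlier index.
    """
    cand = _local_maxima(np.asarray(x, dtype=float))
    if len(cand) < 2:
        return cand
    window = refractory_fraction * float(np.median(np.diff(cand)))
    order = sorted(cand, key=lambda c: (-x[c], c))
    accepted: list[int] = []
    for c in order:
        if all(abs(c - a) >= window for a in accepted):
            accepted.append(int(c))
    return np.array(sorted(accepted), dtype=int)


def _one_per_interval(ic: np.ndarray, cand: np.ndarray, magnitude: np.ndarray) -> np.ndarray:
    """Keep at most one candidate per inter-IC interval (largest magnitude).

    Intervals are (-inf, ic[0]), (ic[0], ic[1]), ..., (ic[-1], +inf) with the
    bounding ICs excluded, which enforces the IC/TO alternation invariant.
    """
    kept = []
    bins = np.searchsorted(ic, cand)  # candidates at an IC index: excluded below
    for b in np.unique(bins):
        group = [c for c, bb in zip(cand, bins) if bb == b and c not in ic]
        if group:
            kept.append(max(group, key=lambda c: (magnitude[c], -c)))
    return np.array(sorted(kept), dtype=int)


# ---------------------------------------------------------------------------
# Detection
# ---------------------------------------------------------------------------

def _progression_sign(trial: MotionTrial) -> int:
    if trial.progression_sign in (1, -1):
        return trial.progression_sign
    sac = trial.landmark("pelvis", "sacrum", "AP")
    return 1 if sac[-1] >= sac[0] else -1


def detect_events(
    trial: MotionTrial,
    side: str,
    refractory_fraction: float = 0.4,
    lowpass_cutoff: float | None = None,
) -> GaitEventSet:
    """Detect IC and TO on one side by the coordinate-based method.

    IC: local maxima of ``sign * (heel_AP - sacrum_AP)``;
    TO: local minima of ``sign * (toe_AP - sacrum_AP)``.
    Detection is invariant to adding a constant to all AP channels.  Set
    ``lowpass_cutoff`` to filter the three AP channels first (6 Hz zero-lag
    Butterworth is conventional for gait landmarks).
    """
    heel = trial.landmark(side, "heel", "AP")
    toe = trial.landmark(side, "toe", "AP")
    sac = trial.landmark("pelvis", "sacrum", "AP")
    if lowpass_cutoff is not None:
        heel = lowpass(heel, trial.sampling_rate, lowpass_cutoff)
        toe = lowpass(toe, trial.sampling_rate, lowpass_cutoff)
        sac = lowpass(sac, trial.sampling_rate, lowpass_cutoff)
    sign = _progression_sign(trial)
    d_heel = sign * (heel - sac)
    d_toe = sign * (toe - sac)

    ic = find_extrema(d_heel, refractory_fraction)
    if len(ic) < 2:
        raise InsufficientStridesError(
            f"insufficient strides: only {len(ic)} initial contact(s) detected on side {side}"
        )
    to_cand = find_extrema(-d_toe, refractory_fraction)
    to = _one_per_interval(ic, to_cand, -d_toe)
    return GaitEventSet(side=side, ic=ic, to=to)


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------

def segment_strides(
    trial: MotionTrial,
    ipsi: GaitEventSet,
    contra: GaitEventSet | None = None,
    quality_filter: bool = True,
    stance_fraction_bounds: tuple[float, float] = (0.4, 0.8),
    max_stride_time_deviation: float = 0.4,
) -> tuple[list[Stride], list[DroppedStride]]:
    """Pair events into strides; drop and log windows that fail checks.

    One window per consecutive ipsilateral IC pair.  Each window must contain
    exactly the ipsilateral TO; when ``contra`` is given it must also contain
    one contralateral TO and one contralateral IC, in the order
    IC < contra_TO < contra_IC < TO < next IC.  Quality checks (on by
    default) drop strides whose stride time deviates more than 40% from the
    trial median or whose stance fraction falls outside (0.4, 0.8).
    """
    fs = trial.sampling_rate
    strides: list[Stride] = []
    dropped: list[DroppedStride] = []

    def _inside(events: np.ndarray, a: int, b: int) -> list[int]:
        return [int(e) for e in events if a < e < b]

    windows = list(zip(ipsi.ic[:-1], ipsi.ic[1:]))
    median_time = float(np.median(np.diff(ipsi.ic))) / fs if len(windows) else 0.0

    for a, b in windows:
        a, b = int(a), int(b)
        tos = _inside(ipsi.to, a, b)
        if len(tos) != 1:
            dropped.append(DroppedStride(a, b, "missing_ipsilateral_to"))
            continue
        to = tos[0]
        c_ic = c_to = None
        if contra is not None:
            c_ics = _inside(contra.ic, a, b)
            c_tos = _inside(contra.to, a, b)
            if len(c_tos) != 1:
                dropped.append(DroppedStride(a, b, "missing_contralateral_to"))
                continue
            if len(c_ics) != 1:
                dropped.append(DroppedStride(a, b, "missing_contralateral_ic"))
                continue
            c_ic, c_to = c_ics[0], c_tos[0]
            if not (a < c_to < c_ic < to < b):
                dropped.append(DroppedStride(a, b, "event_order"))
                continue
        stride = Stride(start=a, end=b, to=to, sampling_rate=fs,
                        contra_ic=c_ic, contra_to=c_to)
        if quality_filter:
            if abs(stride.stride_time - median_time) > max_stride_time_deviation * median_time:
                dropped.append(DroppedStride(a, b, "stride_time_outlier"))
                continue
            lo, hi = stance_fraction_bounds
            if not (lo < stride.stance_fraction < hi):
                dropped.append(DroppedStride(a, b, "stance_fraction_out_of_range"))
                continue
        strides.append(stride)

    for d in dropped:
        logger.info(
            "dropped stride trial=%s window=[%d,%d] reason=%s",
            trial.trial_id, d.start, d.end, d.reason,
        )
    return strides, dropped


# ---------------------------------------------------------------------------
# Time normalization
# ---------------------------------------------------------------------------

def time_normalize(y: np.ndarray, n_points: int = 101) -> np.ndarray:
    """Linearly resample a stride window onto ``n_points`` equal phases.

    Endpoints are preserved exactly.
    """
    y = np.asarray(y, dtype=float)
    if y.shape[0] < 2:
        raise ValueError(f"window must have at least 2 samples, got {y.shape[0]}")
    x = np.linspace(0.0, y.shape[0] - 1, n_points)
    return np.interp(x, np.arange(y.shape[0]), y)


@dataclass
class NormalizedStrideSet:
    """Strides x 101-point curves for one signal, with per-stride phases."""

    signal_id: tuple
    curves: np.ndarray
    stance_fraction: np.ndarray
    to_phase: np.ndarray
    contra_ic_phase: np.ndarray
    contra_to_phase: np.ndarray

    def __post_init__(self) -> None:
        if self.curves.ndim != 2 or self.curves.shape[1] != 101:
            raise ValueError("curves must be (n_strides, 101)")
        if np.any(self.stance_fraction <= 0) or np.any(self.stance_fraction >= 1):
            raise ValueError("stance_fraction must lie in (0, 1)")

    @property
    def n_strides(self) -> int:
        return self.curves.shape[0]


def normalize_trial(
    trial: MotionTrial,
    strides: list[Stride],
    side: str,
    n_points: int = 101,
) -> dict[tuple[str, str], NormalizedStrideSet]:
    """Time-normalize every (joint, plane) angle channel of ``side``.

    Stride windows include both bounding ICs.  Returns one
    :class:`NormalizedStrideSet` per (joint, plane).
    """
    to_phase = np.array([s.to_phase for s in strides])
    c_ic = np.array([np.nan if s.contra_ic_phase is None else s.contra_ic_phase for s in strides])
    c_to = np.array([np.nan if s.contra_to_phase is None else s.contra_to_phase for s in strides])
    out = {}
    for joint in JOINTS:
        for plane in PLANES:
            sig = trial.angle(side, joint, plane)
            curves = np.vstack(
                [time_normalize(sig[s.start:s.end + 1], n_points) for s in strides]
            ) if strides else np.empty((0, n_points))
            out[(joint, plane)] = NormalizedStrideSet(
                signal_id=(side, joint, plane),
                curves=curves,
                stance_fraction=to_phase.copy(),
                to_phase=to_phase.copy(),
                contra_ic_phase=c_ic.copy(),
                contra_to_phase=c_to.copy(),
            )
    return out
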