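"""Trial CSV dialect, cohort files, and the optional C3D adapter.

A trial file is a commented ``key: value`` header block followed by one CSV
row per sample.  Angle columns are named ``<side>.<joint>.<plane>.deg``,
landmark columns ``<side>.<landmark>.<axis>.m`` and
``pelvis.sacrum.<axis>.m``; the first column is ``time.s``.  Floats are
written with Python's shortest round-trip representation, so
``write(read(file))`` is bit-identical for canonical files.
"""

from __future__ import annotations

import csv
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import GroundTruth
from .trial import ANGLE_KEYS, LANDMARK_KEYS, MotionTrial

HEADER_KEYS = (
    "subject_id", "session", "task", "sampling_rate",
    "leg_length", "dominant_side", "progression_sign", "pass_index",
)


class SchemaError(ValueError):
    """A trial file violates the dialect."""


def _angle_column(key: tuple[str, str, str]) -> str:
    side, joint, plane = key
    return f"{side}.{joint}.{plane}.deg"


def _landmark_column(key: tuple[str, str, str]) -> str:
    segment, name, axis = key
    return f"{segment}.{name}.{axis}.m"


ANGLE_COLUMNS = {_angle_column(k): k for k in ANGLE_KEYS}
LANDMARK_COLUMNS = {_landmark_column(k): k for k in LANDMARK_KEYS}
MANDATORY_COLUMNS = ("time.s", *ANGLE_COLUMNS, *LANDMARK_COLUMNS)


def write_trial(trial: MotionTrial, path) -> None:
    path = Path(path)
    columns = ["time.s"]
    arrays = [trial.times()]
    for key in ANGLE_KEYS:
        columns.append(_angle_column(key))
        arrays.append(trial.angles[key])
    for key in LANDMARK_KEYS:
        columns.append(_landmark_column(key))
        arrays.append(trial.landmarks[key])
    for name in sorted(trial.extra):
        columns.append(name)
        arrays.append(trial.extra[name])

    with open(path, "w", newline="") as fh:
        for key in HEADER_KEYS:
            fh.write(f"# {key}: {getattr(trial, key)}\n")
        writer = csv.writer(fh)
        writer.writerow(columns)
        for row in zip(*arrays):
            writer.writerow([repr(float(v)) for v in row])


def read_trial(path) -> MotionTrial:
    path = Path(path)
    header: dict[str, str] = {}
    with open(path, newline="") as fh:
        pos = 0
        for line in fh:
            if not line.startswith("#"):
                break
            pos += len(line)
            k, _, v = line[1:].partition(":")
            header[k.strip()] = v.strip()
        fh.seek(pos)
        reader = csv.reader(fh)
        try:
            columns = next(reader)
        except StopIteration:
            raise SchemaError(f"{path}: no column header row")
        data = [[float(v) for v in row] for row in reader if row]

    missing_meta = [k for k in ("subject_id", "session", "task", "sampling_rate") if k not in header]
    if missing_meta:
        raise SchemaError(f"{path}: missing header keys {missing_meta}")

    table = {c: np.array([row[i] for row in data]) for i, c in enumerate(columns)}
    for col in MANDATORY_COLUMNS:
        if col not in table:
            raise SchemaError(f"{path}: missing mandatory channel column {col!r}")

    t = table["time.s"]
    if np.any(np.diff(t) <= 0):
        raise SchemaError(f"{path}: time column is not strictly increasing")

    known = set(MANDATORY_COLUMNS)
    extra = {c: table[c] for c in columns if c not in known}
    if extra:
        warnings.warn(
            f"{path.name}: ignoring unknown columns {sorted(extra)} (preserved on write)",
            stacklevel=2,
        )

    return MotionTrial(
        subject_id=header["subject_id"],
        session=int(header["session"]),
        task=header["task"],
        sampling_rate=float(header["sampling_rate"]),
        angles={key: table[col] for col, key in ANGLE_COLUMNS.items()},
        landmarks={key: table[col] for col, key in LANDMARK_COLUMNS.items()},
        progression_sign=int(header.get("progression_sign", 0)),
        leg_length=float(header.get("leg_length", 0.84)),
        dominant_side=header.get("dominant_side", "R"),
        pass_index=int(header.get("pass_index", 0)),
        extra=extra,
    )


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

def write_cohort(trials: list[MotionTrial], ground_truth: GroundTruth | None, out_dir) -> None:
    """Write trial CSVs plus ground-truth events/session-values CSVs."""
    out_dir = Path(out_dir)
    (out_dir / "trials").mkdir(parents=True, exist_ok=True)
    for trial in trials:
        write_trial(trial, out_dir / "trials" / f"{trial.trial_id}.csv")
    if ground_truth is None:
        return
    rows = []
    for trial_id, sides in ground_truth.events.items():
        for side, ev in sides.items():
            for kind in ("ic", "to"):
                for idx in ev[kind]:
                    rows.append({"trial_id": trial_id, "side": side,
                                 "event": kind, "sample": int(idx)})
    pd.DataFrame(rows).to_csv(out_dir / "ground_truth_events.csv", index=False)
    ground_truth.session_values.to_csv(out_dir / "ground_truth_sessions.csv", index=False)
    ground_truth.stride_draws.to_csv(out_dir / "ground_truth_strides.csv", index=False)


def read_cohort(in_dir) -> list[MotionTrial]:
    in_dir = Path(in_dir)
    trial_dir = in_dir / "trials" if (in_dir / "trials").is_dir() else in_dir
    paths = sorted(trial_dir.glob("*.csv"))
    if not paths:
        raise SchemaError(f"no trial CSVs found under {in_dir}")
    return [read_trial(p) for p in paths]


def write_events_csv(records: list[dict], path) -> None:
    """Events CSV: trial, side, event type, sample index, time in seconds."""
    pd.DataFrame(records, columns=["trial_id", "side", "event", "sample", "time_s"]).to_csv(
        path, index=False
    )


# ---------------------------------------------------------------------------
# C3D adapter (optional dependency)
# ---------------------------------------------------------------------------

#: default mapping from our landmark keys to C3D point labels
DEFAULT_C3D_LABELS = {
    ("L", "heel"): "LHEE", ("R", "heel"): "RHEE",
    ("L", "toe"): "LTOE", ("R", "toe"): "RTOE",
    ("pelvis", "sacrum"): "SACR",
}


def read_c3d(path, label_map: dict | None = None, **trial_meta) -> MotionTrial:
    """Read landmark trajectories from a C3D file (requires ``ezc3d``).

    ``label_map`` maps ``(segment, landmark)`` keys to C3D point labels;
    positions in millimeters are converted to meters.  Angle channels must be
    supplied separately (C3D point files carry markers, not joint angles);
    this adapter fills angle channels with zeros unless provided in
    ``trial_meta['angles']``.
    """
    try:
        import ezc3d
    except ImportError as exc:  # pragma: no cover - exercised when ezc3d is absent
        raise ImportError(
            "reading C3D files requires the optional dependency 'ezc3d' "
            "(pip install ezc3d); the core CSV pipeline does not need it"
        ) from exc

    labels_wanted = {**DEFAULT_C3D_LABELS, **(label_map or {})}
    c3d = ezc3d.c3d(str(path))
    labels = [l.strip() for l in c3d["parameters"]["POINT"]["LABELS"]["value"]]
    rate = float(c3d["parameters"]["POINT"]["RATE"]["value"][0])
    points = c3d["data"]["points"]  # (4, n_points, n_frames)
    units = c3d["parameters"]["POINT"].get("UNITS", {}).get("value", ["mm"])
    scale = 1e-3 if units and units[0].lower().startswith("mm") else 1.0

    landmarks = {}
    for (segment, name), label in labels_wanted.items():
        if label not in labels:
            raise SchemaError(
                f"C3D point label {label!r} for {segment}/{name} not found; "
                f"available labels: {labels}"
            )
        i = labels.index(label)
        xyz = points[:3, i, :] * scale
        for axis, row in zip(("AP", "ML", "vertical"), xyz):
            landmarks[(segment, name, axis)] = np.asarray(row, dtype=float)

    n = next(iter(landmarks.values())).shape[0]
    angles = trial_meta.pop("angles", None) or {
        key: np.zeros(n) for key in ANGLE_KEYS
    }
    meta = {"subject_id": "c3d", "session": 1, "task": "SSWS"}
    meta.update(trial_meta)
    return MotionTrial(sampling_rate=rate, angles=angles, landmarks=landmarks, **meta)
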