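"""Between-session absolute reliability: RMSD, SEM, SEM%, ICC cross-check.

The unit of analysis is one value per subject per session: per-stride values
are averaged within session (after matching stride counts between sessions),
giving an ``n_subjects x 2`` matrix per variable.  The standard error of
measurement is the square root of the error mean square of a two-way
subjects x sessions ANOVA with one observation per cell; for two sessions
this is algebraically ``SD(d)/sqrt(2)`` where ``d`` is the per-subject
between-session difference, and both forms are computed and checked against
each other on every call.  Full-curve reliability is the root-mean-square
difference between a subject's two session ensemble-average curves, averaged
over subjects per joint/plane.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import REGISTRY
from .spatiotemporal import STP_UNITS, STP_VARIABLES
from .trial import JOINTS, PLANES

logger = logging.getLogger("gaitrel")

#: angle errors at or below this many degrees are conventionally acceptable
ACCEPTABLE_ERROR_DEG = 5.0


def classify_error(value_deg: float, acceptable_max: float = ACCEPTABLE_ERROR_DEG) -> str:
    return "acceptable" if value_deg <= acceptable_max else "needs caution"


# ---------------------------------------------------------------------------
# Curve statistics
# ---------------------------------------------------------------------------

def ensemble_average(curves: np.ndarray) -> np.ndarray:
    """Pointwise mean curve across a subject's within-session strides."""
    curves = np.asarray(curves, dtype=float)
    if curves.ndim != 2 or curves.shape[0] == 0:
        raise ValueError("need at least one stride curve")
    return curves.mean(axis=0)


def rmsd_between_sessions(curve1: np.ndarray, curve2: np.ndarray) -> float:
    """Root-mean-square difference between two session ensemble curves."""
    curve1 = np.asarray(curve1, dtype=float)
    curve2 = np.asarray(curve2, dtype=float)
    if curve1.shape != curve2.shape:
        raise ValueError(f"curve length mismatch: {curve1.shape} vs {curve2.shape}")
    return float(np.sqrt(np.mean((curve1 - curve2) ** 2)))


def cohort_rmsd(session1_curves: list[np.ndarray], session2_curves: list[np.ndarray]) -> float:
    """Mean over subjects of the per-subject between-session RMSD."""
    if len(session1_curves) != len(session2_curves) or not session1_curves:
        raise ValueError("need matching non-empty per-subject curve lists")
    return float(np.mean([
        rmsd_between_sessions(c1, c2) for c1, c2 in zip(session1_curves, session2_curves)
    ]))


# ---------------------------------------------------------------------------
# SEM
# ---------------------------------------------------------------------------

def _anova_two_way(matrix: np.ndarray) -> tuple[float, float, float]:
    """(MS_subjects, MS_error, pooled variance with session effect removed).

    One observation per (subject, session) cell.  The pooled variance is
    (SS_subjects + SS_error) / (k (n-1)) -- the variance base under which
    Weir's SD * sqrt(1 - ICC(3,1)) identity reproduces sqrt(MS_error)
    exactly.
    """
    y = np.asarray(matrix, dtype=float)
    n, k = y.shape
    if n < 2 or k < 2:
        raise ValueError(f"need at least 2 subjects and 2 sessions, got {y.shape}")
    row = y.mean(axis=1, keepdims=True)
    col = y.mean(axis=0, keepdims=True)
    # grand mean computed as the mean of column means so that the residual
    # vanishes exactly (not just to rounding) when sessions are identical
    grand = col.mean()
    ss_subj = float(k * np.sum((row - grand) ** 2))
    ss_err = float(np.sum((y - row - col + grand) ** 2))
    ms_subj = ss_subj / (n - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    pooled_var = (ss_subj + ss_err) / (k * (n - 1))
    return ms_subj, ms_err, pooled_var


def sem_from_differences(matrix: np.ndarray) -> float:
    """SD of per-subject session differences over sqrt(2) (two sessions)."""
    y = np.asarray(matrix, dtype=float)
    if y.shape[1] != 2:
        raise ValueError("difference form requires exactly 2 sessions")
    d = y[:, 1] - y[:, 0]
    return float(np.std(d, ddof=1) / math.sqrt(2.0))


def sem_anova(matrix: np.ndarray) -> float:
    """SEM = sqrt(MS_error) of the subjects x sessions ANOVA.

    For two sessions the result is checked against the equivalent
    ``SD(d)/sqrt(2)`` form; disagreement beyond numerical tolerance raises.
    """
    y = np.asarray(matrix, dtype=float)
    _, ms_err, _ = _anova_two_way(y)
    sem = math.sqrt(ms_err)
    if y.shape[1] == 2:
        alt = sem_from_differences(y)
        if abs(sem - alt) > 1e-9 * max(1.0, sem):
            raise AssertionError(
                f"ANOVA and difference forms of SEM disagree: {sem} vs {alt}"
            )
    return sem


def sem_percent(sem: float, session1_mean: float, session2_mean: float) -> float:
    """SEM as a percentage of the grand mean of the two session means."""
    grand = (session1_mean + session2_mean) / 2.0
    if grand == 0:
        warnings.warn("SEM% undefined: grand mean is zero", stacklevel=2)
        return float("nan")
    return 100.0 * sem / abs(grand)


def icc_cross_check(matrix: np.ndarray) -> tuple[float, float]:
    """ICC(3,1) and the SEM implied by it, ``SD_pooled * sqrt(1 - ICC)``.

    With the pooled SD computed on the matching variance decomposition
    (session main effect removed), the implied SEM equals sqrt(MS_error)
    algebraically; this serves as an internal consistency oracle.  Raises on
    degenerate zero-variance input.
    """
    ms_subj, ms_err, pooled_var = _anova_two_way(matrix)
    k = np.asarray(matrix).shape[1]
    denom = ms_subj + (k - 1) * ms_err
    if denom == 0:
        raise ValueError("ICC undefined for zero-variance matrix")
    icc = (ms_subj - ms_err) / denom
    sem_icc = math.sqrt(max(pooled_var, 0.0)) * math.sqrt(max(1.0 - icc, 0.0))
    return float(icc), float(sem_icc)


# ---------------------------------------------------------------------------
# Subject-session assembly
# ---------------------------------------------------------------------------

@dataclass
class SubjectSessionData:
    """One subject-session: per-stride feature table + normalized curves."""

    subject_id: str
    session: int
    task: str
    features: pd.DataFrame  # strides x variables (kinematic keys + STP names)
    curves: dict[tuple[str, str], np.ndarray]  # (joint, plane) -> (strides, 101)

    @property
    def n_strides(self) -> int:
        return len(self.features)


def match_stride_counts(
    data1: SubjectSessionData, data2: SubjectSessionData
) -> tuple[SubjectSessionData, SubjectSessionData]:
    """Truncate both sessions to the earliest min(n1, n2) valid strides.

    Deterministic (no subsampling), so reports are seed-free reproducible.
    """
    n = min(data1.n_strides, data2.n_strides)
    out = []
    for d in (data1, data2):
        out.append(SubjectSessionData(
            subject_id=d.subject_id,
            session=d.session,
            task=d.task,
            features=d.features.iloc[:n].reset_index(drop=True),
            curves={k: v[:n] for k, v in d.curves.items()},
        ))
    return out[0], out[1]


@dataclass
class ReliabilityReport:
    """Per-variable SEM table and per-joint/plane RMSD table.

    ``variables`` columns: task, joint, plane, name, units, session1_mean,
    session1_sd, session2_mean, session2_sd, sem, sem_pct, n_subjects,
    classification.  ``rmsd`` columns: task, joint, plane, rmsd_deg,
    n_subjects, classification.  Internals keep full precision; rounding
    (SEM to 2 decimals, SEM% to 1) is applied only in formatted output.
    """

    variables: pd.DataFrame
    rmsd: pd.DataFrame
    exclusions: list[dict] = field(default_factory=list)

    def rounded(self) -> "ReliabilityReport":
        v = self.variables.copy()
        for col in ("session1_mean", "session1_sd", "session2_mean", "session2_sd", "sem"):
            v[col] = v[col].round(2)
        v["sem_pct"] = v["sem_pct"].round(1)
        r = self.rmsd.copy()
        r["rmsd_deg"] = r["rmsd_deg"].round(2)
        return ReliabilityReport(variables=v, rmsd=r, exclusions=self.exclusions)

    def to_json(self) -> str:
        rep = self.rounded()
        payload = {
            "variables": rep.variables.replace({np.nan: None}).to_dict(orient="records"),
            "rmsd": rep.rmsd.replace({np.nan: None}).to_dict(orient="records"),
            "exclusions": rep.exclusions,
        }
        return json.dumps(payload, sort_keys=True, indent=1)

    def write(self, out_dir, fmt: str = "csv") -> list[str]:
        """Write one CSV per table analog (plane x task + STP) or one JSON."""
        from pathlib import Path

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        written = []
        if fmt == "json":
            p = out_dir / "reliability_report.json"
            p.write_text(self.to_json())
            return [str(p)]
        rep = self.rounded()
        kin = rep.variables[rep.variables["units"] == "deg"]
        for task in sorted(kin["task"].unique()):
            for plane in PLANES:
                sub = kin[(kin["task"] == task) & (kin["plane"] == plane)]
                if len(sub):
                    p = out_dir / f"kinematics_{plane}_{task.lower()}.csv"
                    sub.drop(columns=["sem_pct"]).to_csv(p, index=False)
                    written.append(str(p))
        stp = rep.variables[rep.variables["units"] != "deg"]
        if len(stp):
            p = out_dir / "spatiotemporal.csv"
            stp.to_csv(p, index=False)
            written.append(str(p))
        if len(rep.rmsd):
            p = out_dir / "rmsd.csv"
            rep.rmsd.to_csv(p, index=False)
            written.append(str(p))
        return written


def _variable_metadata() -> list[dict]:
    meta = []
    for spec in REGISTRY:
        meta.append({"key": spec.key, "joint": spec.joint, "plane": spec.plane,
                     "name": spec.name, "units": "deg"})
    for var in STP_VARIABLES:
        meta.append({"key": var, "joint": "", "plane": "", "name": var,
                     "units": STP_UNITS[var]})
    return meta


def build_report(cohort: list[SubjectSessionData]) -> ReliabilityReport:
    """Assemble the full reliability report from per-subject-session data.

    Stride counts are matched within subject across sessions before
    averaging; subjects missing a session, or missing a variable in either
    session, are dropped per variable and logged.  SEM% is reported for
    spatiotemporal variables only; the acceptability classification applies
    to angle errors (degrees).
    """
    by_key: dict[tuple[str, str, int], SubjectSessionData] = {}
    for d in cohort:
        by_key[(d.task, d.subject_id, d.session)] = d

    tasks = sorted({d.task for d in cohort})
    exclusions: list[dict] = []
    var_rows = []
    rmsd_rows = []

    for task in tasks:
        subjects = sorted({d.subject_id for d in cohort if d.task == task})
        matched: dict[str, tuple[SubjectSessionData, SubjectSessionData]] = {}
        for subj in subjects:
            d1 = by_key.get((task, subj, 1))
            d2 = by_key.get((task, subj, 2))
            if d1 is None or d2 is None or d1.n_strides == 0 or d2.n_strides == 0:
                exclusions.append({"task": task, "subject_id": subj,
                                   "reason": "missing_session"})
                logger.info("excluded subject=%s task=%s reason=missing_session", subj, task)
                continue
            matched[subj] = match_stride_counts(d1, d2)

        # per-variable SEM
        for meta in _variable_metadata():
            key = meta["key"]
            cells = []
            for subj, (d1, d2) in matched.items():
                if key not in d1.features.columns or key not in d2.features.columns:
                    continue
                m1 = d1.features[key].mean()
                m2 = d2.features[key].mean()
                if np.isnan(m1) or np.isnan(m2):
                    exclusions.append({"task": task, "subject_id": subj,
                                       "variable": key, "reason": "missing_variable"})
                    continue
                cells.append((m1, m2))
            if len(cells) < 2:
                continue
            matrix = np.array(cells)
            sem = sem_anova(matrix)
            s1, s2 = matrix[:, 0], matrix[:, 1]
            is_stp = meta["units"] != "deg"
            row = {
                "task": task, "joint": meta["joint"], "plane": meta["plane"],
                "name": meta["name"], "variable": key, "units": meta["units"],
                "session1_mean": float(s1.mean()), "session1_sd": float(s1.std(ddof=1)),
                "session2_mean": float(s2.mean()), "session2_sd": float(s2.std(ddof=1)),
                "sem": sem,
                "sem_pct": sem_percent(sem, float(s1.mean()), float(s2.mean()))
                if is_stp else float("nan"),
                "n_subjects": matrix.shape[0],
                "classification": classify_error(sem) if not is_stp else "",
            }
            var_rows.append(row)

        # per joint/plane cohort RMSD on ensemble-average curves
        for joint in JOINTS:
            for plane in PLANES:
                c1, c2 = [], []
                for subj, (d1, d2) in matched.items():
                    if (joint, plane) not in d1.curves or len(d1.curves[(joint, plane)]) == 0:
                        continue
                    c1.append(ensemble_average(d1.curves[(joint, plane)]))
                    c2.append(ensemble_average(d2.curves[(joint, plane)]))
                if not c1:
                    continue
                value = cohort_rmsd(c1, c2)
                rmsd_rows.append({
                    "task": task, "joint": joint, "plane": plane,
                    "rmsd_deg": value, "n_subjects": len(c1),
                    "classification": classify_error(value),
                })

    return ReliabilityReport(
        variables=pd.DataFrame(var_rows),
        rmsd=pd.DataFrame(rmsd_rows),
        exclusions=exclusions,
    )
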