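"""End-to-end pipeline: trials -> events -> strides -> features -> report."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as gio
from .events import detect_events, filter_trial, normalize_trial, segment_strides
from .features import feature_table
from .reliability import ReliabilityReport, SubjectSessionData, build_report
from .spatiotemporal import compute_stp
from .synthetic import SyntheticCohortConfig, generate_cohort
from .trial import MotionTrial, other_side

logger = logging.getLogger("gaitrel")


@dataclass
class PipelineConfig:
    """Driver configuration; either a synthetic cohort spec or a trial dir.

    ``filter_cutoff`` is the zero-lag Butterworth low-pass cutoff in Hz
    applied to all channels before detection and extraction; ``None``
    disables filtering (synthetic noise-free data needs none).
    """

    synthetic: SyntheticCohortConfig | None = None
    trials_dir: str | None = None
    task: str = "both"
    seed: int = 0
    filter_cutoff: float | None = 6.0
    out_dir: str | None = None
    out_format: str = "csv"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        syn = doc.pop("synthetic", None)
        cfg = cls(**doc)
        if syn is not None:
            if "template_coefficients" in syn:
                syn["template_coefficients"] = {
                    tuple(k.split(".")): v for k, v in syn["template_coefficients"].items()
                }
            cfg.synthetic = SyntheticCohortConfig(**syn)
        return cfg


def process_trial(
    trial: MotionTrial, filter_cutoff: float | None = None
) -> tuple[pd.DataFrame, dict, list]:
    """Run one trial through detection, segmentation and extraction.

    Returns the per-stride feature table (kinematic + spatiotemporal
    columns), the dominant side's normalized curves, and the dropped-stride
    records.
    """
    work = filter_trial(trial, filter_cutoff) if filter_cutoff else trial
    side = trial.dominant_side
    ipsi = detect_events(work, side)
    contra = detect_events(work, other_side(side))
    strides, dropped = segment_strides(work, ipsi, contra)
    curve_sets = normalize_trial(work, strides, side)
    kin = feature_table(curve_sets)
    stp = compute_stp(work, side, strides)
    stp = stp.loc[kin.index]  # keep only strides that passed phase validation
    features = pd.concat([kin, stp], axis=1).reset_index(drop=True)
    curves = {key: cs.curves[kin.index.to_numpy()] for key, cs in curve_sets.items()}
    return features, curves, dropped


def process_cohort(
    trials: list[MotionTrial], filter_cutoff: float | None = None
) -> tuple[list[SubjectSessionData], list[dict]]:
    """Group trials by subject/session/task and aggregate across passes."""
    import numpy as np

    groups: dict[tuple[str, str, int], list[MotionTrial]] = {}
    for t in trials:
        groups.setdefault((t.task, t.subject_id, t.session), []).append(t)

    cohort = []
    drop_log: list[dict] = []
    for (task, subject, session), group in sorted(groups.items()):
        feats = []
        curves: dict[tuple[str, str], list] = {}
        for trial in sorted(group, key=lambda t: t.pass_index):
            f, c, dropped = process_trial(trial, filter_cutoff)
            for d in dropped:
                drop_log.append({"trial_id": trial.trial_id, "start": d.start,
                                 "end": d.end, "reason": d.reason})
            feats.append(f)
            for key, arr in c.items():
                curves.setdefault(key, []).append(arr)
        features = pd.concat(feats, ignore_index=True) if feats else pd.DataFrame()
        cohort.append(SubjectSessionData(
            subject_id=subject, session=session, task=task,
            features=features,
            curves={k: np.vstack(v) for k, v in curves.items()},
        ))
    return cohort, drop_log


def run_pipeline(config: PipelineConfig) -> ReliabilityReport:
    """Execute the full pipeline and (optionally) write artifacts.

    Stage order: simulate/load -> detect -> segment -> normalize -> extract
    -> reliability.  Stride exclusions and subject drops are logged; schema
    errors propagate (the CLI converts them to a nonzero exit status).
    """
    if config.synthetic is not None:
        syn = config.synthetic
        if config.seed and not syn.seed:
            from dataclasses import replace
            syn = replace(syn, seed=config.seed)
        trials, _ = generate_cohort(syn)
    elif config.trials_dir:
        trials = gio.read_cohort(config.trials_dir)
    else:
        raise ValueError("config must name either a synthetic cohort or a trials_dir")

    if config.task.lower() != "both":
        trials = [t for t in trials if t.task.lower() == config.task.lower()]

    cohort, drop_log = process_cohort(trials, config.filter_cutoff)
    report = build_report(cohort)
    report.exclusions = list(report.exclusions) + drop_log

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        report.write(out, fmt=config.out_format)
        (out / "reliability_report.json").write_text(report.to_json())
        if drop_log:
            pd.DataFrame(drop_log).to_csv(out / "dropped_strides.csv", index=False)
    return report
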