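"""End-to-end orchestration: stack in, classified records and stats out.

Stage order: dark/flat correction → phase splitting → within-group drift
registration → segmentation on the stretch group → cross-phase transform
estimation → ROI mapping → trace extraction → normalization and peak
detection → classification → per-sample summary.  Every output bundle
carries a provenance block with the software version, a config hash and
every threshold used, and reruns on identical inputs are bit-identical
(every stage is deterministic).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .classify import CellRecord, analyze_and_classify
from .config import ExperimentConfig
from .errors import ConfigurationError
from .imaging import (GROUP_NAMES, CorrectionFrames, FrameStack, LabelMap,
                      correct_stack, estimate_phase_transform, extract_traces,
                      map_rois, register_drift, segment_cells, split_phases)
from .schedule import PHASE_NAMES, PhaseSchedule
from .stats import SampleSummary, summarize_sample
from .traces import RawTrace

logger = logging.getLogger(__name__)

__all__ = ["PipelineResult", "run_pipeline", "load_stack", "traces_to_frame",
           "records_to_frame", "write_report"]


@dataclass
class PipelineResult:
    """Everything the pipeline produced for one sample."""

    traces: list[RawTrace]
    records: list[CellRecord]
    summary: SampleSummary
    labelmaps: dict[str, LabelMap]
    transforms: dict[str, dict]
    provenance: dict


def load_stack(path: str | Path, schedule: PhaseSchedule) -> FrameStack:
    """Read a multi-page TIFF as a FrameStack timed by the schedule."""
    import tifffile

    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    n = len(frames)
    times = schedule.starts[0] + np.arange(n) / schedule.frame_rate
    return FrameStack(frames, times, schedule.phase_of(times),
                      schedule.frame_period)


def traces_to_frame(traces: list[RawTrace]) -> pd.DataFrame:
    rows = []
    for tr in traces:
        for k in range(len(tr)):
            rows.append((tr.cell_id, k, tr.time_s[k], PHASE_NAMES[tr.phase[k]]
                         if tr.phase[k] >= 0 else "none", tr.values[k]))
    return pd.DataFrame(rows, columns=["cell_id", "frame", "time_s", "phase",
                                       "raw_intensity"])


def frame_to_traces(df: pd.DataFrame, sample_id: str = "sample") -> list[RawTrace]:
    """Inverse of :func:`traces_to_frame`."""
    name_to_idx = {n: i for i, n in enumerate(PHASE_NAMES)}
    out = []
    for cid, g in df.groupby("cell_id"):
        g = g.sort_values("time_s")
        out.append(RawTrace(time_s=g["time_s"].to_numpy(),
                            values=g["raw_intensity"].to_numpy(),
                            phase=np.array([name_to_idx.get(p, -1)
                                            for p in g["phase"]]),
                            cell_id=int(cid), sample_id=sample_id))
    return out


def records_to_frame(records: list[CellRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {"cell_id": r.cell_id, "sample_id": r.sample_id,
               "gsmtx4": r.condition.get("gsmtx4"),
               "yoda1": r.condition.get("yoda1"),
               "activity_class": r.activity_class.value,
               "excluded": r.excluded_from_response_analysis}
        if r.markers is not None:
            m = r.markers
            row.update({
                "first_activity_phase": (PHASE_NAMES[m.first_activity_phase]
                                         if m.first_activity_phase is not None else None),
                "baseline_elevated_PII": m.baseline_elevated_PII,
                "baseline_elevated_PIII": m.baseline_elevated_PIII,
                "baseline_elevated_PIV": m.baseline_elevated_PIV,
                "oscillation_increase_PII": m.oscillation_increase_PII,
                "response_PIII": m.response_PIII.value,
                "response_PIV": m.response_PIV.value,
                "fewer_oscillations_PIV_vs_PII": m.fewer_oscillations_PIV_vs_PII,
            })
        for met in r.metrics:
            p = PHASE_NAMES[met.phase]
            row[f"n_peaks_{p}"] = met.n_peaks
            row[f"peaks_per_min_{p}"] = met.peaks_per_min
            row[f"mean_peak_height_{p}"] = met.mean_peak_height
            row[f"initial_max_peak_height_{p}"] = met.initial_max_peak_height
            row[f"baseline_intensity_{p}"] = met.baseline_intensity
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(config: ExperimentConfig,
                 stack: Optional[FrameStack] = None,
                 correction: Optional[CorrectionFrames] = None,
                 out_dir: Optional[str | Path] = None) -> PipelineResult:
    """Run the full analysis for one sample.

    Inputs come either from the config's paths (TIFF files) or in-memory via
    ``stack``/``correction``.  If ``out_dir`` is given, all result tables
    and maps are written there via :func:`write_report`.
    """
    schedule = config.phase_schedule()
    params = config.analysis.to_params()
    seg_params = config.segmentation.to_params()

    if stack is None:
        if not config.paths.stack:
            raise ConfigurationError("no stack provided (paths.stack is empty)")
        if not Path(config.paths.stack).exists():
            raise ConfigurationError(f"stack file not found: {config.paths.stack}")
        stack = load_stack(config.paths.stack, schedule)
    if correction is None and config.paths.dark:
        import tifffile
        for key in ("dark", "flat"):
            p = getattr(config.paths, key)
            if not p or not Path(p).exists():
                raise ConfigurationError(f"correction enabled but {key} frame "
                                         f"missing: {p!r}")
        correction = CorrectionFrames(dark=tifffile.imread(config.paths.dark),
                                      flat=tifffile.imread(config.paths.flat))

    def stage(name):
        logger.info("stage: %s", name)
        return time.perf_counter()

    t0 = stage("correct")
    if correction is not None:
        stack = correct_stack(stack, correction)

    stage("split")
    groups = split_phases(stack, schedule)

    stage("register")
    registered: dict[str, FrameStack] = {}
    for g in GROUP_NAMES:
        registered[g], _ = register_drift(groups[g]) if len(groups[g]) else (groups[g], [])

    stage("segment")
    labels_stretch = segment_cells(registered["stretch"], seg_params)

    stage("map")
    stretch_proj = registered["stretch"].max_projection()
    labelmaps: dict[str, LabelMap] = {"stretch": labels_stretch}
    transforms: dict[str, dict] = {}
    for g in ("pre", "release"):
        tf = estimate_phase_transform(stretch_proj,
                                      registered[g].max_projection())
        mapped, dropped = map_rois(labels_stretch, tf, target_frame=g)
        labelmaps[g] = mapped
        transforms[g] = {"scale": tf.scale, "rotation": tf.rotation,
                         "translation": list(tf.translation),
                         "center": list(tf.center), "dropped_labels": dropped}

    stage("extract")
    traces, incomplete = extract_traces(registered, labelmaps, schedule,
                                        sample_id=config.sample_id)

    stage("classify")
    records = [analyze_and_classify(tr, schedule, params, schedule.condition)
               for tr in traces]

    stage("summarize")
    summary = summarize_sample(records) if records else summarize_sample([])

    provenance = config.provenance(__version__)
    provenance["n_cells"] = len(records)
    provenance["incomplete_cells"] = sorted(incomplete)
    logger.info("pipeline finished in %.1f s", time.perf_counter() - t0)

    result = PipelineResult(traces=traces, records=records, summary=summary,
                            labelmaps=labelmaps, transforms=transforms,
                            provenance=provenance)
    if out_dir is not None:
        write_report(result, out_dir)
    return result


def write_report(result: PipelineResult, out_dir: str | Path) -> dict[str, Path]:
    """Write traces, records, label maps, transforms and provenance."""
    import tifffile

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    paths["traces"] = out / "traces.csv"
    traces_to_frame(result.traces).to_csv(paths["traces"], index=False)
    paths["records"] = out / "records.csv"
    records_to_frame(result.records).to_csv(paths["records"], index=False)
    for g, lm in result.labelmaps.items():
        p = out / f"labels_{g}.tif"
        tifffile.imwrite(p, lm.labels.astype(np.uint16))
        paths[f"labels_{g}"] = p
    paths["transforms"] = out / "transforms.json"
    with open(paths["transforms"], "w") as fh:
        json.dump(result.transforms, fh, indent=2)
    paths["provenance"] = out / "provenance.json"
    with open(paths["provenance"], "w") as fh:
        json.dump(result.provenance, fh, indent=2)
    paths["summary"] = out / "summary.json"
    s = result.summary
    with open(paths["summary"], "w") as fh:
        json.dump({"sample_id": s.sample_id, "condition": s.condition,
                   "n_cells": s.n_cells, "n_classified": s.n_classified,
                   "class_percent": s.class_percent,
                   "response_percent": s.response_percent}, fh, indent=2)
    return paths
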