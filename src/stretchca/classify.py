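"""Rule-based single-cell response classification.

Each cell is assigned exactly one activity class:

* ``SPONTANEOUS`` — at least two Ca2+ peaks during the pre-stretch baseline
  (P I): the cell oscillates on its own.
* ``STRETCH_ACTIVATED`` — fewer than two P I peaks but at least one peak in
  the stretch phase (P III), or a peakless sustained baseline elevation in
  P III (a strong sustained response can saturate into a plateau in which
  at most one peak is detectable).
* ``RANDOM_PEAKS`` — some peaks, fitting neither pattern.
* ``NO_PEAKS`` — no activity at all (dead cell or misplaced ROI).
* ``INCOMPLETE`` — the trace is missing samples in one or more phases
  (e.g. the ROI was lost in a phase group) and cannot be classified.

On top of the class, a set of response markers is computed: the phase of
first activity, baseline elevation of each phase vs its predecessor, an
oscillation-rate increase in P II (the expected Yoda1 signature), and the
stretch/release response category (sustained / oscillating / neither) of
P III and P IV, both judged against the P II baseline.

A *sustained* response requires the baseline intensity (BI) of the phase's
first third to exceed the P II baseline by at least 1.5 relative units, and
the BI of each of the two remaining thirds to retain at least 20% of that
initial elevation.  All thresholds are inclusive (at-least semantics).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import IntegrityError
from .schedule import PhaseSchedule
from .traces import (AnalysisParams, Peak, PhaseMetrics, RelativeTrace,
                     phase_baseline)

__all__ = [
    "ActivityClass",
    "ResponseCategory",
    "ResponseMarkers",
    "CellRecord",
    "classify_activity",
    "test_sustained_elevation",
    "categorize_stretch_response",
    "detect_baseline_elevation",
    "detect_oscillation_increase",
    "classify_cell",
]


class ActivityClass(str, enum.Enum):
    SPONTANEOUS = "spontaneous"
    STRETCH_ACTIVATED = "stretch_activated"
    RANDOM_PEAKS = "random_peaks"
    NO_PEAKS = "no_peaks"
    INCOMPLETE = "incomplete"


class ResponseCategory(str, enum.Enum):
    SUSTAINED = "sustained"
    OSCILLATING = "oscillating"
    NEITHER = "neither"


@dataclass(frozen=True)
class ResponseMarkers:
    """Per-cell response annotations of the classification tree."""

    first_activity_phase: Optional[int]
    baseline_elevated_PII: Optional[bool]
    baseline_elevated_PIII: Optional[bool]
    baseline_elevated_PIV: Optional[bool]
    oscillation_increase_PII: Optional[bool]
    response_PIII: ResponseCategory
    response_PIV: ResponseCategory
    fewer_oscillations_PIV_vs_PII: Optional[bool]


@dataclass(frozen=True)
class CellRecord:
    """One classified cell: identity, condition, class, markers, metrics."""

    cell_id: int
    sample_id: str
    condition: dict
    activity_class: ActivityClass
    markers: Optional[ResponseMarkers]
    metrics: tuple[PhaseMetrics, PhaseMetrics, PhaseMetrics, PhaseMetrics]
    excluded_from_response_analysis: bool


def classify_activity(metrics: Sequence[PhaseMetrics],
                      params: AnalysisParams = AnalysisParams(),
                      *, sustained_p3: bool = False) -> ActivityClass:
    """Assign the activity class from per-phase peak counts.

    ``sustained_p3`` flags a peakless sustained elevation detected in P III
    (computed from the relative trace by :func:`test_sustained_elevation`);
    it makes an otherwise peak-poor cell STRETCH_ACTIVATED.
    """
    counts = [m.n_peaks for m in metrics]
    if any(c is None for c in counts):
        return ActivityClass.INCOMPLETE
    n_pre = counts[0] + (counts[1] if params.spontaneous_includes_PII else 0)
    if n_pre >= params.spontaneous_min_peaks:
        return ActivityClass.SPONTANEOUS
    if counts[2] >= 1 or sustained_p3:
        return ActivityClass.STRETCH_ACTIVATED
    if any(c > 0 for c in counts):
        return ActivityClass.RANDOM_PEAKS
    return ActivityClass.NO_PEAKS


def test_sustained_elevation(rel: RelativeTrace, phase_window: tuple[float, float],
                             reference_bi: Optional[float],
                             params: AnalysisParams = AnalysisParams()) -> bool:
    """Check the sustained-elevation criterion for one phase.

    Splits the phase window into three equal thirds.  Let
    ``E = BI(first third) - reference_bi`` (the initial elevation over the
    P II baseline).  The response is sustained iff ``E >= sustained_delta``
    and the BI of each of the two remaining thirds is at least
    ``reference_bi + retention_fraction * E``.  Returns False when the
    window or the reference baseline is missing.
    """
    if reference_bi is None:
        return False
    lo, hi = phase_window
    if hi <= lo:
        return False
    edges = np.linspace(lo, hi, 4)
    bis = [phase_baseline(rel, (edges[i], edges[i + 1]), params) for i in range(3)]
    if any(b is None for b in bis):
        return False
    elevation = bis[0] - reference_bi
    if elevation < params.sustained_delta:
        return False
    floor = reference_bi + params.retention_fraction * elevation
    return bis[1] >= floor and bis[2] >= floor


def categorize_stretch_response(rel: RelativeTrace, peaks: Sequence[Peak],
                                metrics: Sequence[PhaseMetrics], phase: int,
                                schedule: PhaseSchedule,
                                params: AnalysisParams = AnalysisParams()) -> ResponseCategory:
    """Categorize the response in P III or P IV as sustained / oscillating / neither.

    The reference baseline is always BI(P II), for both phases.
    """
    if phase not in (2, 3):
        raise ValueError("stretch response is defined for P III and P IV only")
    ref = metrics[1].baseline_intensity
    if test_sustained_elevation(rel, schedule.window(phase), ref, params):
        return ResponseCategory.SUSTAINED
    m = metrics[phase]
    if (m.n_peaks is not None and m.n_peaks >= 2 and ref is not None
            and m.baseline_intensity is not None
            and m.baseline_intensity - ref < params.sustained_delta):
        return ResponseCategory.OSCILLATING
    return ResponseCategory.NEITHER


def detect_baseline_elevation(prev_bi: Optional[float], cur_bi: Optional[float],
                              params: AnalysisParams = AnalysisParams()) -> Optional[bool]:
    """Baseline-elevation marker: current BI at least ``elevation_threshold``
    above the previous phase's BI.  ``None`` when either value is missing."""
    if prev_bi is None or cur_bi is None:
        return None
    return bool(cur_bi - prev_bi >= params.elevation_threshold)


def detect_oscillation_increase(metrics_p1: PhaseMetrics,
                                metrics_p2: PhaseMetrics) -> Optional[bool]:
    """Strictly more peaks per minute in P II than in P I (Yoda1 signature)."""
    if metrics_p1.peaks_per_min is None or metrics_p2.peaks_per_min is None:
        return None
    return bool(metrics_p2.peaks_per_min > metrics_p1.peaks_per_min)


def classify_cell(rel: RelativeTrace, peaks: Sequence[Peak],
                  metrics: Sequence[PhaseMetrics], schedule: PhaseSchedule,
                  condition: Optional[dict] = None,
                  params: AnalysisParams = AnalysisParams()) -> CellRecord:
    """Assemble the full per-cell record: class, markers and metrics.

    Cells with any empty phase window are INCOMPLETE (no markers).
    RANDOM_PEAKS, NO_PEAKS and INCOMPLETE cells are flagged as excluded from
    the response analyses.
    """
    if len(metrics) != 4:
        raise IntegrityError("expected metrics for exactly four phases")
    for p in peaks:
        if not (rel.time_s[0] <= p.time_s <= rel.time_s[-1]):
            raise IntegrityError(f"peak at t={p.time_s:.2f}s lies outside the trace")
    condition = dict(condition) if condition is not None else schedule.condition

    if any(m.empty for m in metrics):
        return CellRecord(rel.cell_id, rel.sample_id, condition,
                          ActivityClass.INCOMPLETE, None, tuple(metrics), True)

    sustained_p3 = test_sustained_elevation(
        rel, schedule.window(2), metrics[1].baseline_intensity, params)
    cls = classify_activity(metrics, params, sustained_p3=sustained_p3)

    first_activity = None
    for m in metrics:
        if m.n_peaks:
            first_activity = m.phase
            break
    markers = ResponseMarkers(
        first_activity_phase=first_activity,
        baseline_elevated_PII=detect_baseline_elevation(
            metrics[0].baseline_intensity, metrics[1].baseline_intensity, params),
        baseline_elevated_PIII=detect_baseline_elevation(
            metrics[1].baseline_intensity, metrics[2].baseline_intensity, params),
        baseline_elevated_PIV=detect_baseline_elevation(
            metrics[2].baseline_intensity, metrics[3].baseline_intensity, params),
        oscillation_increase_PII=detect_oscillation_increase(metrics[0], metrics[1]),
        response_PIII=categorize_stretch_response(rel, peaks, metrics, 2, schedule, params),
        response_PIV=categorize_stretch_response(rel, peaks, metrics, 3, schedule, params),
        fewer_oscillations_PIV_vs_PII=(
            None if metrics[3].peaks_per_min is None or metrics[1].peaks_per_min is None
            else bool(metrics[3].peaks_per_min < metrics[1].peaks_per_min)),
    )
    excluded = cls in (ActivityClass.RANDOM_PEAKS, ActivityClass.NO_PEAKS)
    return CellRecord(rel.cell_id, rel.sample_id, condition, cls, markers,
                      tuple(metrics), excluded)


def analyze_and_classify(raw, schedule: PhaseSchedule,
                         params: AnalysisParams = AnalysisParams(),
                         condition: Optional[dict] = None) -> CellRecord:
    """Convenience: S_0 → normalize → peaks → metrics → record for one trace."""
    from .traces import compute_phase_metrics, detect_peaks, estimate_s0, normalize_trace

    s0 = estimate_s0(raw, params)
    rel = normalize_trace(raw, s0)
    peaks = detect_peaks(rel, params)
    metrics = compute_phase_metrics(rel, peaks, schedule, params)
    return classify_cell(rel, peaks, metrics, schedule, condition, params)
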