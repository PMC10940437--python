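"""Per-cell trace normalization, peak detection and phase metrics.

The raw readout of a cell is its mean Fluo-4 fluorescence over the cell ROI
per frame, S_t.  Because dye loading differs between cells, every trace is
expressed relative to a peak-free early baseline S_0 (the average of a 3-s
stretch of signal that contains no Ca2+ transient).  Peaks are then detected
on the relative trace S_t/S_0 by topographic prominence: a local maximum
counts as a Ca2+ event when the vertical distance between its apex and the
lowest contour connecting it to higher ground is at least 0.3 relative
units, which separates transients from shot noise.

Per phase the module reports the peak count and rate, the mean apex height,
the baseline intensity (BI, a low percentile of the relative trace that
tracks the plateau level while ignoring superimposed transients), and — for
the stretch and release phases — the highest peak of the initial response
(first 20 s of the phase).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.signal import find_peaks, peak_widths

from .errors import NormalizationError
from .schedule import PHASE_NAMES, PhaseSchedule

__all__ = [
    "AnalysisParams",
    "RawTrace",
    "RelativeTrace",
    "Peak",
    "PhaseMetrics",
    "estimate_s0",
    "normalize_trace",
    "detect_peaks",
    "phase_baseline",
    "compute_phase_metrics",
]


@dataclass(frozen=True)
class AnalysisParams:
    """Thresholds of the trace-analysis and classification stages.

    Attributes
    ----------
    prominence_threshold : float
        Minimum topographic prominence (relative units) for a local maximum
        to count as a Ca2+ peak.  Default 0.3.
    s0_window_s : float
        Length of the peak-free window averaged for S_0, seconds. Default 3.
    spontaneous_min_peaks : int
        Minimum P I peak count for a cell to be called spontaneously active.
    sustained_delta : float
        Minimum first-third baseline elevation over the P II baseline
        (relative units) for a sustained stretch response.  Default 1.5.
    retention_fraction : float
        Fraction of the initial elevation that must be retained in the last
        two thirds of the phase.  Default 0.2.
    initial_response_window_s : float
        Window after stretch/release onset within which the initial-response
        peak is sought.  Default 20 s.
    baseline_percentile : float
        Percentile of the relative trace used as the baseline intensity
        estimator.  Default 10.
    elevation_threshold : float
        Minimum baseline increase vs the previous phase (relative units) for
        the baseline-elevation marker.  Default 0.1.
    spontaneous_includes_PII : bool
        If true, spontaneity is judged on P I and P II peaks combined
        instead of P I alone.  Default false.
    """

    prominence_threshold: float = 0.3
    s0_window_s: float = 3.0
    spontaneous_min_peaks: int = 2
    sustained_delta: float = 1.5
    retention_fraction: float = 0.2
    initial_response_window_s: float = 20.0
    baseline_percentile: float = 10.0
    elevation_threshold: float = 0.1
    spontaneous_includes_PII: bool = False

    def __post_init__(self) -> None:
        positive = (
            "prominence_threshold",
            "s0_window_s",
            "spontaneous_min_peaks",
            "sustained_delta",
            "initial_response_window_s",
            "baseline_percentile",
            "elevation_threshold",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.retention_fraction < 1.0:
            raise ValueError("retention_fraction must lie in (0, 1)")


@dataclass(frozen=True)
class RawTrace:
    """Raw mean ROI intensity per frame for one cell."""

    time_s: np.ndarray
    values: np.ndarray
    phase: np.ndarray
    cell_id: int = 0
    sample_id: str = "sample"

    def __post_init__(self) -> None:
        t = np.asarray(self.time_s, dtype=float)
        v = np.asarray(self.values, dtype=float)
        p = np.asarray(self.phase, dtype=int)
        if not (t.shape == v.shape == p.shape):
            raise ValueError("time, values and phase must have equal length")
        if t.size >= 2 and not np.all(np.diff(t) > 0):
            raise ValueError("time must be strictly increasing")
        if not np.all(np.isfinite(v)):
            raise ValueError("trace values must be finite")
        object.__setattr__(self, "time_s", t)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "phase", p)

    def __len__(self) -> int:
        return self.time_s.size


@dataclass(frozen=True)
class RelativeTrace:
    """Normalized trace S_t/S_0 with the same sampling as its RawTrace."""

    time_s: np.ndarray
    values: np.ndarray
    phase: np.ndarray
    s0: float
    cell_id: int = 0
    sample_id: str = "sample"

    def __len__(self) -> int:
        return self.time_s.size


@dataclass(frozen=True)
class Peak:
    """A detected Ca2+ transient: apex sample, time, height and prominence."""

    index: int
    time_s: float
    height: float
    prominence: float


@dataclass(frozen=True)
class PhaseMetrics:
    """Per-phase summary of one cell's relative trace.

    Fields are ``None`` (absent, not zero) when the phase window contains no
    samples.  ``initial_max_peak_height`` is only meaningful for the stretch
    and release phases and is ``None`` when no peak falls in the first
    ``initial_response_window_s`` seconds of the phase.
    """

    phase: int
    n_peaks: Optional[int]
    peaks_per_min: Optional[float]
    mean_peak_height: Optional[float]
    initial_max_peak_height: Optional[float]
    baseline_intensity: Optional[float]

    @property
    def phase_name(self) -> str:
        return PHASE_NAMES[self.phase]

    @property
    def empty(self) -> bool:
        return self.n_peaks is None


def detect_peaks(rel: RelativeTrace | np.ndarray, params: AnalysisParams = AnalysisParams(),
                 time_s: np.ndarray | None = None) -> list[Peak]:
    """Detect Ca2+ peaks by topographic prominence.

    Returns every local maximum of the relative trace whose prominence is at
    least ``params.prominence_threshold`` (inclusive), ordered by time.
    Plateau maxima are reported once, at the leftmost sample of the plateau.
    """
    if isinstance(rel, RelativeTrace):
        x = np.asarray(rel.values, dtype=float)
        t = rel.time_s
    else:
        x = np.asarray(rel, dtype=float)
        t = time_s if time_s is not None else np.arange(x.size, dtype=float)
    if x.size < 3:
        return []
    idx, props = find_peaks(x, prominence=params.prominence_threshold,
                            plateau_size=(1, None))
    peaks = []
    for i, left in enumerate(props["left_edges"]):
        peaks.append(Peak(index=int(left), time_s=float(t[left]),
                          height=float(x[left]),
                          prominence=float(props["prominences"][i])))
    return peaks


def _peak_exclusion_mask(x: np.ndarray, params: AnalysisParams) -> np.ndarray:
    """Boolean mask of samples lying within the extent of a detected peak.

    The extent of each peak is its width measured near the base (at 95% of
    the prominence below the apex), so both the rising flank and the decay
    tail of a transient are excluded from baseline estimation.
    """
    mask = np.zeros(x.size, dtype=bool)
    if x.size < 3:
        return mask
    idx, props = find_peaks(x, prominence=params.prominence_threshold)
    if idx.size == 0:
        return mask
    _, _, lips, rips = peak_widths(x, idx, rel_height=0.95,
                                   prominence_data=(props["prominences"],
                                                    props["left_bases"],
                                                    props["right_bases"]))
    for lo, hi in zip(lips, rips):
        mask[int(np.floor(lo)):int(np.ceil(hi)) + 1] = True
    return mask


def estimate_s0(raw: RawTrace, params: AnalysisParams = AnalysisParams()) -> float:
    """Estimate the normalization constant S_0.

    S_0 is the mean of the earliest ``s0_window_s``-long window of P I that
    contains no detected Ca2+ peak.  Peaks are pre-detected on a
    provisionally normalized trace (raw / median of P I); a window "contains"
    a peak when it overlaps the peak's near-base extent, so decay tails do
    not leak into the baseline.  If no peak-free window exists in P I, S_0
    falls back to the mean of the lowest ``baseline_percentile`` percent of
    P I samples.
    """
    v = raw.values
    duration = raw.time_s[-1] - raw.time_s[0] if len(raw) else 0.0
    if duration < params.s0_window_s:
        raise ValueError(
            f"trace covers {duration:.2f} s, shorter than the "
            f"{params.s0_window_s:.2f} s S_0 window")
    p1 = v[raw.phase == 0]
    if p1.size == 0:
        p1 = v
    prov = float(np.median(p1))
    if prov <= 0:
        raise NormalizationError("provisional baseline is non-positive "
                                 "(all-zero or negative trace)")
    excluded = _peak_exclusion_mask(v / prov, params)

    dt = float(np.median(np.diff(raw.time_s)))
    w = max(int(round(params.s0_window_s / dt)), 1)
    n1 = int(np.sum(raw.phase == 0)) or len(raw)
    s0 = None
    for start in range(0, n1 - w + 1):
        if not excluded[start:start + w].any():
            s0 = float(np.mean(v[start:start + w]))
            break
    if s0 is None:
        k = max(int(np.ceil(p1.size * params.baseline_percentile / 100.0)), 1)
        s0 = float(np.mean(np.sort(p1)[:k]))
    if s0 <= 0:
        raise NormalizationError("estimated S_0 is non-positive")
    return s0


def normalize_trace(raw: RawTrace, s0: float) -> RelativeTrace:
    """Divide a raw trace by S_0, preserving sampling and metadata."""
    if s0 <= 0:
        raise NormalizationError("S_0 must be positive")
    return RelativeTrace(time_s=raw.time_s, values=raw.values / s0,
                         phase=raw.phase, s0=float(s0),
                         cell_id=raw.cell_id, sample_id=raw.sample_id)


def phase_baseline(rel: RelativeTrace, window: tuple[float, float],
                   params: AnalysisParams = AnalysisParams()) -> Optional[float]:
    """Baseline intensity: low percentile of the trace within a window.

    Returns ``None`` for an empty window.
    """
    lo, hi = window
    sel = (rel.time_s >= lo) & (rel.time_s < hi)
    if not sel.any():
        return None
    return float(np.percentile(rel.values[sel], params.baseline_percentile))


def compute_phase_metrics(rel: RelativeTrace, peaks: Sequence[Peak],
                          schedule: PhaseSchedule,
                          params: AnalysisParams = AnalysisParams()) -> list[PhaseMetrics]:
    """Per-phase peak counts, rates, heights and baselines.

    Peaks are assigned to phases by apex time (half-open windows).  For the
    stretch (P III) and release (P IV) phases the maximum apex height among
    peaks in the first ``initial_response_window_s`` seconds of the phase is
    reported as the initial response.
    """
    out: list[PhaseMetrics] = []
    for ph in range(4):
        lo, hi = schedule.window(ph)
        if not ((rel.time_s >= lo) & (rel.time_s < hi)).any():
            out.append(PhaseMetrics(ph, None, None, None, None, None))
            continue
        in_phase = [p for p in peaks if lo <= p.time_s < hi]
        n = len(in_phase)
        rate = n / (schedule.duration(ph) / 60.0) if schedule.duration(ph) > 0 else None
        mean_h = float(np.mean([p.height for p in in_phase])) if n else None
        init_max = None
        if ph >= 2:
            early = [p for p in in_phase
                     if p.time_s < lo + params.initial_response_window_s]
            if early:
                init_max = float(max(p.height for p in early))
        bi = phase_baseline(rel, (lo, hi), params)
        out.append(PhaseMetrics(ph, n, rate, mean_h, init_max, bi))
    return out
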