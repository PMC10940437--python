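"""Shared fixtures: trace builders and the brute-force prominence oracle."""

from __future__ import annotations

import numpy as np
import pytest

from stretchca import AnalysisParams, PhaseSchedule, RawTrace


@pytest.fixture(scope="session")
def schedule() -> PhaseSchedule:
    """Default protocol: four 1-min phases at 10 frames/s."""
    return PhaseSchedule()


@pytest.fixture(scope="session")
def params() -> AnalysisParams:
    return AnalysisParams()


def oracle_prominence_peaks(x: np.ndarray, pmin: float):
    """Exhaustive prominence oracle, independent of scipy.

    A peak is a strict local maximum (plateaus count once, at their leftmost
    sample).  Its prominence is found by scanning left and right until a
    strictly higher value or the signal edge, taking the minimum on each
    side, and subtracting the larger of the two minima from the apex.
    Returns (index, height, prominence) triples for prominence >= pmin.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    out = []
    i = 1
    while i < n - 1:
        j = i
        while j + 1 < n and x[j + 1] == x[i]:
            j += 1
        if x[i] > x[i - 1] and j + 1 < n and x[i] > x[j + 1]:
            h = x[i]
            lmin = h
            k = i - 1
            while k >= 0 and x[k] <= h:
                lmin = min(lmin, x[k])
                k -= 1
            rmin = h
            k = j + 1
            while k < n and x[k] <= h:
                rmin = min(rmin, x[k])
                k += 1
            prom = h - max(lmin, rmin)
            if prom >= pmin:
                out.append((i, h, prom))
        i = j + 1
    return out


def bump(t: np.ndarray, center: float, height: float, half_width: float = 0.5):
    """Triangular transient of given apex height over the local baseline."""
    return height * np.clip(1.0 - np.abs(t - center) / half_width, 0.0, None)


def make_raw_trace(schedule: PhaseSchedule, rel: np.ndarray, f0: float = 100.0,
                   cell_id: int = 0) -> RawTrace:
    """Wrap a relative-signal array into a RawTrace scaled by f0."""
    t = schedule.times()
    assert rel.shape == t.shape
    return RawTrace(time_s=t, values=f0 * rel, phase=schedule.phase_of(t),
                    cell_id=cell_id)


def flat_relative(schedule: PhaseSchedule, level: float = 1.0) -> np.ndarray:
    return np.full(schedule.times().shape, level)
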