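"""Experiment phase schedule.

A stretch experiment runs in four contiguous phases, each one minute by
default: P I (pre-stretch baseline, optionally with the mechanosensitive
channel blocker GsMTx4 present), P II (the Piezo1 agonist Yoda1 may be
added), P III (15% isotropic radial stretch), P IV (release back to 0%
stretch). Phase windows are half-open ``[start, end)`` so every time point
belongs to exactly one phase.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

PHASE_NAMES = ("PI", "PII", "PIII", "PIV")


@dataclass(frozen=True)
class PhaseSchedule:
    """Four half-open phase windows with acquisition and condition metadata.

    Parameters
    ----------
    starts, ends : tuple of 4 floats
        Phase window boundaries in seconds; windows must be contiguous and
        non-overlapping (``ends[i] == starts[i+1]``).
    frame_rate : float
        Acquisition rate in frames per second.
    stretch_percent : float
        Radial stretch applied during P III, in percent.
    gsmtx4 : bool
        GsMTx4 present from P I on.
    yoda1 : bool
        Yoda1 added at the start of P II.
    """

    starts: tuple[float, float, float, float] = (0.0, 60.0, 120.0, 180.0)
    ends: tuple[float, float, float, float] = (60.0, 120.0, 180.0, 240.0)
    frame_rate: float = 10.0
    stretch_percent: float = 15.0
    gsmtx4: bool = False
    yoda1: bool = False

    def __post_init__(self) -> None:
        if len(self.starts) != 4 or len(self.ends) != 4:
            raise ValueError("a schedule has exactly four phases")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        for i in range(4):
            if self.ends[i] < self.starts[i]:
                raise ValueError(f"phase {PHASE_NAMES[i]} has negative length")
            if i and not np.isclose(self.starts[i], self.ends[i - 1]):
                raise ValueError("phase windows must be contiguous")

    @property
    def frame_period(self) -> float:
        return 1.0 / self.frame_rate

    @property
    def total_duration(self) -> float:
        return self.ends[3] - self.starts[0]

    def window(self, phase: int) -> tuple[float, float]:
        """Half-open time window ``[start, end)`` of phase 0..3."""
        return self.starts[phase], self.ends[phase]

    def duration(self, phase: int) -> float:
        return self.ends[phase] - self.starts[phase]

    def phase_of(self, t: np.ndarray | float) -> np.ndarray:
        """Phase index for each time (half-open windows); -1 outside."""
        t = np.asarray(t, dtype=float)
        out = np.full(t.shape, -1, dtype=int)
        for i in range(4):
            out[(t >= self.starts[i]) & (t < self.ends[i])] = i
        return out

    def times(self) -> np.ndarray:
        """Sample times covering the whole experiment at the frame rate."""
        n = int(round(self.total_duration * self.frame_rate))
        return self.starts[0] + np.arange(n) / self.frame_rate

    @property
    def condition(self) -> dict[str, bool]:
        return {"gsmtx4": self.gsmtx4, "yoda1": self.yoda1}

    @property
    def condition_label(self) -> str:
        return ("GsMTx4" if self.gsmtx4 else "-") + "/" + ("Yoda1" if self.yoda1 else "-")
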