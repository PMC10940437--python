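"""Sample-level summaries and gated two-group comparisons.

Category percentages are assessed separately for each sample (biological
replicate) and summarized as boxplots whose box spans the quartiles and
whose whiskers span the 5th-95th percentiles.  Two groups are compared at a
time: each group is first checked for normality with the Shapiro-Wilk test;
if both pass, a one-way ANOVA is used, otherwise the Kruskal-Wallis H test.
p < 0.05 is considered significant.  No multiplicity correction is applied
by default (comparisons are pairwise and reported as-is); an optional Holm
correction is available for modern use.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .classify import ActivityClass, CellRecord, ResponseCategory
from .errors import InsufficientDataError

__all__ = [
    "SampleSummary",
    "BoxplotSummary",
    "GroupComparison",
    "summarize_sample",
    "boxplot_summary",
    "compare_groups",
    "holm_correction",
]


@dataclass(frozen=True)
class BoxplotSummary:
    """Median, quartiles and 5-95% whiskers of a value list."""

    median: Optional[float]
    q1: Optional[float]
    q3: Optional[float]
    whisker_low: Optional[float]
    whisker_high: Optional[float]
    n: int


@dataclass(frozen=True)
class GroupComparison:
    """Result of one Shapiro-Wilk-gated two-group comparison."""

    labels: tuple[str, str]
    normality_p: tuple[float, float]
    test: str                    # "anova" or "kruskal-wallis"
    statistic: float
    p_value: float
    significant: bool
    alpha: float = 0.05

    @property
    def stars(self) -> str:
        if self.p_value < 0.001:
            return "***"
        if self.p_value < 0.01:
            return "**"
        if self.p_value < 0.05:
            return "*"
        return "ns"


@dataclass
class SampleSummary:
    """Per-sample aggregation of cell records."""

    sample_id: str
    condition: dict
    n_cells: int
    n_classified: int
    class_percent: dict[str, float]
    response_percent: dict[str, dict[str, float]]   # by activity type
    peak_heights: dict[str, list[float]]            # per phase name
    baselines: dict[str, list[float]]               # per phase name

    def to_frame(self) -> pd.DataFrame:
        rows = [{"sample_id": self.sample_id, "metric": f"class_{k}",
                 "value": v} for k, v in self.class_percent.items()]
        for group, d in self.response_percent.items():
            rows += [{"sample_id": self.sample_id,
                      "metric": f"{group}_{k}", "value": v}
                     for k, v in d.items()]
        return pd.DataFrame(rows)


def boxplot_summary(values: Sequence[float]) -> BoxplotSummary:
    """Order statistics with linear-interpolation percentiles."""
    v = np.asarray([x for x in values if x is not None and np.isfinite(x)], dtype=float)
    if v.size == 0:
        return BoxplotSummary(None, None, None, None, None, 0)
    q = np.percentile(v, [5, 25, 50, 75, 95])
    return BoxplotSummary(median=float(q[2]), q1=float(q[1]), q3=float(q[3]),
                          whisker_low=float(q[0]), whisker_high=float(q[4]),
                          n=int(v.size))


def summarize_sample(records: Sequence[CellRecord]) -> SampleSummary:
    """Fractions per activity class and per response category for one sample.

    Class percentages are over classified (non-INCOMPLETE) cells.  Response
    percentages are computed separately within the spontaneously active and
    the stretch-activated subsets, which may represent different
    physiological states.
    """
    records = list(records)
    if not records:
        return SampleSummary("", {}, 0, 0, {}, {}, {}, {})
    sample_id = records[0].sample_id
    if any(r.sample_id != sample_id for r in records):
        raise ValueError("all records must share one sample_id")
    classified = [r for r in records if r.activity_class != ActivityClass.INCOMPLETE]
    n_cls = len(classified)

    class_percent = {}
    for cls in (ActivityClass.SPONTANEOUS, ActivityClass.STRETCH_ACTIVATED,
                ActivityClass.RANDOM_PEAKS, ActivityClass.NO_PEAKS):
        k = sum(1 for r in classified if r.activity_class == cls)
        class_percent[cls.value] = 100.0 * k / n_cls if n_cls else 0.0

    response_percent: dict[str, dict[str, float]] = {}
    for cls in (ActivityClass.SPONTANEOUS, ActivityClass.STRETCH_ACTIVATED):
        subset = [r for r in classified if r.activity_class == cls]
        d: dict[str, float] = {}
        n = len(subset)
        for phase_key in ("response_PIII", "response_PIV"):
            for cat in ResponseCategory:
                k = sum(1 for r in subset
                        if getattr(r.markers, phase_key) == cat)
                d[f"{phase_key}_{cat.value}"] = 100.0 * k / n if n else float("nan")
        for flag in ("oscillation_increase_PII", "baseline_elevated_PIII"):
            k = sum(1 for r in subset if getattr(r.markers, flag))
            d[flag] = 100.0 * k / n if n else float("nan")
        response_percent[cls.value] = d

    peak_heights: dict[str, list[float]] = {}
    baselines: dict[str, list[float]] = {}
    for ph, name in enumerate(("PI", "PII", "PIII", "PIV")):
        hs, bs = [], []
        for r in classified:
            m = r.metrics[ph]
            height = m.initial_max_peak_height if ph >= 2 else m.mean_peak_height
            if height is not None:
                hs.append(height)
            if m.baseline_intensity is not None:
                bs.append(m.baseline_intensity)
        peak_heights[name] = hs
        baselines[name] = bs

    return SampleSummary(sample_id=sample_id, condition=records[0].condition,
                         n_cells=len(records), n_classified=n_cls,
                         class_percent=class_percent,
                         response_percent=response_percent,
                         peak_heights=peak_heights, baselines=baselines)


def compare_groups(a: Sequence[float], b: Sequence[float], alpha: float = 0.05,
                   labels: tuple[str, str] = ("a", "b")) -> GroupComparison:
    """Shapiro-Wilk-gated two-group comparison.

    Both groups normal at ``alpha`` -> one-way ANOVA; otherwise
    Kruskal-Wallis H.  Constant groups are treated as non-normal (the
    Shapiro-Wilk statistic is undefined for them); if all pooled values are
    identical the comparison is trivially non-significant.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise InsufficientDataError(
            "each group needs >= 3 observations for the normality gate")

    def shapiro_p(x: np.ndarray) -> float:
        if np.ptp(x) == 0:
            return 0.0  # degenerate: treat as non-normal
        return float(sps.shapiro(x).pvalue)

    pa, pb = shapiro_p(a), shapiro_p(b)
    if np.ptp(np.concatenate([a, b])) == 0:
        return GroupComparison(labels, (pa, pb), "kruskal-wallis", 0.0, 1.0,
                               False, alpha)
    if pa > alpha and pb > alpha:
        res = sps.f_oneway(a, b)
        test = "anova"
    else:
        res = sps.kruskal(a, b)
        test = "kruskal-wallis"
    p = float(res.pvalue)
    return GroupComparison(labels, (pa, pb), test, float(res.statistic), p,
                           bool(p < alpha), alpha)


def holm_correction(comparisons: Sequence[GroupComparison]) -> list[GroupComparison]:
    """Holm step-down adjustment over a family of comparisons (opt-in)."""
    m = len(comparisons)
    order = np.argsort([c.p_value for c in comparisons])
    adjusted = [0.0] * m
    running = 0.0
    for rank, idx in enumerate(order):
        p_adj = min((m - rank) * comparisons[idx].p_value, 1.0)
        running = max(running, p_adj)
        adjusted[idx] = running
    out = []
    for c, p_adj in zip(comparisons, adjusted):
        out.append(GroupComparison(c.labels, c.normality_p, c.test, c.statistic,
                                   p_adj, bool(p_adj < c.alpha), c.alpha))
    return out
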