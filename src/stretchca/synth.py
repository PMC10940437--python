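"""Synthetic Fluo-4 traces and image stacks with known ground truth.

Real recordings of stretch experiments are not redistributable, so every
downstream stage is exercised on synthetic data that emulates Fluo-4-loaded
HL-1 cardiomyocytes: spontaneous Ca2+ oscillations whose rate can be
modulated by a drug from P II on, a stretch response in P III that is either
a train of oscillations or a sustained baseline elevation, 15% isotropic
geometric scaling of the field at stretch onset, radial vignetting, a dark
offset, and signal-dependent shot noise.

Ca2+ transients use a fast-rise / exponential-decay kernel (time-to-peak
~0.3 s, decay constant 1.5 s) with amplitudes jittered +/-20%.  Event times
follow a homogeneous Poisson process per phase; events closer than a 2-s
refractory gap to their predecessor are dropped so that every ground-truth
event is a resolvable peak.

Everything is deterministic per seed: identical spec + seed gives
bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import PlacementError
from .schedule import PhaseSchedule
from .traces import RawTrace

__all__ = [
    "Phenotype",
    "TraceTruth",
    "SceneSpec",
    "SceneBundle",
    "simulate_trace",
    "render_scene",
    "apply_stretch_transform",
    "write_scene",
]

# Transient kernel time constants (seconds).
RISE_TAU = 0.1
DECAY_TAU = 1.5
# Minimum separation between ground-truth events so each is a distinct peak.
REFRACTORY_S = 2.0
# Oscillation rate (peaks/min) evoked in P III for "oscillating" responders.
STRETCH_OSC_RATE = 6.0
# Raw-signal scale and noise of the trace-only simulator.
TRACE_F0 = 400.0
TRACE_GAIN = 2.0
TRACE_READ_SIGMA = 2.0


@dataclass(frozen=True)
class Phenotype:
    """Ground-truth activity program of one synthetic cell.

    Attributes
    ----------
    spontaneous_rate : float
        Spontaneous oscillation rate in peaks per minute during P I.
    drug_rate_multiplier : float
        Factor applied to the oscillation rate from P II onward (the Yoda1
        sensitisation effect; 1.0 = no drug effect).
    stretch_response : str
        ``"sustained"``, ``"oscillating"`` or ``"none"``.
    sustained_amplitude : float
        Baseline elevation (relative units) added during P III for
        sustained responders; must be 0 otherwise.
    peak_amplitude : float
        Typical relative transient height (> 0), jittered +/-20% per event.
    """

    spontaneous_rate: float = 0.0
    drug_rate_multiplier: float = 1.0
    stretch_response: str = "none"
    sustained_amplitude: float = 0.0
    peak_amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.peak_amplitude <= 0:
            raise ValueError("peak_amplitude must be positive")
        if self.spontaneous_rate < 0 or self.drug_rate_multiplier < 0:
            raise ValueError("rates must be non-negative")
        if self.stretch_response not in ("sustained", "oscillating", "none"):
            raise ValueError("stretch_response must be sustained|oscillating|none")
        if self.sustained_amplitude > 0 and self.stretch_response != "sustained":
            raise ValueError("sustained_amplitude > 0 requires stretch_response='sustained'")
        if self.stretch_response == "sustained" and self.sustained_amplitude <= 0:
            raise ValueError("sustained responders need sustained_amplitude > 0")


@dataclass(frozen=True)
class TraceTruth:
    """Ground truth emitted alongside a simulated trace."""

    event_times: tuple[float, ...]
    sustained_interval: Optional[tuple[float, float]]


def _kernel(t: np.ndarray) -> np.ndarray:
    """Fast-rise/exponential-decay transient, peak-normalized to 1."""
    k = np.where(t >= 0, np.exp(-t / DECAY_TAU) - np.exp(-t / RISE_TAU), 0.0)
    tpk = RISE_TAU * DECAY_TAU / (DECAY_TAU - RISE_TAU) * math.log(DECAY_TAU / RISE_TAU)
    peak = math.exp(-tpk / DECAY_TAU) - math.exp(-tpk / RISE_TAU)
    return k / peak


def _poisson_events(rng: np.random.Generator, window: tuple[float, float],
                    rate_per_min: float) -> list[float]:
    lo, hi = window
    lam = rate_per_min * (hi - lo) / 60.0
    if lam <= 0:
        return []
    n = rng.poisson(lam)
    return sorted(rng.uniform(lo, hi, size=n).tolist())


def _enforce_refractory(times: list[float]) -> list[float]:
    kept: list[float] = []
    for t in times:
        if not kept or t - kept[-1] >= REFRACTORY_S:
            kept.append(t)
    return kept


def relative_signal(phenotype: Phenotype, schedule: PhaseSchedule,
                    rng: np.random.Generator) -> tuple[np.ndarray, TraceTruth]:
    """Noise-free relative trace S_t/S_0 plus its ground truth."""
    t = schedule.times()
    sig = np.ones_like(t)

    events: list[float] = []
    for ph in range(4):
        rate = phenotype.spontaneous_rate
        if ph >= 1:
            rate *= phenotype.drug_rate_multiplier
        if ph == 2 and phenotype.stretch_response == "oscillating":
            rate = max(rate, STRETCH_OSC_RATE)
        events.extend(_poisson_events(rng, schedule.window(ph), rate))
    if phenotype.stretch_response == "sustained":
        # one initial transient riding on the plateau at stretch onset
        events.append(schedule.starts[2] + float(rng.uniform(0.5, 2.0)))
    events = _enforce_refractory(sorted(events))

    for te in events:
        amp = phenotype.peak_amplitude * float(rng.uniform(0.8, 1.2))
        span = t >= te
        sig[span] += amp * _kernel(t[span] - te)

    sustained_interval = None
    if phenotype.stretch_response == "sustained":
        t3, t3e = schedule.window(2)
        t4, t4e = schedule.window(3)
        a = phenotype.sustained_amplitude
        in3 = (t >= t3) & (t < t3e)
        sig[in3] += a * (1.0 - np.exp(-(t[in3] - t3) / 1.0))
        # after release the plateau decays but stays partly elevated early on
        in4 = t >= t4
        level_at_release = a * (1.0 - math.exp(-(t3e - t3) / 1.0))
        sig[in4] += level_at_release * np.exp(-(t[in4] - t4) / 15.0)
        sustained_interval = (t3, t3e)

    return sig, TraceTruth(tuple(events), sustained_interval)


def simulate_trace(phenotype: Phenotype, schedule: PhaseSchedule, seed: int,
                   f0: float = TRACE_F0, noise: bool = True,
                   cell_id: int = 0, sample_id: str = "synthetic") -> tuple[RawTrace, TraceTruth]:
    """Simulate one raw fluorescence trace at the schedule's frame rate.

    The raw signal is ``f0`` times the relative signal, with shot-like
    Poisson noise (variance proportional to the signal) and Gaussian read
    noise added when ``noise`` is true.  Deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    rel, truth = relative_signal(phenotype, schedule, rng)
    raw = f0 * rel
    if noise:
        raw = rng.poisson(raw * TRACE_GAIN) / TRACE_GAIN
        raw = raw + rng.normal(0.0, TRACE_READ_SIGMA, size=raw.shape)
        raw = np.clip(raw, 0.0, None)
    t = schedule.times()
    return RawTrace(time_s=t, values=raw, phase=schedule.phase_of(t),
                    cell_id=cell_id, sample_id=sample_id), truth


def apply_stretch_transform(points: np.ndarray, scale: float,
                            center: np.ndarray | Sequence[float]) -> np.ndarray:
    """Isotropic scaling about a center: p -> center + scale * (p - center)."""
    if scale <= 0:
        raise ValueError("scale must be positive")
    pts = np.asarray(points, dtype=float)
    c = np.asarray(center, dtype=float)
    return c + scale * (pts - c)


@dataclass(frozen=True)
class NoiseModel:
    """Camera/optics model of the renderer: offset, gain, vignette, noise."""

    dark_offset: float = 100.0
    gain: float = 2.0
    read_sigma: float = 2.0
    vignette_strength: float = 0.3
    background: float = 30.0
    enabled: bool = True


@dataclass(frozen=True)
class SceneSpec:
    """Description of one synthetic stretch-experiment recording.

    Cells are soft-edged discs whose brightness follows a simulated relative
    Ca2+ trace.  At P III onset all positions and radii are scaled by
    ``stretch_scale`` about the field center (the 15% isotropic stretch);
    at P IV they return to the pre-stretch geometry.  A per-phase
    translation emulates chamber drift.
    """

    n_cells: int = 20
    field_size: tuple[int, int] = (320, 320)
    cell_radius_range: tuple[float, float] = (6.0, 10.0)
    phenotypes: Optional[tuple[Phenotype, ...]] = None
    stretch_scale: float = 1.15
    drift: tuple[tuple[float, float], ...] = ((0.0, 0.0), (0.0, 0.0), (2.0, 1.0), (0.5, -0.5))
    noise: NoiseModel = field(default_factory=NoiseModel)
    schedule: PhaseSchedule = field(default_factory=lambda: PhaseSchedule(frame_rate=5.0))
    cell_f0_range: tuple[float, float] = (250.0, 450.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.stretch_scale < 1.0:
            raise ValueError("stretch_scale must be >= 1")
        if len(self.drift) != 4:
            raise ValueError("drift needs one translation per phase")
        if self.phenotypes is not None and len(self.phenotypes) != self.n_cells:
            raise ValueError("phenotype_assignment length must equal n_cells")


@dataclass
class SceneBundle:
    """Rendered scene: stack, correction frames, labels and truth table."""

    frames: np.ndarray           # (T, H, W) uint16
    times: np.ndarray
    phase_tags: np.ndarray
    dark: np.ndarray             # (H, W) float
    flat: np.ndarray             # (H, W) float, includes dark offset
    label_map: np.ndarray        # (H, W) uint16, P III coordinates
    truth: pd.DataFrame          # one row per cell
    cell_truths: list[TraceTruth]
    spec: SceneSpec


def default_phenotype_mix(n: int, rng: np.random.Generator,
                          spontaneous_fraction: float = 0.5) -> tuple[Phenotype, ...]:
    """A realistic cohort: half spontaneous oscillators (4-8 peaks/min),
    the rest quiescent; stretch responders split between sustained
    (amplitude ~2) and oscillating."""
    out = []
    for _ in range(n):
        spont = rng.uniform() < spontaneous_fraction
        rate = float(rng.uniform(4.0, 8.0)) if spont else 0.0
        if rng.uniform() < 0.5:
            ph = Phenotype(spontaneous_rate=rate, stretch_response="sustained",
                           sustained_amplitude=float(rng.uniform(1.8, 2.5)))
        else:
            ph = Phenotype(spontaneous_rate=rate, stretch_response="oscillating")
        out.append(ph)
    return tuple(out)


def _place_cells(spec: SceneSpec, rng: np.random.Generator,
                 max_tries: int = 20000) -> tuple[np.ndarray, np.ndarray]:
    """Non-overlapping (y, x) centers and radii, valid in all phases.

    Placement is checked in pre-stretch coordinates (separation there implies
    larger separation after isotropic up-scaling) and containment is checked
    for the stretched geometry including drift.
    """
    h, w = spec.field_size
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    max_drift = max(max(abs(dy), abs(dx)) for dy, dx in spec.drift)
    centers: list[tuple[float, float]] = []
    radii: list[float] = []
    tries = 0
    while len(centers) < spec.n_cells:
        if tries >= max_tries:
            raise PlacementError(
                f"placed only {len(centers)}/{spec.n_cells} cells after "
                f"{max_tries} attempts; reduce n_cells or radii")
        tries += 1
        r = float(rng.uniform(*spec.cell_radius_range))
        rs = r * spec.stretch_scale
        margin = rs + max_drift + 3.0
        # sample in stretched coordinates so the stretched cell stays inside,
        # then back-project to the pre-stretch position
        ys = rng.uniform(margin, h - 1 - margin)
        xs = rng.uniform(margin, w - 1 - margin)
        y = cy + (ys - cy) / spec.stretch_scale
        x = cx + (xs - cx) / spec.stretch_scale
        ok = all((y - yc) ** 2 + (x - xc) ** 2 >= (r + rc + 4.0) ** 2
                 for (yc, xc), rc in zip(centers, radii))
        if ok:
            centers.append((y, x))
            radii.append(r)
    return np.array(centers), np.array(radii)


def _soft_disc_patch(center: tuple[float, float], radius: float,
                     shape: tuple[int, int], edge: float = 1.5):
    """Weight patch of a soft-edged disc; returns (slice_y, slice_x, weights)."""
    y0, x0 = center
    h, w = shape
    rr = radius + edge
    ylo, yhi = max(int(y0 - rr) - 1, 0), min(int(y0 + rr) + 2, h)
    xlo, xhi = max(int(x0 - rr) - 1, 0), min(int(x0 + rr) + 2, w)
    yy, xx = np.mgrid[ylo:yhi, xlo:xhi]
    d = np.sqrt((yy - y0) ** 2 + (xx - x0) ** 2)
    wgt = np.clip((radius - d) / edge + 0.5, 0.0, 1.0)
    return slice(ylo, yhi), slice(xlo, xhi), wgt


def vignette_profile(shape: tuple[int, int], strength: float) -> np.ndarray:
    """Radial illumination falloff, 1 at the center."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    r2 = ((yy - cy) ** 2 + (xx - cx) ** 2) / (cy ** 2 + cx ** 2)
    return 1.0 - strength * r2


def render_scene(spec: SceneSpec) -> SceneBundle:
    """Render a full four-phase recording of a synthetic scene.

    Returns the noisy uint16 stack, the dark and flat correction frames, a
    ground-truth label map in P III (stretch-phase) coordinates, a per-cell
    truth table and the per-cell event ground truth.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.field_size
    center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    centers, radii = _place_cells(spec, rng)

    phenotypes = spec.phenotypes
    if phenotypes is None:
        phenotypes = default_phenotype_mix(spec.n_cells, rng)

    schedule = spec.schedule
    t = schedule.times()
    phases = schedule.phase_of(t)
    cell_f0 = rng.uniform(*spec.cell_f0_range, size=spec.n_cells)

    rels = []
    truths: list[TraceTruth] = []
    for i in range(spec.n_cells):
        rel, truth = relative_signal(phenotypes[i], schedule, rng)
        rels.append(rel)
        truths.append(truth)

    # per-phase geometry: positions, radii and patches computed once; drift
    # translations are (dy, dx) in pixels
    drift = np.asarray(spec.drift, dtype=float)
    per_phase = []
    for ph in range(4):
        if ph == 2:
            pos = apply_stretch_transform(centers, spec.stretch_scale, center)
            rad = radii * spec.stretch_scale
        else:
            pos = centers.copy()
            rad = radii
        pos = pos + drift[ph]
        patches = [_soft_disc_patch((pos[i, 0], pos[i, 1]), rad[i], (h, w))
                   for i in range(spec.n_cells)]
        per_phase.append(patches)

    vign = vignette_profile((h, w), spec.noise.vignette_strength if spec.noise.enabled else 0.0)
    frames = np.empty((t.size, h, w), dtype=np.uint16)
    base = np.full((h, w), spec.noise.background, dtype=float)
    for k in range(t.size):
        ph = int(phases[k])
        clean = base.copy()
        patches = per_phase[ph]
        for i in range(spec.n_cells):
            sy, sx, wgt = patches[i]
            clean[sy, sx] += wgt * (cell_f0[i] * rels[i][k])
        photon = clean * vign
        if spec.noise.enabled:
            img = rng.poisson(photon * spec.noise.gain) / spec.noise.gain
            img = img + spec.noise.dark_offset
            img = img + rng.normal(0.0, spec.noise.read_sigma, size=img.shape)
        else:
            img = photon + spec.noise.dark_offset
        frames[k] = np.clip(np.round(img), 0, 65535).astype(np.uint16)

    dark = np.full((h, w), float(spec.noise.dark_offset))
    flat = vign * 1000.0 + spec.noise.dark_offset

    # ground-truth labels in P III coordinates (the segmentation frame)
    label_map = np.zeros((h, w), dtype=np.uint16)
    pos3 = apply_stretch_transform(centers, spec.stretch_scale, center) + drift[2]
    rad3 = radii * spec.stretch_scale
    yy, xx = np.mgrid[0:h, 0:w]
    for i in range(spec.n_cells):
        mask = (yy - pos3[i, 0]) ** 2 + (xx - pos3[i, 1]) ** 2 <= rad3[i] ** 2
        label_map[mask] = i + 1

    rows = []
    for i in range(spec.n_cells):
        p = phenotypes[i]
        rows.append({
            "cell_id": i + 1,
            "y_pre": centers[i, 0], "x_pre": centers[i, 1],
            "y_stretch": pos3[i, 0], "x_stretch": pos3[i, 1],
            "radius_px": radii[i],
            "area_pre_px2": math.pi * radii[i] ** 2,
            "area_stretch_px2": math.pi * rad3[i] ** 2,
            "f0": cell_f0[i],
            "spontaneous_rate": p.spontaneous_rate,
            "drug_rate_multiplier": p.drug_rate_multiplier,
            "stretch_response": p.stretch_response,
            "sustained_amplitude": p.sustained_amplitude,
            "peak_amplitude": p.peak_amplitude,
            "n_events": len(truths[i].event_times),
            "event_times": ";".join(f"{e:.3f}" for e in truths[i].event_times),
        })
    truth = pd.DataFrame(rows)
    return SceneBundle(frames=frames, times=t, phase_tags=phases, dark=dark,
                       flat=flat, label_map=label_map, truth=truth,
                       cell_truths=truths, spec=spec)


def write_scene(bundle: SceneBundle, out_dir: str | Path) -> dict[str, Path]:
    """Write a rendered scene to disk: TIFFs for images, CSV for truth."""
    import tifffile

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "stack": out / "stack.tif",
        "dark": out / "dark.tif",
        "flat": out / "flat.tif",
        "labels": out / "labels_truth.tif",
        "truth": out / "truth.csv",
    }
    tifffile.imwrite(paths["stack"], bundle.frames)
    tifffile.imwrite(paths["dark"], bundle.dark.astype(np.float32))
    tifffile.imwrite(paths["flat"], bundle.flat.astype(np.float32))
    tifffile.imwrite(paths["labels"], bundle.label_map)
    bundle.truth.to_csv(paths["truth"], index=False)
    return paths
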