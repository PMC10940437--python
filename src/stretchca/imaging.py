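"""From raw image stacks to per-cell raw intensity traces.

The stages mirror a standard stretch-imaging workflow: dark/flat correction,
splitting the time-lapse into the pre-stretch / stretch / release phase
groups (the field of view shifts and scales when the chamber is stretched,
so each group lives in its own coordinate frame), translational drift
registration within a group, cell segmentation on the temporal maximum
projection of the stretch group (best signal-to-noise: most cells light up
under stretch), estimation of a similarity transform between phase groups,
carrying the segmented ROIs into the other groups through that transform,
and extraction of mean ROI intensity per frame.

Coordinate convention: pixel-centered, origin at the top-left, x right and
y down; arrays are indexed (y, x); label maps use 0 for background and
contiguous positive integers for cells.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage as ndi
from scipy.optimize import minimize_scalar
from skimage.filters import gaussian, threshold_otsu
from skimage.registration import phase_cross_correlation
from skimage.segmentation import watershed

from .errors import CorrectionError, RegistrationError, TransformEstimationError
from .schedule import PhaseSchedule
from .traces import RawTrace

logger = logging.getLogger(__name__)

__all__ = [
    "FrameStack",
    "CorrectionFrames",
    "LabelMap",
    "SimilarityTransform",
    "SegmentationParams",
    "correct_stack",
    "split_phases",
    "register_drift",
    "segment_cells",
    "estimate_phase_transform",
    "map_rois",
    "extract_traces",
]

GROUP_NAMES = ("pre", "stretch", "release")
#: phase indices belonging to each phase group
GROUP_PHASES = {"pre": (0, 1), "stretch": (2,), "release": (3,)}


@dataclass
class FrameStack:
    """An ordered stack of equally sized 2-D frames with timing metadata."""

    frames: np.ndarray          # (T, H, W)
    times: np.ndarray           # (T,) seconds
    phase_tags: np.ndarray      # (T,) phase index per frame
    frame_period: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (T, H, W) array")
        self.times = np.asarray(self.times, dtype=float)
        self.phase_tags = np.asarray(self.phase_tags, dtype=int)
        if not (len(self.times) == len(self.frames) == len(self.phase_tags)):
            raise ValueError("times/phase_tags must match the frame count")
        if self.frame_period <= 0:
            raise ValueError("frame_period must be positive")
        if np.any(np.diff(self.phase_tags) < 0):
            raise ValueError("phase tags must be non-decreasing")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    def max_projection(self) -> np.ndarray:
        return self.frames.max(axis=0)


@dataclass
class CorrectionFrames:
    """Dark frame and flat-field frame (flat as recorded, dark included)."""

    dark: np.ndarray
    flat: np.ndarray

    def normalized_flat(self) -> np.ndarray:
        """Dark-subtracted flat scaled to unit mean; must be positive."""
        f = np.asarray(self.flat, dtype=float) - np.asarray(self.dark, dtype=float)
        if f.min() <= 0:
            raise CorrectionError("flat-field is non-positive after dark subtraction")
        return f / f.mean()


@dataclass
class LabelMap:
    """Integer label image: 0 background, k > 0 cell k."""

    labels: np.ndarray
    coordinate_frame: str = "stretch"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("label map must be 2-D")

    @property
    def ids(self) -> np.ndarray:
        u = np.unique(self.labels)
        return u[u > 0]


@dataclass(frozen=True)
class SimilarityTransform:
    """Scale + rotation + translation about a fixed center.

    Maps source coordinates to target coordinates as
    ``p_target = center + scale * R(rotation) @ (p_source - center) + translation``
    with coordinates in (y, x) pixel order.
    """

    scale: float
    rotation: float = 0.0
    translation: tuple[float, float] = (0.0, 0.0)
    center: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    def _rot(self) -> np.ndarray:
        c, s = np.cos(self.rotation), np.sin(self.rotation)
        return np.array([[c, -s], [s, c]])

    def apply(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points, dtype=float))
        c = np.asarray(self.center)
        t = np.asarray(self.translation)
        return c + self.scale * (self._rot() @ (p - c).T).T + t

    def inverse_apply(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points, dtype=float))
        c = np.asarray(self.center)
        t = np.asarray(self.translation)
        return c + (self._rot().T @ ((p - c - t) / self.scale).T).T

    def inverse(self) -> "SimilarityTransform":
        c = np.asarray(self.center)
        t = np.asarray(self.translation)
        tinv = -(self._rot().T @ t) / self.scale
        return SimilarityTransform(scale=1.0 / self.scale, rotation=-self.rotation,
                                   translation=tuple(tinv), center=tuple(c))


@dataclass(frozen=True)
class SegmentationParams:
    """Parameters of threshold + maxima-seeded watershed segmentation."""

    threshold: Optional[float] = None   # None -> Otsu on the max projection
    min_area: int = 30                  # px^2; smaller ROIs discarded
    min_distance: int = 8               # px between watershed seeds
    smoothing_sigma: float = 3.0        # px, Gaussian smoothing before seeding


def correct_stack(stack: FrameStack, corr: CorrectionFrames) -> FrameStack:
    """Dark-subtract and flat-divide every frame; clip negatives at zero."""
    dark = np.asarray(corr.dark, dtype=float)
    if dark.shape != stack.shape:
        raise ValueError(f"dark frame shape {dark.shape} != stack shape {stack.shape}")
    flatn = corr.normalized_flat()
    if flatn.shape != stack.shape:
        raise ValueError(f"flat frame shape {flatn.shape} != stack shape {stack.shape}")
    out = np.clip((stack.frames.astype(float) - dark) / flatn, 0.0, None)
    return FrameStack(out, stack.times.copy(), stack.phase_tags.copy(),
                      stack.frame_period)


def split_phases(stack: FrameStack, schedule: PhaseSchedule) -> dict[str, FrameStack]:
    """Partition a stack into pre-stretch (P I + P II), stretch (P III) and
    release (P IV) groups by half-open time windows."""
    if len(stack) == 0 or stack.times[-1] + stack.frame_period < schedule.ends[3] - 1e-9:
        raise ValueError("schedule extends beyond the stack")
    groups: dict[str, FrameStack] = {}
    for name, phases in GROUP_PHASES.items():
        lo = schedule.starts[phases[0]]
        hi = schedule.ends[phases[-1]]
        sel = (stack.times >= lo) & (stack.times < hi)
        groups[name] = FrameStack(stack.frames[sel], stack.times[sel],
                                  stack.phase_tags[sel], stack.frame_period)
    return groups


def register_drift(stack: FrameStack, reference_index: int = 0,
                   min_correlation: float = 0.2,
                   upsample_factor: int = 10) -> tuple[FrameStack, list[SimilarityTransform]]:
    """Translation-only registration of every frame to a reference frame.

    Returns the resampled stack and, per frame, the transform mapping
    original to reference coordinates.  Frames that cannot be matched to the
    reference (featureless, or correlation below ``min_correlation`` after
    alignment) raise :class:`RegistrationError` naming the frame.
    """
    if len(stack) == 0:
        raise ValueError("cannot register an empty stack")
    if not 0 <= reference_index < len(stack):
        raise ValueError("reference_index out of range")
    ref = stack.frames[reference_index].astype(float)
    if ref.std() == 0:
        raise RegistrationError(f"reference frame {reference_index} is featureless")
    # Hann window + demeaning suppress FFT edge artefacts in the shift estimate
    h, w = ref.shape
    window = np.hanning(h)[:, None] * np.hanning(w)[None, :]
    ref_w = (ref - ref.mean()) * window
    out = np.empty_like(stack.frames, dtype=float)
    transforms: list[SimilarityTransform] = []
    for k in range(len(stack)):
        frame = stack.frames[k].astype(float)
        if frame.std() == 0:
            raise RegistrationError(f"frame {k} is featureless (constant)")
        shift, _, _ = phase_cross_correlation(ref_w, (frame - frame.mean()) * window,
                                              normalization=None,
                                              upsample_factor=upsample_factor)
        if np.all(np.abs(shift) < 0.05):
            aligned = frame
            shift = np.zeros(2)
        else:
            aligned = ndi.shift(frame, shift, order=1, mode="nearest")
        cc = np.corrcoef(ref.ravel(), aligned.ravel())[0, 1]
        if not np.isfinite(cc) or cc < min_correlation:
            raise RegistrationError(
                f"frame {k} failed registration (correlation {cc:.3f} "
                f"below {min_correlation})")
        out[k] = aligned
        # original -> reference: the frame content moves by +shift
        transforms.append(SimilarityTransform(scale=1.0, rotation=0.0,
                                              translation=tuple(shift)))
    return FrameStack(out, stack.times.copy(), stack.phase_tags.copy(),
                      stack.frame_period), transforms


def segment_cells(stretch_stack: FrameStack,
                  params: SegmentationParams = SegmentationParams()) -> LabelMap:
    """Segment cells on the temporal maximum projection of the stretch group.

    Foreground comes from a global threshold (Otsu by default, user override
    via ``params.threshold``); labels from a watershed seeded at every
    regional maximum of the Gaussian-smoothed projection (equal-plateau
    maxima merge into one seed).  ROIs smaller than ``min_area`` or touching
    the image border are removed and the rest renumbered contiguously.
    """
    if len(stretch_stack) == 0:
        raise ValueError("cannot segment an empty stack")
    proj = stretch_stack.max_projection().astype(float)
    smooth = gaussian(proj, sigma=params.smoothing_sigma, preserve_range=True)
    if params.threshold is not None:
        thr = float(params.threshold)
    else:
        if smooth.max() == smooth.min():
            warnings.warn("blank stack: empty segmentation", stacklevel=2)
            return LabelMap(np.zeros(proj.shape, dtype=np.int32))
        # Otsu in log space: fluorescence spans a wide dynamic range (bright
        # responders vs resting cells) and a linear-domain threshold would
        # cut off dim but clearly supra-background cells
        thr = float(np.expm1(threshold_otsu(np.log1p(np.clip(smooth, 0, None)))))
    mask = smooth > thr
    if not mask.any():
        warnings.warn("empty foreground after thresholding", stacklevel=2)
        return LabelMap(np.zeros(proj.shape, dtype=np.int32))

    size = 2 * params.min_distance + 1
    maxima = (smooth == ndi.maximum_filter(smooth, size=size)) & mask
    seed_labels, n_seeds = ndi.label(maxima)
    if n_seeds == 0:
        warnings.warn("no watershed seeds found", stacklevel=2)
        return LabelMap(np.zeros(proj.shape, dtype=np.int32))
    labels = watershed(-smooth, markers=seed_labels, mask=mask, connectivity=1)

    # Per-cell half-maximum refinement: the global threshold is inclusive so
    # dim resting cells are detected, but it overshoots the boundary of
    # bright cells; each ROI is cut back at half its own peak intensity
    # above the background level.
    bg = float(np.median(smooth[~mask])) if (~mask).any() else 0.0
    refined = np.zeros_like(labels)
    for lab in np.unique(labels):
        if lab == 0:
            continue
        region = labels == lab
        peak = float(smooth[region].max())
        keep = region & (smooth >= bg + 0.5 * (peak - bg))
        if not keep.any():
            continue
        comp, n = ndi.label(keep)
        if n > 1:  # keep the component holding the maximum
            sizes = ndi.sum_labels(np.ones_like(comp), comp, index=range(1, n + 1))
            keep = comp == (int(np.argmax(sizes)) + 1)
        refined[keep] = lab
    labels = refined

    h, w = labels.shape
    border = np.zeros_like(labels, dtype=bool)
    border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
    drop = set(np.unique(labels[border])) - {0}
    keep = []
    for lab in np.unique(labels):
        if lab == 0 or lab in drop:
            continue
        if int((labels == lab).sum()) >= params.min_area:
            keep.append(lab)
    out = np.zeros_like(labels, dtype=np.int32)
    for new, lab in enumerate(keep, start=1):
        out[labels == lab] = new
    return LabelMap(out, coordinate_frame="stretch")


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    return float((a * b).sum() / denom) if denom > 0 else 0.0


def _warp_scale(img: np.ndarray, scale: float, center: np.ndarray) -> np.ndarray:
    """Resample img scaled by ``scale`` about ``center`` (output frame fixed)."""
    # output pixel p maps back to source pixel center + (p - center)/scale
    matrix = np.eye(2) / scale
    offset = center - matrix @ center
    return ndi.affine_transform(img, matrix, offset=offset, order=1, mode="nearest")


def estimate_phase_transform(source_image: np.ndarray, target_image: np.ndarray,
                             scale_range: tuple[float, float] = (0.75, 1.35),
                             ) -> SimilarityTransform:
    """Estimate the similarity transform between two phase-group images.

    Finds the isotropic scale (about the image center) and translation that
    maximize the normalized cross-correlation between the warped source and
    the target; rotation is assumed negligible (the stretch device scales
    isotropically).  Used to absorb the stretch-induced scale change between
    phase groups.
    """
    src = np.asarray(source_image, dtype=float)
    tgt = np.asarray(target_image, dtype=float)
    if src.shape != tgt.shape:
        raise ValueError("source and target must share dimensions")
    if src.std() == 0 or tgt.std() == 0:
        raise TransformEstimationError("constant image: transform is undefined")
    src_s = gaussian(src, sigma=1.5, preserve_range=True)
    tgt_s = gaussian(tgt, sigma=1.5, preserve_range=True)
    center = (np.asarray(src.shape, dtype=float) - 1.0) / 2.0

    def score(scale: float) -> tuple[float, np.ndarray]:
        warped = _warp_scale(src_s, scale, center)
        shift, _, _ = phase_cross_correlation(tgt_s, warped, normalization=None,
                                              upsample_factor=10)
        aligned = ndi.shift(warped, shift, order=1, mode="nearest")
        return _ncc(tgt_s, aligned), shift

    coarse = np.linspace(scale_range[0], scale_range[1], 25)
    scores = [score(s)[0] for s in coarse]
    best = int(np.argmax(scores))
    lo = coarse[max(best - 1, 0)]
    hi = coarse[min(best + 1, len(coarse) - 1)]
    res = minimize_scalar(lambda s: -score(s)[0], bounds=(lo, hi),
                          method="bounded", options={"xatol": 5e-4})
    scale = float(res.x)
    ncc, shift = score(scale)
    if ncc < 0.2:
        raise TransformEstimationError(
            f"transform estimation degenerate (best correlation {ncc:.3f})")
    return SimilarityTransform(scale=scale, rotation=0.0,
                               translation=tuple(np.asarray(shift)),
                               center=tuple(center))


def map_rois(labels: LabelMap, transform: SimilarityTransform,
             target_frame: str = "mapped") -> tuple[LabelMap, list[int]]:
    """Carry a label map into another coordinate frame.

    Each target pixel looks up its label through the inverse transform with
    nearest-neighbour sampling, so label identities are preserved exactly.
    Labels whose every pixel maps outside the field are dropped and returned
    in the second element.
    """
    lab = labels.labels
    h, w = lab.shape
    yy, xx = np.mgrid[0:h, 0:w]
    pts = np.stack([yy.ravel(), xx.ravel()], axis=1).astype(float)
    src = transform.inverse_apply(pts)
    sy = np.round(src[:, 0]).astype(int)
    sx = np.round(src[:, 1]).astype(int)
    inside = (sy >= 0) & (sy < h) & (sx >= 0) & (sx < w)
    out = np.zeros(h * w, dtype=lab.dtype)
    out[inside] = lab[sy[inside], sx[inside]]
    out = out.reshape(h, w)
    dropped = sorted(set(np.unique(lab)) - set(np.unique(out)) - {0})
    if dropped:
        logger.warning("labels dropped in ROI mapping: %s", dropped)
    return LabelMap(out, coordinate_frame=target_frame), [int(d) for d in dropped]


def extract_traces(phase_stacks: dict[str, FrameStack],
                   labelmaps: dict[str, LabelMap],
                   schedule: PhaseSchedule,
                   sample_id: str = "sample") -> tuple[list[RawTrace], set[int]]:
    """Mean ROI intensity per cell per frame, concatenated over phase groups.

    Cells whose label is missing from some phase group get a trace covering
    only the groups where they exist and are returned in the incomplete set
    (downstream classification marks them INCOMPLETE).  A label present in
    no group at all raises a ``ValueError``.
    """
    all_ids = sorted(set().union(*(set(labelmaps[g].ids.tolist())
                                   for g in GROUP_NAMES if g in labelmaps)))
    if not all_ids:
        return [], set()
    per_cell_t: dict[int, list] = {i: [] for i in all_ids}
    per_cell_v: dict[int, list] = {i: [] for i in all_ids}
    per_cell_p: dict[int, list] = {i: [] for i in all_ids}
    incomplete: set[int] = set()
    for g in GROUP_NAMES:
        stack, labmap = phase_stacks[g], labelmaps[g]
        lab = labmap.labels.ravel()
        nmax = int(lab.max()) + 1 if lab.size else 1
        counts = np.bincount(lab, minlength=nmax)
        present = {i for i in all_ids if i < nmax and counts[i] > 0}
        for i in all_ids:
            if i not in present:
                incomplete.add(i)
        for k in range(len(stack)):
            sums = np.bincount(lab, weights=stack.frames[k].ravel().astype(float),
                               minlength=nmax)
            for i in present:
                per_cell_t[i].append(stack.times[k])
                per_cell_v[i].append(sums[i] / counts[i])
                per_cell_p[i].append(stack.phase_tags[k])
    traces = []
    for i in all_ids:
        if not per_cell_t[i]:
            raise ValueError(f"label {i} absent from every phase group")
        traces.append(RawTrace(time_s=np.asarray(per_cell_t[i]),
                               values=np.asarray(per_cell_v[i]),
                               phase=np.asarray(per_cell_p[i]),
                               cell_id=i, sample_id=sample_id))
    return traces, incomplete
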