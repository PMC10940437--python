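# Methods

This note records the models, defaults and numerical choices behind
`stretchca`, and what the synthetic benchmark does and does not establish.

## Experimental model

An experiment is four contiguous one-minute phases sampled at 10 frames/s:
P I pre-stretch baseline (optionally with the mechanosensitive-channel
blocker GsMTx4 present), P II drug window (optionally the Piezo1 agonist
Yoda1 is added), P III with 15% isotropic radial stretch of the substrate,
P IV after release. Phase windows are half-open `[start, end)`, so every
frame and every peak apex belongs to exactly one phase. All of these are
configurable; the values above are the package defaults.

## Trace analysis

**Normalization.** S₀ is the mean of the earliest 3-s window of P I that
contains no Ca²⁺ transient. Peaks are pre-detected on a provisionally
normalized trace (raw / median of P I), and a window is considered to
contain a peak when it overlaps the peak's extent measured at 95% of its
prominence below the apex — apex-only exclusion would let decay tails leak
into the baseline. The window search advances one frame at a time
(deterministic); if no peak-free window exists in P I, S₀ falls back to
the mean of the lowest 10% of P I samples. Whether the original protocol
used strictly the first 3 s or any 3-s window is ambiguous; the earliest
clean window is used here.

**Peak detection** uses topographic prominence (`scipy.signal.find_peaks`)
with an inclusive threshold of 0.3 relative units. Plateau maxima are
reported once, at the leftmost sample. The test suite checks the detector
for exact agreement (indices, heights, prominences) against an exhaustive
brute-force oracle that scans left/right to higher ground for every local
maximum.

**Peak height** is the relative signal value at the apex, not the
prominence: phase-level summaries report signal levels, and the apex value
is the natural reading of that. Peaks are detected once on the full-length
trace rather than per phase, so prominence sees cross-phase context;
phase-local detection would inflate prominence at phase boundaries.

**Baseline intensity (BI)** is the 10th percentile of the relative trace
within a window. The estimator is a declared design choice (the underlying
protocol does not define one): a low percentile tracks the plateau level,
ignores superimposed transients occupying < ~10% of samples, and still
follows a sustained elevation, which the P III criterion requires.

**Sustained-elevation rule.** With E = BI(first third of the phase) −
BI(P II): sustained iff E ≥ 1.5 relative units and BI of each remaining
third ≥ BI(P II) + 0.2·E. All inequalities are inclusive ("at least"
semantics), verified by fixtures lying exactly on both thresholds. For
P IV the reference baseline remains BI(P II), as for P III.

**Classification.** Spontaneity is judged on P I alone (≥ 2 peaks); a
config switch `spontaneous_includes_PII` widens it to P I + P II for users
who prefer the broader reading. A peakless sustained elevation in P III
still makes a cell stretch-activated — a saturating sustained response can
show at most one detectable peak, and would otherwise land in the
random-peaks bin. Markers are computed for all classified cells;
random-peaks and no-peaks cells are flagged excluded from response
analyses. Cells missing frames in any phase (e.g. ROI lost in a phase
group) are INCOMPLETE and never classified.

## Image pipeline

Correction is `(frame − dark) / flat` with the dark-subtracted flat
normalized to unit mean, clipped at zero. Drift registration is
translation-only within a phase group (phase cross-correlation with 0.1-px
upsampling on Hann-windowed, demeaned frames; the window suppresses FFT
edge artefacts). Frames that are constant or whose post-alignment
correlation with the reference falls below 0.2 raise a registration error
naming the frame.

Segmentation runs on the temporal maximum projection of the stretch group,
which has the best signal-to-noise (most cells light up under stretch).
The manual threshold of the original workflow is replaced by an automatic
global Otsu threshold computed in log space — fluorescence spans a wide
dynamic range and a linear-domain Otsu cuts off dim resting cells — with
an optional user override. Watershed seeds are the regional maxima of the
Gaussian-smoothed (σ = 3 px) projection, equal-plateau maxima merged into
one seed, minimum seed separation 8 px. Each watershed region is then cut
back at half its own peak intensity above background, which keeps the
inclusive global threshold from bloating bright cells' ROIs. ROIs smaller
than 30 px² or touching the border are removed (partial cells bias
mean-intensity traces), and labels are renumbered contiguously.

The cross-phase mapping replaces the original elastic warp with a
similarity transform (isotropic scale + translation about the image
center; rotation fixed at 0 because the stretch device scales
isotropically by construction). The scale is found by a coarse scan plus
bounded 1-D refinement maximizing normalized cross-correlation, with the
translation estimated by phase correlation at each candidate scale. ROIs
are carried between frames by nearest-neighbour lookup through the inverse
transform, preserving label identity; labels mapped fully outside the
field are dropped and reported. Traces are the mean (not integrated) ROI
intensity per frame — mean is invariant under the area change that stretch
induces; the original protocol does not state its choice.

Coordinates are pixel-centered, origin top-left, y down / x right; label
maps are 0-background with contiguous positive labels.

## Statistics

Two groups at a time: Shapiro–Wilk on each at α = 0.05; ANOVA iff both
pass, else Kruskal–Wallis H; two-sided p; significant at p < 0.05. No
multiplicity correction by default (faithful to the underlying protocol);
Holm step-down is available as an opt-in. Constant groups are routed to
the nonparametric branch (the Shapiro–Wilk statistic is undefined for
them), and two identical constant groups compare as trivially
non-significant. Percentages are computed per sample before pooling; the
unit of analysis for category comparisons is the per-sample percentage,
while peak-height/baseline comparisons pool cells with the replicate id
retained.

## Synthetic data

The generator emulates Fluo-4-loaded HL-1 cells. Transients use a
fast-rise/exponential-decay kernel (double exponential, τ_rise = 0.1 s
giving ~0.3 s time-to-peak, τ_decay = 1.5 s), amplitudes jittered ±20%
around a per-cell typical height (default 1.0 relative units). Event times
are a homogeneous Poisson process per phase at the phenotype's rate
(spontaneous cells default to 4–8 peaks/min, a realistic range for
spontaneously oscillating HL-1 cultures), with events closer than 2 s to
their predecessor dropped so every ground-truth event is a resolvable
peak; the truth list contains only kept events. Sustained responders add a
saturating plateau (τ = 1 s rise) during P III that decays with τ = 15 s
after release, plus one initial transient at stretch onset; oscillating
responders fire at ≥ 6 peaks/min during P III. Raw traces are scaled to
~400 counts and carry Poisson-like shot noise (variance ∝ signal, gain 2)
plus Gaussian read noise.

Scenes render cells as non-overlapping soft-edged discs (radius 6–10 px)
whose brightness follows a simulated trace, on a background with radial
vignetting (strength 0.3), a dark offset of 100 counts, shot noise and
read noise, written as 16-bit values. At P III onset all positions and
radii scale by the stretch factor about the field center and a small
per-phase translation emulates chamber drift; at P IV the geometry returns
to pre-stretch. The ground-truth label map is defined in P III coordinates
(the segmentation frame). Cells are placed by rejection sampling in
stretched coordinates (so stretched cells stay inside the field) with
non-overlap enforced in pre-stretch coordinates; placement failure after a
bounded number of tries raises an error. Everything is deterministic per
seed.

What the generator does **not** model: photobleaching, dye buffering and
saturation kinetics, contraction-induced shape change, focus drift,
non-rigid chamber deformation, cell clumping/overlap, and realistic
heterogeneous morphologies. Passing tests therefore demonstrate the
correctness of the algorithms under the stated model, not performance on
real recordings; in particular real elastic deformations may exceed what a
similarity transform absorbs, and real SNR figures are unknown (noise
defaults were chosen for testability).

A phenotype with a low spontaneous rate can genuinely emit fewer than two
events in a one-minute window, so recovered spontaneous fractions sit
slightly below the generating fraction; the binomial-interval check in the
acceptance suite accommodates this realization noise.

## Problem sizes and runtime

Trace-level analyses use the full 10 frames/s acquisition rate. Rendered
scenes default to 5 frames/s, and the benchmark scenes in the tests and
the acceptance script use 2 frames/s at 384×384 px (50 cells) and
192×192 px (6 cells) — geometric and segmentation contracts do not depend
on temporal sampling, and these sizes keep the full validation run in the
order of a minute on a single core. The statistics calibration uses 2000
Monte-Carlo repetitions (n = 50 per group); phenotype-recovery cohorts use
100 cells per fraction.

## Known limitations

* The similarity transform absorbs only global scale + translation;
  hooks exist for thin-plate-spline refinement but none is implemented.
* Registration is translation-only within a phase group; rotational drift
  is not corrected.
* S₀ estimation assumes the cell is quiescent somewhere in P I; a cell
  oscillating faster than one event per 3 s falls back to the low-percentile
  estimator, which slightly underestimates S₀ in heavy noise.
* The statistics module implements the gated two-group protocol exactly as
  specified, including its lack of multiplicity correction; for modern use
  enable the Holm option.
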