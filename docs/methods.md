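# Methods

This note documents the models behind each pipeline stage, the parameter
choices that matter, what the synthetic generators do and do not emulate,
and the numerical conventions that make results bit-reproducible.

## Synthetic data: what it emulates

The generators exist so every downstream stage can be validated against
known ground truth.  They emulate the *measurement structure* of the assays,
not larval biophysics.

**Temperature profiles** are piecewise linear:
baseline → ramp-down → hold → ramp-up → recovery, with optional Gaussian
sensor noise.  Named paradigms carry the stimulus conventions of the assay
family: `gcamp` (30 s baseline at 25 °C, ramp to 6 °C at 20 °C/min, 10 s
hold), `ephys` (30 s at ~22 °C, fast 3.3 °C/s ramp to the target, 60 s
hold), and `behavior` (brief room-temperature baseline, then contact with a
10 °C plate modeled as a fast ramp).  Every parameter is overridable.

**Area traces.**  A responder's silhouette area falls from baseline to
(1 − magnitude)·baseline over a half-cosine transition (default 0.3 s; 0
gives a step), holds for the contraction duration, and relaxes
exponentially (default τ = 1 s).  Noise is multiplicative Gaussian per
frame (default sd 2%), approximating segmentation jitter.  Cohorts draw
responder status i.i.d. Bernoulli(p_ct) and per-animal magnitude/duration
from clipped normals — defaults magnitude 0.25 ± 0.04 (floor 0.15) and hold
duration 2.5 ± 0.5 s (floor 0.7 s).  The floors keep simulated responders
in the clearly-detectable regime (a contraction near the −10% criterion
would be an ambiguous "responder" label under frame noise, which is a
property of the label, not of the measurement code).  Real traces have
locomotion, head sweeps, and occlusions that these traces do not; passing
tests therefore validates the *metric definitions*, not robustness to every
behavior a plate video can contain.

**Spike trains.**  Tonic firing is a renewal process whose hazard follows
temperature — base rate (default 1 Hz) plus a cold gain (0.25 Hz/°C below
18 °C) — with inter-spike intervals drawn as a refractory floor plus an
exponential, so the mean rate equals the hazard exactly.  Burst events
arrive as an inhomogeneous Poisson process on the cooling rate (default 0.5
bursts per °C dropped), each a run of ≥ 3 spikes with intra-burst intervals
uniform on [0.02, 0.12] s.  The generator's ISI regimes are placed strictly
on either side of the 0.15 s classifier cutoff (intra-burst < 0.15 s
required; tonic floor > 0.15 s required), and tonic spikes landing within
the cutoff of a burst are removed, so ground-truth labels are recoverable
by construction; parameter sets that overlap the cutoff are rejected rather
than silently generating unrecoverable labels.  No bursting adaptation,
temperature hysteresis, or spike-amplitude structure is modeled.

**Neuron images** are a soma disk plus straight radial dendrites over a
uniform background; the red channel is a specified ratio field ρ (constant,
radius-dependent, or per-pixel) times the green channel, plus optional
Gaussian noise.  Real CaMPARI stacks add depth blur, neighboring neurites,
and registration error, all out of scope here.

**Larva videos** rasterize each area trace as a fixed-aspect-ratio ellipse
(default 3:1) on a gray arena.  Rasterization keeps pixel area within about
1% of the requested area at the default ~2,000 px² silhouette; the exact
rasterized areas are stored as ground truth so tests can separate
rasterization error from measurement error.

**Touch cohorts** are independent Bernoulli draws per behavior, trial, and
animal — no trial-order or habituation structure.

All generators take a single seed and touch no global random state;
identical seeds give bit-identical outputs.

## Behavior quantification

Arena frames are thresholded with the Triangle method, connected components
above the minimum blob area (default 100 px²) become animals, and each is
cropped to 250 × 250 px around its centroid (flagged when clipped at an
edge).  Within each crop, background is removed per frame by Li
thresholding and only the component nearest the crop center is kept, so
overlapping crops never inherit a neighbor's pixels.  Area is the
foreground pixel count; empty-mask frames record area 0 and are flagged.

The percent-change reference ("initial area") defaults to the mean area
over the 0.5 s immediately before stimulus onset — robust to single-frame
noise — with the single onset frame available by option.  CT duration
counts *all* sub-threshold time in the window, not only the qualifying run,
matching the "total time below −10%" convention.  Samples exactly at −10%
count as sub-threshold, and a run of exactly 0.5 s qualifies (both
boundaries are measure-zero on real data but are pinned down for
reproducibility).  The analysis window defaults to the first 5 s of
stimulus (cold plate); optogenetic experiments conventionally use the 10 s
light-on period, set via the `window` argument.  Animals not elongated at
onset are excluded via a major/minor axis ratio test (default ≥ 2.0), an
objective proxy for the manual analyzability criterion.  Cohort CT
magnitude averages over all analyzed animals (responders-only available by
filtering the metrics list).

## Thresholding

Triangle, Li, and Moments operate on a 256-bin histogram (exact 0–255 for
8-bit input, uniform binning otherwise), matching the classic ImageJ
implementations in spirit but specified exactly:

- **Triangle**: the bin between the histogram peak and the far end of the
  longer tail that maximizes perpendicular distance to the chord joining
  peak and tail end *at their actual heights*.  With both endpoints on the
  histogram the argmax is invariant to axis scaling, so no normalization
  step is needed.
- **Li**: exhaustive minimization of the cross-entropy criterion
  −Σ_low g·h·log μ_low − Σ_high g·h·log μ_high over all 255 cuts (rather
  than the iterative fixed-point scheme, whose result can depend on
  initialization).  Exact ties — e.g. a run of empty bins between two
  separated modes — keep the last minimizing cut, placing the threshold
  against the bright mode.
- **Moments** (Tsai): the closed-form moment-preserving fraction p₀ from
  the first three gray-level moments, then the bin whose cumulative
  fraction is closest to p₀.

Each selector is validated against an independently coded brute-force
criterion search in the test suite.

## Imaging

The CaMPARI soma pipeline thresholds the green channel (Moments), removes
thin branches with a morphological opening (disk radius 2 px by default),
and keeps connected components within the area filter as ROIs.  The
reported ratio is (red sum)/(green sum) over the ROI — identical to the
ratio of area-normalized means since both channels share the ROI area.

Radial profiles use annuli of width 5 px at 1 px steps: a pixel belongs to
the annulus at radius r when its center-to-center Euclidean distance from
the profile center lies in the closed interval [r − 2.5, r + 2.5] and it is
inside the neuron's foreground mask.  Consecutive annuli overlap by
construction; with step = width they tile the mask.  The per-radius ratio
is (sum red)/(sum green) by default — robust to zero-green pixels — with
mean-of-pixel-ratios available by flag.  The profile center is the
intensity-weighted centroid of the soma ROI by default (geometric centroid
by option).  No background subtraction is applied before ratioing.
Classic Sholl intersection counts walk each sampling circle at 4 samples
per pixel of arc, collapse duplicate pixels, and count cyclic runs of
foreground.

ΔF/F uses the baseline-window mean; the peak window defaults to stimulus
onset through the end of the trace.  ΔF/F is exactly invariant to channel
scaling and identically zero for constant F.

## Electrophysiology

Spike detection is threshold crossing with a refractory period —
deliberately minimal, since suction-electrode recordings here are
single-unit; waveform sorting is out of scope.  The burst rule uses a
strict inequality (an ISI exactly 0.15 s does not join a burst) on maximal
runs: any qualifying group of ≥ 3 spikes lies inside exactly one maximal
run, so labels are unique and bursts cannot overlap.  Classification is
global, before binning, so a burst straddling a bin edge keeps its label
and per-bin counts conserve total = burst + tonic exactly.  Default epochs:
room temperature = the 30 s before onset; stimulus = 60 s from onset;
"first 10 s" starts at the onset annotation.  Per-condition rates average
per animal and then across animals; pooling is available by working with
the per-bin counts directly.

## Statistics

Fisher's exact test enumerates the hypergeometric support with a 1 + 1e-7
relative guard on probability ties (the convention of common
implementations); tests verify agreement with exact rational enumeration to
1e-12 for margins up to 40.  BH and Holm–Šídák return standard adjusted
p-values.  The BKY procedure is the two-stage linear step-up variant (the
common default): stage 1 at α′ = α/(1+α) estimates m₀ = m − r₁; stage 2
reruns BH at α′·m/m₀.  Its primary output is the rejection flags; the
reported pseudo-adjusted values are the standard construction
BH_adj · m₀/m (to be compared against α′) and are labeled as such.
Kruskal–Wallis, Mann–Whitney, one-way ANOVA and paired t are thin scipy
wrappers — they are standard routines, not part of this package's
contribution — and the implemented adjustments are cross-checked against
statsmodels in the tests.

## Problem sizes and determinism

The test and acceptance workloads use desk-scale sizes chosen to make the
Monte-Carlo bounds tight enough to be meaningful: 1,000 random trains for
the burst oracle, 200-animal cohorts over 20 seeds for %CT recovery,
10,000 replicates for the null-FDR simulation, 50 runs for the power
simulation, and 256 × 256 images for profile oracles.  Every stochastic
path flows through explicit seeds; reports carry the config hash and seed.

## Known limitations

- No image registration/stabilization; inputs are assumed registered.
- No multi-animal identity tracking through occlusions or collisions.
- The spike generator's burst timing is memoryless within a ramp; real
  cold-evoked bursting shows adaptation the generator does not produce.
- Acceptance is property-based on synthetic data: the live-animal effect
  sizes reported in the literature (genotype differences in %CT, firing
  composition, ΔF/F peaks) depend on recordings this package does not
  model, and are not reproduced here.
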