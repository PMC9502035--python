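"""Cold-plate / optogenetic contraction (CT) behavior quantification.

The pipeline mirrors a high-throughput larval cold-plate workflow: individual
larvae are found in the full-arena video by automatic Triangle thresholding,
each is cropped into its own 250 x 250 px clip, background is removed per
frame with Li thresholding, and the projected silhouette area is measured per
frame.  Percent change in area from the pre-stimulus reference then yields
the three contraction metrics per animal:

* **responded** — at least a 10% reduction in surface area sustained for at
  least 0.5 s within the analysis window (5 s of stimulus by default);
* **CT duration** — the total time spent below the -10% line in the window;
* **CT magnitude** — the mean percent change in area over the window.

Cohorts are summarized as %CT (fraction of responders) plus the per-animal
metric distributions that feed :mod:`coldtrace.stats`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from skimage import measure

from .errors import (DegenerateTraceError, EmptyCohortError, ParameterError)
from .synthgen import AreaTrace
from .thresholds import auto_threshold

logger = logging.getLogger(__name__)

CROP_SIZE = 250           # px, side of a single-larva clip
CT_THRESHOLD = -10.0      # percent change defining a contraction
CT_MIN_DURATION = 0.5     # s a run must last to count as a response
COLD_WINDOW = 5.0         # s of stimulus analyzed for the cold-plate assay
MIN_ELONGATION = 2.0      # major/minor axis ratio required at onset

# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------


@dataclass
class LarvaClip:
    """A single larva cropped from the arena video, with per-frame masks."""

    animal_id: str
    frames: np.ndarray          # (T, crop, crop) grayscale
    masks: np.ndarray           # (T, crop, crop) boolean foreground
    frame_rate: float
    center: tuple[float, float] = (0.0, 0.0)   # centroid in arena coords
    clipped_at_edge: bool = False

    def __post_init__(self) -> None:
        if self.frames.shape != self.masks.shape:
            raise ParameterError("frames and masks must share a shape")

    def elongation(self, frame_index: int = 0) -> float:
        """Major/minor axis ratio of the mask in one frame (inf if linear)."""
        props = measure.regionprops(self.masks[frame_index].astype(np.uint8))
        if not props:
            return 0.0
        p = max(props, key=lambda q: q.area)
        if p.axis_minor_length == 0:
            return np.inf
        return p.axis_major_length / p.axis_minor_length


@dataclass
class PercentTrace:
    """Percent change in silhouette area from the pre-stimulus reference."""

    times: np.ndarray
    values: np.ndarray          # percent
    reference_area: float
    onset: float
    frame_rate: float
    animal_id: str = "animal0"

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values)):
            raise DegenerateTraceError("percent trace contains non-finite values")


@dataclass
class CTMetrics:
    """Per-animal contraction metrics."""

    animal_id: str
    responded: bool
    duration: float             # s below threshold within the window
    magnitude: float            # mean percent change over the window
    excluded: bool = False      # e.g. not elongated at onset

    def __post_init__(self) -> None:
        if self.duration < 0:
            raise ParameterError("duration must be non-negative")


@dataclass
class BehaviorSummary:
    """Cohort-level roll-up of contraction metrics."""

    label: str
    n_analyzed: int
    n_responders: int
    pct_ct: float
    metrics: list[CTMetrics] = field(default_factory=list)

    @property
    def durations(self) -> np.ndarray:
        return np.array([m.duration for m in self.metrics])

    @property
    def magnitudes(self) -> np.ndarray:
        return np.array([m.magnitude for m in self.metrics])


# --------------------------------------------------------------------------
# Segmentation
# --------------------------------------------------------------------------


def binarize_frame(frame: np.ndarray, method: str = "triangle"):
    """Threshold one frame automatically; returns ``(mask, threshold)``.

    ``method`` is ``'triangle'`` (arena-level larva detection) or ``'li'``
    (within-crop background removal).  Pixels strictly above the threshold
    are foreground.
    """
    frame = np.asarray(frame)
    thr = auto_threshold(frame, method)
    return frame > thr, thr


def segment_larvae(
    stack: np.ndarray,
    method: str = "triangle",
    min_area: float = 100.0,
    crop_size: int = CROP_SIZE,
    frame_rate: float = 30.0,
    reference_frame: int = 0,
) -> list[LarvaClip]:
    """Find individual larvae and crop each into its own clip.

    Larvae are connected foreground components of the automatically
    thresholded reference frame that pass the ``min_area`` filter.  Each gets
    a ``crop_size`` x ``crop_size`` crop centered on its centroid (clipped
    and flagged at arena edges).  Inside each crop, background is removed per
    frame with Li thresholding and only the connected component nearest the
    crop center is kept, so overlapping crops never share mask pixels with a
    neighboring animal.
    """
    stack = np.asarray(stack)
    if stack.ndim != 3 or stack.shape[0] == 0:
        raise ParameterError("stack must be a non-empty (T, H, W) array")
    ref_mask, _ = binarize_frame(stack[reference_frame], method)
    labels = measure.label(ref_mask)
    props = [p for p in measure.regionprops(labels) if p.area >= min_area]
    if not props:
        logger.warning("no component passed the %.0f px^2 area filter", min_area)
        return []

    n_frames, h, w = stack.shape
    half = crop_size // 2
    clips = []
    for i, p in enumerate(sorted(props, key=lambda q: q.centroid)):
        cy, cx = p.centroid
        r0, c0 = int(round(cy)) - half, int(round(cx)) - half
        r0c, c0c = max(r0, 0), max(c0, 0)
        r1c, c1c = min(r0 + crop_size, h), min(c0 + crop_size, w)
        clipped = (r0c, c0c, r1c, c1c) != (r0, c0, r0 + crop_size, c0 + crop_size)
        frames = stack[:, r0c:r1c, c0c:c1c].astype(float)
        masks = np.zeros_like(frames, dtype=bool)
        cc = (cy - r0c, cx - c0c)  # larva centroid in crop coordinates
        for f in range(n_frames):
            try:
                m, _ = binarize_frame(frames[f], "li")
            except Exception:
                continue  # constant frame -> empty mask, flagged downstream
            masks[f] = _nearest_component(m, cc)
        clips.append(LarvaClip(animal_id=f"larva{i}", frames=frames,
                               masks=masks, frame_rate=frame_rate,
                               center=(float(cy), float(cx)),
                               clipped_at_edge=clipped))
    return clips


def _nearest_component(mask: np.ndarray, point: tuple[float, float]) -> np.ndarray:
    """Keep only the connected component whose centroid is nearest ``point``."""
    lab = measure.label(mask)
    props = measure.regionprops(lab)
    if not props:
        return np.zeros_like(mask, dtype=bool)
    best = min(props, key=lambda p: (p.centroid[0] - point[0]) ** 2
               + (p.centroid[1] - point[1]) ** 2)
    return lab == best.label


def area_series(clip: LarvaClip, onset: float = 0.0) -> AreaTrace:
    """Foreground pixel count per frame; empty-mask frames give 0, flagged."""
    areas = clip.masks.reshape(clip.masks.shape[0], -1).sum(axis=1).astype(float)
    flags = areas == 0
    if flags.any():
        logger.warning("%s: %d empty-mask frame(s) recorded as area 0",
                       clip.animal_id, int(flags.sum()))
    return AreaTrace(frame_rate=clip.frame_rate, areas=areas, onset=onset,
                     animal_id=clip.animal_id, flags=flags)


# --------------------------------------------------------------------------
# Contraction metrics
# --------------------------------------------------------------------------


def percent_change_trace(
    trace: AreaTrace,
    reference: str = "mean_pre_onset_window",
    window: float = 0.5,
) -> PercentTrace:
    """Percent change in area from the animal's pre-stimulus "initial area".

    The reference is either the mean area over the ``window`` seconds
    immediately preceding stimulus onset (default; robust to single-frame
    noise) or the single frame at onset (``reference='frame_at_onset'``).
    """
    t = trace.times
    if not (t[0] <= trace.onset <= t[-1]):
        raise ParameterError("stimulus onset must lie within the trace")
    onset_idx = int(np.searchsorted(t, trace.onset))
    if reference == "frame_at_onset":
        ref = float(trace.areas[min(onset_idx, t.size - 1)])
    elif reference == "mean_pre_onset_window":
        lo = max(0, onset_idx - int(round(window * trace.frame_rate)))
        sel = trace.areas[lo:max(onset_idx, lo + 1)]
        ref = float(sel.mean()) if sel.size else float(trace.areas[0])
    else:
        raise ParameterError(f"unknown reference {reference!r}")
    if ref <= 0:
        raise DegenerateTraceError("reference area must be positive")
    values = 100.0 * (trace.areas - ref) / ref
    return PercentTrace(times=t, values=values, reference_area=ref,
                        onset=trace.onset, frame_rate=trace.frame_rate,
                        animal_id=trace.animal_id)


def ct_metrics(
    ptrace: PercentTrace,
    threshold: float = CT_THRESHOLD,
    min_duration: float = CT_MIN_DURATION,
    window: float = COLD_WINDOW,
) -> CTMetrics:
    """Contraction metrics over the analysis window starting at onset.

    ``responded`` requires a contiguous run of samples at or below
    ``threshold`` lasting at least ``min_duration``; ``duration`` counts all
    sub-threshold time in the window (not only the qualifying run);
    ``magnitude`` is the mean percent change over the whole window.  Samples
    exactly at the threshold count as sub-threshold.
    """
    t = ptrace.times
    start, end = ptrace.onset, ptrace.onset + window
    if end > t[-1] + 1.0 / ptrace.frame_rate + 1e-9:
        raise ParameterError("analysis window extends past the trace")
    sel = (t >= start - 1e-9) & (t < end - 1e-9)
    v = ptrace.values[sel]
    if v.size == 0:
        raise ParameterError("analysis window contains no samples")
    dt = 1.0 / ptrace.frame_rate
    below = v <= threshold
    duration = float(below.sum()) * dt
    responded = False
    run = 0
    for b in below:
        run = run + 1 if b else 0
        if run * dt >= min_duration - 1e-9:
            responded = True
            break
    magnitude = float(v.mean())
    return CTMetrics(animal_id=ptrace.animal_id, responded=responded,
                     duration=duration, magnitude=magnitude)


def summarize_behavior(metrics: list[CTMetrics], label: str = "") -> BehaviorSummary:
    """Cohort summary: %CT and metric distributions over analyzed animals.

    Animals flagged ``excluded`` (e.g. not elongated at stimulus onset) are
    dropped before counting.
    """
    if not metrics:
        raise EmptyCohortError("no metrics to summarize")
    kept = [m for m in metrics if not m.excluded]
    if not kept:
        raise EmptyCohortError("all animals were excluded")
    n_resp = sum(m.responded for m in kept)
    return BehaviorSummary(label=label, n_analyzed=len(kept),
                           n_responders=n_resp,
                           pct_ct=100.0 * n_resp / len(kept), metrics=kept)


# --------------------------------------------------------------------------
# Video -> metrics convenience path
# --------------------------------------------------------------------------


def analyze_video(
    stack: np.ndarray,
    onset: float,
    frame_rate: float = 30.0,
    window: float = COLD_WINDOW,
    min_area: float = 100.0,
    min_elongation: float = MIN_ELONGATION,
    label: str = "",
) -> BehaviorSummary:
    """Run the full video path: segment, measure area, compute CT metrics.

    Animals whose onset-frame silhouette is not elongated (major/minor axis
    ratio below ``min_elongation``) are excluded from the summary, mirroring
    the manual analyzability criterion of plate assays.
    """
    clips = segment_larvae(stack, min_area=min_area, frame_rate=frame_rate)
    metrics = []
    onset_frame = int(round(onset * frame_rate))
    for clip in clips:
        trace = area_series(clip, onset=onset)
        m = ct_metrics(percent_change_trace(trace), window=window)
        if clip.elongation(min(onset_frame, len(clip.frames) - 1)) < min_elongation:
            m.excluded = True
        metrics.append(m)
    return summarize_behavior(metrics, label=label)
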