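"""Calcium-imaging quantification: GCaMP dF/F traces and CaMPARI ratiometry.

GCaMP activity is reported as the percent change in area-normalized
fluorescence from a pre-stimulus baseline window,

    dF/F_baseline = (F_n - F_baseline) / F_baseline * 100,

with the cohort statistic being the peak dF/F over the stimulus window.

CaMPARI photoconversion is reported as the F_red/F_green ratio, either over a
detected soma ROI (Moments thresholding of the green channel, morphological
opening to strip thin branches, particle analysis to draw the ROI) or as a
radial intensity profile: five-pixel-wide annular ROIs stepped at one-pixel
intervals away from the cell-body center, restricted to the neuron's own
foreground mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure, morphology

from .errors import DegenerateTraceError, ParameterError
from .synthgen import TwoChannelImage
from .thresholds import auto_threshold

ANNULUS_WIDTH = 5   # px, width of each radial ROI
ANNULUS_STEP = 1    # px, spacing between consecutive radii

# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------


@dataclass
class FluorescenceTrace:
    """Area-normalized fluorescence vs time with a baseline window."""

    times: np.ndarray
    F: np.ndarray
    baseline_window: tuple[float, float]
    onset: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.F = np.asarray(self.F, dtype=float)
        if self.times.shape != self.F.shape:
            raise ParameterError("times and F must have the same length")
        if not np.all(np.isfinite(self.F)):
            raise ParameterError("fluorescence must be finite")
        lo, hi = self.baseline_window
        if not (lo < hi <= self.onset):
            raise ParameterError("baseline window must be non-empty and "
                                 "precede stimulus onset")


@dataclass
class DFFTrace:
    """Percent change in fluorescence from the baseline-window mean."""

    times: np.ndarray
    values: np.ndarray        # percent
    baseline_F: float
    peak: float               # max over the stimulus window, percent


@dataclass
class SomaROI:
    """A connected cell-body region."""

    pixels: np.ndarray        # (N, 2) array of (row, col) indices
    centroid: tuple[float, float]
    area: int

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        m[self.pixels[:, 0], self.pixels[:, 1]] = True
        return m


@dataclass
class RadialIntensityProfile:
    """Per-radius channel sums, annulus areas, and red/green ratios.

    ``ratio`` is NaN at radii whose annulus has no foreground pixels or zero
    green signal.
    """

    radii: np.ndarray
    red_sum: np.ndarray
    green_sum: np.ndarray
    area: np.ndarray
    ratio: np.ndarray


# --------------------------------------------------------------------------
# GCaMP dF/F
# --------------------------------------------------------------------------


def dff(trace: FluorescenceTrace,
        peak_window: tuple[float, float] | None = None) -> DFFTrace:
    """Percent change from the baseline-window mean; peak over the stimulus.

    ``peak_window`` defaults to stimulus onset through the end of the trace.
    """
    lo, hi = trace.baseline_window
    base_sel = (trace.times >= lo) & (trace.times <= hi)
    if not base_sel.any():
        raise ParameterError("baseline window contains no samples")
    baseline = float(trace.F[base_sel].mean())
    if baseline <= 0:
        raise DegenerateTraceError("baseline mean must be positive")
    values = 100.0 * (trace.F - baseline) / baseline
    if peak_window is None:
        peak_window = (trace.onset, float(trace.times[-1]))
    p0, p1 = peak_window
    peak_sel = (trace.times >= p0) & (trace.times <= p1)
    peak = float(values[peak_sel].max()) if peak_sel.any() else float("nan")
    return DFFTrace(times=trace.times, values=values, baseline_F=baseline,
                    peak=peak)


# --------------------------------------------------------------------------
# CaMPARI soma analysis
# --------------------------------------------------------------------------


def detect_somata(
    green: np.ndarray,
    threshold_method: str = "moments",
    opening_radius: int = 2,
    area_range: tuple[float, float] = (20.0, 10_000.0),
) -> list[SomaROI]:
    """Detect cell bodies on the green channel.

    The channel is thresholded (Moments method by default), thin branches
    and background specks are removed by a morphological opening (erode then
    dilate with a disk of ``opening_radius``), and each remaining connected
    component inside ``area_range`` becomes a :class:`SomaROI`.
    """
    green = np.asarray(green, dtype=float)
    thr = auto_threshold(green, threshold_method)
    binary = green > thr
    if opening_radius > 0:
        binary = morphology.opening(binary, morphology.disk(opening_radius))
    lo, hi = area_range
    rois = []
    for p in measure.regionprops(measure.label(binary)):
        if lo <= p.area <= hi:
            rois.append(SomaROI(pixels=p.coords,
                                centroid=tuple(map(float, p.centroid)),
                                area=int(p.area)))
    return rois


def campari_ratio(image: TwoChannelImage, roi: SomaROI) -> float:
    """Photoconversion ratio over an ROI: (red sum) / (green sum).

    Because the two channels share the ROI area, the ratio of area-normalized
    means equals the ratio of the raw sums.
    """
    rr, cc = roi.pixels[:, 0], roi.pixels[:, 1]
    green_sum = float(image.green[rr, cc].sum())
    if green_sum <= 0:
        raise DegenerateTraceError("zero green signal over the ROI")
    return float(image.red[rr, cc].sum()) / green_sum


def soma_center(image: TwoChannelImage, roi: SomaROI,
                weighted: bool = True) -> tuple[float, float]:
    """Profile center: intensity-weighted (default) or geometric centroid."""
    if not weighted:
        return roi.centroid
    rr, cc = roi.pixels[:, 0], roi.pixels[:, 1]
    wts = image.green[rr, cc]
    if wts.sum() <= 0:
        return roi.centroid
    return (float((rr * wts).sum() / wts.sum()),
            float((cc * wts).sum() / wts.sum()))


# --------------------------------------------------------------------------
# Radial ("Sholl-style") intensity profile
# --------------------------------------------------------------------------


def radial_intensity_profile(
    image: TwoChannelImage,
    mask: np.ndarray,
    center: tuple[float, float],
    annulus_width: int = ANNULUS_WIDTH,
    step: int = ANNULUS_STEP,
    max_radius: float | None = None,
    pixel_mean: bool = False,
) -> RadialIntensityProfile:
    """Red/green intensity in annular ROIs stepped away from the soma center.

    For each radius r = 0, step, 2*step, ... the annulus is the set of
    foreground pixels whose Euclidean center-to-center distance from
    ``center`` lies in the closed interval [r - w/2, r + w/2] with
    w = ``annulus_width`` (consecutive annuli overlap when step < width).
    Records summed red, summed green, annulus foreground area, and the ratio
    (sum red)/(sum green) — or the mean of per-pixel ratios when
    ``pixel_mean`` is set.  Radii with empty annuli or zero green give NaN.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != image.green.shape:
        raise ParameterError("mask shape must match the image")
    cy, cx = center
    h, w = mask.shape
    if not (0 <= cy < h and 0 <= cx < w):
        raise ParameterError("center must lie inside the image")
    yy, xx = np.mgrid[0:h, 0:w]
    dist = np.hypot(yy - cy, xx - cx)
    if max_radius is None:
        max_radius = float(dist[mask].max()) if mask.any() else 0.0
    half = annulus_width / 2.0
    radii = np.arange(0.0, max_radius + step, step)
    red_s = np.zeros(radii.size)
    green_s = np.zeros(radii.size)
    area = np.zeros(radii.size, dtype=int)
    ratio = np.full(radii.size, np.nan)
    for i, r in enumerate(radii):
        ann = mask & (dist >= r - half) & (dist <= r + half)
        area[i] = int(ann.sum())
        if area[i] == 0:
            continue
        red_s[i] = float(image.red[ann].sum())
        green_s[i] = float(image.green[ann].sum())
        if pixel_mean:
            g = image.green[ann]
            ok = g > 0
            if ok.any():
                ratio[i] = float((image.red[ann][ok] / g[ok]).mean())
        elif green_s[i] > 0:
            ratio[i] = red_s[i] / green_s[i]
    return RadialIntensityProfile(radii=radii, red_sum=red_s,
                                  green_sum=green_s, area=area, ratio=ratio)


def sholl_intersections(
    mask: np.ndarray,
    center: tuple[float, float],
    step: float = 1.0,
    max_radius: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Classic Sholl profile: branch crossings per sampling circle.

    Walks each circle of radius r = step, 2*step, ... around ``center`` and
    counts the connected runs of foreground pixels it crosses (cyclic runs
    are merged).  Returns ``(radii, counts)``; an empty mask gives all-zero
    counts over an empty radius grid.
    """
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    cy, cx = center
    if not (0 <= cy < h and 0 <= cx < w):
        raise ParameterError("center must lie inside the image")
    if not mask.any():
        return np.array([]), np.array([], dtype=int)
    if max_radius is None:
        yy, xx = np.nonzero(mask)
        max_radius = float(np.hypot(yy - cy, xx - cx).max())
    radii = np.arange(step, max_radius + step, step)
    counts = np.zeros(radii.size, dtype=int)
    for i, r in enumerate(radii):
        counts[i] = _circle_run_count(mask, cy, cx, r)
    return radii, counts


def _circle_run_count(mask: np.ndarray, cy: float, cx: float, r: float) -> int:
    """Count cyclic runs of foreground pixels along one sampling circle."""
    h, w = mask.shape
    n = max(16, int(np.ceil(2 * np.pi * r * 4)))  # 4 samples per pixel arc
    theta = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
    rr = np.clip(np.round(cy + r * np.sin(theta)).astype(int), 0, h - 1)
    cc = np.clip(np.round(cx + r * np.cos(theta)).astype(int), 0, w - 1)
    inside = (cy + r * np.sin(theta) >= -0.5) & (cy + r * np.sin(theta) < h - 0.5) \
        & (cx + r * np.cos(theta) >= -0.5) & (cx + r * np.cos(theta) < w - 0.5)
    vals = mask[rr, cc] & inside
    # collapse consecutive duplicate pixels so runs are counted in pixel space
    keep = np.ones(n, dtype=bool)
    keep[1:] = (rr[1:] != rr[:-1]) | (cc[1:] != cc[:-1])
    vals = vals[keep]
    if vals.size == 0 or not vals.any():
        return 0
    if vals.all():
        return 1
    transitions = int(np.sum(vals & ~np.roll(vals, 1)))  # cyclic rising edges
    return transitions
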