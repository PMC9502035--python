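"""Automatic histogram thresholding: Triangle, Li (minimum cross-entropy),
and Tsai's moment-preserving method.

All three operate on a 256-bin intensity histogram, matching the behavior of
the classic ImageJ auto-threshold implementations.  Each selector computes
its published criterion at every candidate threshold (or, for Moments, the
closed-form moment-preserving fraction) so the chosen bin is exactly the
criterion's optimum — verifiable against a brute-force search.
"""

from __future__ import annotations

import numpy as np

from .errors import DegenerateImageError

N_BINS = 256


def image_histogram(image: np.ndarray, n_bins: int = N_BINS):
    """256-bin histogram of an image plus the bin centers.

    Unsigned 8-bit images use the exact 0..255 grid; other dtypes are binned
    uniformly over [min, max].
    """
    image = np.asarray(image)
    if image.min() == image.max():
        raise DegenerateImageError("constant image has no threshold")
    if image.dtype == np.uint8 and n_bins == 256:
        hist = np.bincount(image.ravel(), minlength=256).astype(float)
        centers = np.arange(256, dtype=float)
    else:
        hist, edges = np.histogram(image.ravel(), bins=n_bins)
        hist = hist.astype(float)
        centers = (edges[:-1] + edges[1:]) / 2.0
    return hist, centers


def triangle_threshold(hist: np.ndarray, centers: np.ndarray) -> float:
    """Triangle method: the bin maximizing the perpendicular distance from
    the histogram to the chord joining the peak and the far tail end.

    The chord runs from the histogram peak (at its height) to the last
    non-empty bin on the side of the longer tail (at its height); the
    maximizer of the point-to-chord distance is invariant to independent
    axis scaling, so no normalization is needed.  Returns the threshold bin
    *value*; pixels strictly above it are foreground when the bright tail is
    the longer one.
    """
    hist = np.asarray(hist, dtype=float)
    nz = np.flatnonzero(hist)
    if nz.size < 2:
        raise DegenerateImageError("histogram has fewer than two occupied bins")
    first, last = int(nz[0]), int(nz[-1])
    peak = int(np.argmax(hist))
    end = last if (last - peak) >= (peak - first) else first
    if end == peak:
        return float(centers[peak])
    t = np.arange(min(peak, end), max(peak, end) + 1)
    # |cross product| of (end - peak) x (t - peak): distance to the chord
    # up to the constant chord length
    cross = np.abs((end - peak) * (hist[t] - hist[peak])
                   - (t - peak) * (hist[end] - hist[peak]))
    best = int(t[np.argmax(cross)])
    return float(centers[best])


def li_threshold(hist: np.ndarray, centers: np.ndarray) -> float:
    """Li's minimum cross-entropy threshold, by exhaustive criterion search.

    For each candidate cut t the criterion is
    ``-(sum_low g*h) * log(mean_low) - (sum_high g*h) * log(mean_high)``
    over the two classes the cut induces; the returned bin value minimizes
    it.  Pixels strictly above the value are foreground.
    """
    hist = np.asarray(hist, dtype=float)
    g = np.asarray(centers, dtype=float)
    if g[0] <= 0:
        g = g - g[0] + 1.0  # criterion needs positive gray levels
    w = np.cumsum(hist)
    m = np.cumsum(hist * g)
    w_tot, m_tot = w[-1], m[-1]
    if w_tot == 0:
        raise DegenerateImageError("empty histogram")
    # candidate cut after bin t: low = bins [0..t], high = bins (t..]
    w_lo, m_lo = w[:-1], m[:-1]
    w_hi, m_hi = w_tot - w_lo, m_tot - m_lo
    valid = (w_lo > 0) & (w_hi > 0)
    crit = np.full(hist.size - 1, np.inf)
    mu_lo = np.where(valid, m_lo / np.where(w_lo > 0, w_lo, 1), 1.0)
    mu_hi = np.where(valid, m_hi / np.where(w_hi > 0, w_hi, 1), 1.0)
    crit[valid] = (-m_lo * np.log(mu_lo) - m_hi * np.log(mu_hi))[valid]
    if not np.any(np.isfinite(crit)):
        raise DegenerateImageError("histogram has a single occupied bin")
    # exact ties (e.g. a run of empty bins between modes) keep the last cut,
    # so the threshold sits against the bright mode rather than the dark one
    best = int(np.flatnonzero(crit == crit.min()).max())
    return float(centers[best])


def moments_threshold(hist: np.ndarray, centers: np.ndarray) -> float:
    """Tsai's moment-preserving threshold.

    Solves for the background fraction ``p0`` such that a two-level image
    preserves the first three gray-level moments of the input, then returns
    the bin value whose cumulative histogram fraction is closest to ``p0``.
    """
    hist = np.asarray(hist, dtype=float)
    g = np.asarray(centers, dtype=float)
    total = hist.sum()
    if total == 0:
        raise DegenerateImageError("empty histogram")
    p = hist / total
    m1 = float(np.sum(p * g))
    m2 = float(np.sum(p * g ** 2))
    m3 = float(np.sum(p * g ** 3))
    cd = m2 - m1 * m1
    if cd <= 0:
        raise DegenerateImageError("degenerate histogram (zero variance)")
    c0 = (-m2 * m2 + m1 * m3) / cd
    c1 = (-m3 + m2 * m1) / cd
    disc = c1 * c1 - 4.0 * c0
    if disc < 0:
        raise DegenerateImageError("moment equations have no real solution")
    z0 = 0.5 * (-c1 - np.sqrt(disc))
    z1 = 0.5 * (-c1 + np.sqrt(disc))
    if z1 == z0:
        raise DegenerateImageError("moment-preserving levels coincide")
    p0 = (z1 - m1) / (z1 - z0)
    cdf = np.cumsum(p)
    best = int(np.argmin(np.abs(cdf - p0)))
    return float(centers[best])


_METHODS = {
    "triangle": triangle_threshold,
    "li": li_threshold,
    "moments": moments_threshold,
}


def auto_threshold(image: np.ndarray, method: str = "triangle") -> float:
    """Select a threshold for ``image`` with the named histogram method."""
    try:
        fn = _METHODS[method]
    except KeyError:
        raise ValueError(f"unknown threshold method {method!r}") from None
    hist, centers = image_histogram(image)
    return fn(hist, centers)
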