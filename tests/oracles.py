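"""Independent brute-force oracles used to validate the implementation.

Each oracle is written directly from the defining rule of the quantity it
checks — plain Python loops, exact arithmetic where possible — and shares no
code with the package.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np


# ------------------------------------------------------------------ bursts

def burst_labels_oracle(times, isi_max=0.15, min_count=3):
    """Mark every spike contained in ANY contiguous subsequence of
    >= min_count spikes whose every consecutive ISI is < isi_max."""
    times = list(times)
    n = len(times)
    burst = [False] * n
    for i in range(n):
        j = i
        while j + 1 < n and times[j + 1] - times[j] < isi_max:
            j += 1
        # i..j is the longest qualifying stretch starting at i
        if j - i + 1 >= min_count:
            for k in range(i, j + 1):
                burst[k] = True
    return ["burst" if b else "tonic" for b in burst]


# ------------------------------------------------------------- radial profile

def radial_profile_oracle(red, green, mask, center, width=5, step=1,
                          max_radius=None):
    """Per-pixel distance binning: accumulate sums for every annulus the
    pixel's center-to-center distance falls into (closed [r-w/2, r+w/2])."""
    h, w_img = mask.shape
    cy, cx = center
    dists, pix = [], []
    for y in range(h):
        for x in range(w_img):
            if mask[y, x]:
                dists.append(((y - cy) ** 2 + (x - cx) ** 2) ** 0.5)
                pix.append((y, x))
    if max_radius is None:
        max_radius = max(dists) if dists else 0.0
    radii = []
    r = 0.0
    while r <= max_radius + step - 1e-12:
        radii.append(r)
        r += step
    half = width / 2.0
    red_s = [0.0] * len(radii)
    green_s = [0.0] * len(radii)
    area = [0] * len(radii)
    for d, (y, x) in zip(dists, pix):
        for i, r in enumerate(radii):
            if r - half <= d <= r + half:
                area[i] += 1
                red_s[i] += red[y, x]
                green_s[i] += green[y, x]
    ratio = [rs / gs if (a > 0 and gs > 0) else float("nan")
             for rs, gs, a in zip(red_s, green_s, area)]
    return (np.array(radii), np.array(red_s), np.array(green_s),
            np.array(area), np.array(ratio))


# ------------------------------------------------------------- thresholds

def triangle_oracle(hist, centers):
    """Exhaustive search: bin between peak and far tail end maximizing the
    point-to-chord distance (chord joins peak and far end at their heights)."""
    hist = list(map(float, hist))
    nz = [i for i, v in enumerate(hist) if v > 0]
    first, last = nz[0], nz[-1]
    peak = max(range(len(hist)), key=lambda i: (hist[i], -i))
    end = last if (last - peak) >= (peak - first) else first
    if end == peak:
        return float(centers[peak])
    lo, hi = min(peak, end), max(peak, end)
    best_t, best_d = None, -1.0
    chord_len = ((end - peak) ** 2 + (hist[end] - hist[peak]) ** 2) ** 0.5
    for t in range(lo, hi + 1):
        cross = abs((end - peak) * (hist[t] - hist[peak])
                    - (t - peak) * (hist[end] - hist[peak]))
        d = cross / chord_len
        if d > best_d:
            best_d, best_t = d, t
    return float(centers[best_t])


def li_oracle(hist, centers):
    """Exhaustive search of the minimum-cross-entropy criterion."""
    g = [float(c) for c in centers]
    if g[0] <= 0:
        shift = -g[0] + 1.0
        g = [v + shift for v in g]
    best_t, best_c = None, float("inf")
    for t in range(len(hist) - 1):
        w_lo = sum(hist[:t + 1])
        w_hi = sum(hist[t + 1:])
        if w_lo == 0 or w_hi == 0:
            continue
        m_lo = sum(h * gv for h, gv in zip(hist[:t + 1], g[:t + 1]))
        m_hi = sum(h * gv for h, gv in zip(hist[t + 1:], g[t + 1:]))
        crit = -m_lo * np.log(m_lo / w_lo) - m_hi * np.log(m_hi / w_hi)
        if crit <= best_c:       # ties keep the last cut, as implemented
            best_c, best_t = crit, t
    return float(centers[best_t])


def moments_oracle(hist, centers):
    """Tsai's moment-preserving fraction via numpy root finding, then an
    exhaustive search for the bin whose CDF is closest to it."""
    hist = np.asarray(hist, dtype=float)
    g = np.asarray(centers, dtype=float)
    p = hist / hist.sum()
    m1, m2, m3 = (np.sum(p * g ** k) for k in (1, 2, 3))
    cd = m2 - m1 ** 2
    c0 = (m1 * m3 - m2 ** 2) / cd
    c1 = (m1 * m2 - m3) / cd
    z0, z1 = np.sort(np.roots([1.0, c1, c0]).real)
    p0 = (z1 - m1) / (z1 - z0)
    cdf = 0.0
    best_t, best_d = None, float("inf")
    for t in range(len(hist)):
        cdf += p[t]
        d = abs(cdf - p0)
        if d < best_d:
            best_d, best_t = d, t
    return float(centers[best_t])


# ------------------------------------------------------------- statistics

def fisher_two_sided_oracle(table):
    """Exact-arithmetic hypergeometric enumeration of the two-sided p."""
    (a, b), (c, d) = table
    n = a + b + c + d
    row1, col1 = a + b, a + c
    denom = comb(n, col1)
    support = range(max(0, col1 - (n - row1)), min(col1, row1) + 1)
    probs = {k: Fraction(comb(row1, k) * comb(n - row1, col1 - k), denom)
             for k in support}
    p_obs = probs[a]
    return float(sum(p for p in probs.values() if p <= p_obs))


def bh_oracle(pvals, alpha):
    """Literal step-up rule: reject the k smallest with
    p_(k) <= k * alpha / m, k maximal; adjusted by the min-over-larger-rank
    definition computed with plain loops."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    k_star = 0
    for rank, i in enumerate(order, start=1):
        if pvals[i] <= rank * alpha / m:
            k_star = rank
    reject = [False] * m
    for rank, i in enumerate(order, start=1):
        if rank <= k_star:
            reject[i] = True
    adjusted = [0.0] * m
    for rank, i in enumerate(order, start=1):
        vals = [m * pvals[order[j]] / (j + 1) for j in range(rank - 1, m)]
        adjusted[i] = min(1.0, min(vals))
    return adjusted, reject


def holm_sidak_oracle(pvals):
    """Step-down Sidak adjustment with plain loops."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adjusted = [0.0] * m
    prev = 0.0
    for rank, i in enumerate(order, start=1):
        val = 1.0 - (1.0 - pvals[i]) ** (m - rank + 1)
        prev = max(prev, val)
        adjusted[i] = min(1.0, prev)
    return adjusted


def bky_reject_oracle(pvals, alpha):
    """Literal two-stage procedure: BH step-up at alpha/(1+alpha), estimate
    m0 = m - r1, then BH step-up at (alpha/(1+alpha)) * m / m0."""
    def step_up_count(ps, level):
        m = len(ps)
        s = sorted(ps)
        k_star = 0
        for k in range(1, m + 1):
            if s[k - 1] <= k * level / m:
                k_star = k
        return k_star

    m = len(pvals)
    q1 = alpha / (1.0 + alpha)
    r1 = step_up_count(pvals, q1)
    if r1 == 0:
        return [False] * m
    m0 = m - r1
    if m0 == 0:
        return [True] * m
    r2 = step_up_count(pvals, q1 * m / m0)
    cutoff = sorted(pvals)[r2 - 1] if r2 > 0 else -1.0
    return [p <= cutoff and r2 > 0 for p in pvals]
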