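"""Synthetic-data generators with stored ground truth.

Every input the quantification pipeline consumes — temperature ramps, larval
silhouette area traces, raw video frames, cold-evoked spike trains, two-channel
(green/red) neuron images, and gentle-touch behavior cohorts — can be generated
here with known ground truth, so each downstream stage is testable without any
external recordings.

All randomness flows through one ``numpy.random.Generator`` seeded per call;
no global random state is touched.  Identical seeds give bit-identical output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .errors import ParameterError

# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class TemperatureProfile:
    """A sampled temperature trajectory T(t) on a uniform time grid.

    Attributes
    ----------
    times : array of float
        Sample times in seconds, uniform grid starting at 0.
    temperature : array of float
        Temperature in degrees Celsius at each sample.
    onset : float
        Stimulus onset (end of the pre-stimulus baseline), seconds.
    target : float
        Stimulus target temperature, degrees Celsius.
    """

    times: np.ndarray
    temperature: np.ndarray
    onset: float
    target: float

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        temp = np.asarray(self.temperature, dtype=float)
        if t.ndim != 1 or t.size < 2:
            raise ParameterError("need at least two time samples")
        dt = np.diff(t)
        if not (np.all(dt > 0) and np.allclose(dt, dt[0], rtol=1e-9, atol=1e-12)):
            raise ParameterError("times must be strictly increasing and uniform")
        if temp.shape != t.shape or not np.all(np.isfinite(temp)):
            raise ParameterError("temperature must be finite, one value per time")
        if not (t[0] <= self.onset <= t[-1]):
            raise ParameterError("onset must lie within the time range")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "temperature", temp)

    @property
    def sample_rate(self) -> float:
        return 1.0 / (self.times[1] - self.times[0])

    def cooling_rate(self) -> np.ndarray:
        """Instantaneous cooling rate max(0, -dT/dt) in degC/s, per sample."""
        g = -np.gradient(self.temperature, self.times)
        return np.clip(g, 0.0, None)


@dataclass
class AreaTrace:
    """Per-frame larval silhouette area versus time.

    ``ground_truth`` (set by the generators) stores the noiseless parameters
    used to build the trace: responder flag, contraction magnitude (fraction),
    contraction duration (s), and the noiseless area series.
    """

    frame_rate: float
    areas: np.ndarray
    onset: float
    animal_id: str = "animal0"
    flags: np.ndarray | None = None  # per-frame problem flags (e.g. empty mask)
    ground_truth: dict | None = None

    def __post_init__(self) -> None:
        self.areas = np.asarray(self.areas, dtype=float)
        if self.frame_rate <= 0:
            raise ParameterError("frame_rate must be positive")
        if np.any(self.areas < 0):
            raise ParameterError("areas must be non-negative")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.areas.size) / self.frame_rate


@dataclass
class SpikeTrain:
    """Sorted spike times within a recording window.

    ``labels`` is the generator's ground truth ('burst' or 'tonic' per spike)
    when known; the classifier in :mod:`coldtrace.ephys` never reads it.
    """

    times: np.ndarray
    window: tuple[float, float]
    labels: np.ndarray | None = None
    profile: TemperatureProfile | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if t.size and not np.all(np.diff(t) > 0):
            raise ParameterError("spike times must be strictly increasing")
        lo, hi = self.window
        if t.size and (t[0] < lo or t[-1] > hi):
            raise ParameterError("spike times must lie within the window")
        if self.labels is not None:
            lab = np.asarray(self.labels)
            if lab.shape != t.shape:
                raise ParameterError("one label per spike required")
            self.labels = lab
        self.times = t

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass
class TwoChannelImage:
    """Registered green and red intensity grids (photoconversion source data).

    Ground-truth attributes are populated by the generator: ``mask`` is the
    true foreground (soma + dendrites), ``soma_centers`` the (row, col) soma
    centers, and ``rho`` the true per-pixel red/green ratio field.
    """

    green: np.ndarray
    red: np.ndarray
    mask: np.ndarray | None = None
    soma_centers: list[tuple[float, float]] | None = None
    rho: np.ndarray | None = None

    def __post_init__(self) -> None:
        g = np.asarray(self.green, dtype=float)
        r = np.asarray(self.red, dtype=float)
        if g.shape != r.shape or g.ndim != 2:
            raise ParameterError("green and red must be 2-D grids of equal shape")
        if not (np.all(np.isfinite(g)) and np.all(np.isfinite(r))):
            raise ParameterError("intensities must be finite")
        if np.any(g < 0) or np.any(r < 0):
            raise ParameterError("intensities must be non-negative")
        self.green, self.red = g, r


@dataclass
class TouchCohort:
    """Binary gentle-touch outcomes: shape (animals, 3 trials, 4 behaviors).

    Behavior order along the last axis: pause, head withdrawal, turn,
    reverse locomotion.
    """

    outcomes: np.ndarray
    probabilities: np.ndarray

    BEHAVIORS = ("pause", "head_withdrawal", "turn", "reverse_locomotion")

    def __post_init__(self) -> None:
        o = np.asarray(self.outcomes, dtype=int)
        if o.ndim != 3 or o.shape[1] != 3 or o.shape[2] != 4:
            raise ParameterError("outcomes must have shape (n_animals, 3, 4)")
        if not np.isin(o, (0, 1)).all():
            raise ParameterError("outcomes must be binary")
        self.outcomes = o

    @property
    def n_animals(self) -> int:
        return int(self.outcomes.shape[0])


# --------------------------------------------------------------------------
# Temperature profiles
# --------------------------------------------------------------------------

#: Default stimulus paradigms.  ``gcamp``: 30 s baseline at 25 degC, ramp to
#: 6 degC at 20 degC/min, 10 s hold, ramp back, 30 s recovery.  ``ephys``:
#: 30 s at room temperature (~22 degC), fast ramp (3.3 degC/s) to the target,
#: 60 s hold, fast ramp back.  ``behavior``: brief room-temperature baseline
#: then contact with a 10 degC plate (effectively a fast ramp) held for the
#: 5 s scoring window and beyond.
PARADIGMS: dict[str, dict] = {
    "gcamp": dict(baseline_c=25.0, baseline_s=30.0, target_c=6.0,
                  ramp_rate=20.0 / 60.0, hold_s=10.0, post_s=30.0),
    "ephys": dict(baseline_c=22.0, baseline_s=30.0, target_c=10.0,
                  ramp_rate=3.3, hold_s=60.0, post_s=10.0),
    "behavior": dict(baseline_c=23.0, baseline_s=5.0, target_c=10.0,
                     ramp_rate=20.0, hold_s=10.0, post_s=0.0),
}


def make_temperature_profile(
    paradigm: str = "gcamp",
    *,
    target_c: float | None = None,
    ramp_rate: float | None = None,
    hold_s: float | None = None,
    baseline_s: float | None = None,
    baseline_c: float | None = None,
    post_s: float | None = None,
    sample_rate: float = 20.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> TemperatureProfile:
    """Build a piecewise-linear baseline -> ramp-down -> hold -> ramp-up profile.

    Parameters default to the named ``paradigm`` (see :data:`PARADIGMS`); any
    keyword overrides the paradigm value.  ``ramp_rate`` is in degC/s,
    ``noise_sd`` adds i.i.d. Gaussian sensor noise.  The stimulus-onset
    annotation is the end of the baseline.
    """
    if paradigm not in PARADIGMS:
        raise ParameterError(f"unknown paradigm {paradigm!r}")
    p = dict(PARADIGMS[paradigm])
    for name, value in (("target_c", target_c), ("ramp_rate", ramp_rate),
                        ("hold_s", hold_s), ("baseline_s", baseline_s),
                        ("baseline_c", baseline_c), ("post_s", post_s)):
        if value is not None:
            p[name] = float(value)
    if p["ramp_rate"] <= 0 or sample_rate <= 0:
        raise ParameterError("ramp_rate and sample_rate must be positive")
    if p["hold_s"] < 0 or p["baseline_s"] < 0 or p["post_s"] < 0:
        raise ParameterError("durations must be non-negative")

    drop = abs(p["baseline_c"] - p["target_c"])
    ramp_s = drop / p["ramp_rate"]
    total = p["baseline_s"] + ramp_s + p["hold_s"] + ramp_s + p["post_s"]
    n = int(round(total * sample_rate)) + 1
    t = np.arange(n) / sample_rate
    knot_t = np.array([0.0, p["baseline_s"], p["baseline_s"] + ramp_s,
                       p["baseline_s"] + ramp_s + p["hold_s"],
                       p["baseline_s"] + ramp_s + p["hold_s"] + ramp_s, total])
    knot_T = np.array([p["baseline_c"], p["baseline_c"], p["target_c"],
                       p["target_c"], p["baseline_c"], p["baseline_c"]])
    temp = np.interp(t, knot_t, knot_T)
    if noise_sd > 0:
        temp = temp + np.random.default_rng(seed).normal(0.0, noise_sd, size=n)
    return TemperatureProfile(times=t, temperature=temp,
                              onset=p["baseline_s"], target=p["target_c"])


# --------------------------------------------------------------------------
# Area traces and cohorts (cold-plate / optogenetic behavior)
# --------------------------------------------------------------------------


def simulate_area_trace(
    *,
    baseline_area: float = 2000.0,
    responder: bool = True,
    magnitude: float = 0.25,
    latency: float = 0.5,
    ct_duration: float = 2.5,
    transition: float = 0.3,
    recovery_tau: float = 1.0,
    noise_sd: float = 0.02,
    frame_rate: float = 30.0,
    total_s: float = 10.0,
    onset: float = 2.0,
    animal_id: str = "animal0",
    seed: int | None = None,
) -> AreaTrace:
    """Simulate a larval silhouette area trace with an optional contraction.

    A responder's area declines smoothly (half-cosine ramp of width
    ``transition`` seconds; width 0 means a step) from ``baseline_area`` to
    ``(1 - magnitude) * baseline_area`` starting ``latency`` seconds after
    stimulus ``onset``, holds there for ``ct_duration`` seconds, then relaxes
    exponentially back with time constant ``recovery_tau`` (0 means a step
    back).  A non-responder stays at baseline.  Noise is multiplicative
    Gaussian with standard deviation ``noise_sd`` (fraction of the local
    area).  The noiseless series and generating parameters are stored in
    ``ground_truth``.
    """
    if not (0.0 <= magnitude < 1.0):
        raise ParameterError("magnitude must lie in [0, 1)")
    if min(latency, ct_duration, transition, recovery_tau) < 0:
        raise ParameterError("durations must be non-negative")
    if frame_rate <= 0 or baseline_area <= 0:
        raise ParameterError("frame_rate and baseline_area must be positive")

    n = int(round(total_s * frame_rate))
    t = np.arange(n) / frame_rate
    clean = np.full(n, baseline_area, dtype=float)
    if responder and magnitude > 0:
        t0 = onset + latency                  # contraction starts
        t1 = t0 + transition                  # fully contracted
        t2 = t1 + ct_duration                 # release starts
        depth = magnitude * baseline_area
        frac = np.zeros(n)
        if transition > 0:
            ramp = (t >= t0) & (t < t1)
            frac[ramp] = 0.5 * (1 - np.cos(np.pi * (t[ramp] - t0) / transition))
        frac[(t >= t1) & (t < t2)] = 1.0
        post = t >= t2
        if recovery_tau > 0:
            frac[post] = np.exp(-(t[post] - t2) / recovery_tau)
        clean = baseline_area - depth * frac

    rng = np.random.default_rng(seed)
    areas = clean * (1.0 + rng.normal(0.0, noise_sd, size=n)) if noise_sd > 0 \
        else clean.copy()
    areas = np.clip(areas, 1e-9, None)
    truth = dict(responder=bool(responder and magnitude > 0),
                 magnitude=float(magnitude), latency=float(latency),
                 ct_duration=float(ct_duration), clean_areas=clean,
                 baseline_area=float(baseline_area))
    return AreaTrace(frame_rate=frame_rate, areas=areas, onset=onset,
                     animal_id=animal_id, ground_truth=truth)


def simulate_cohort_traces(
    n_animals: int,
    p_ct: float,
    *,
    magnitude_mean: float = 0.25,
    magnitude_sd: float = 0.04,
    duration_mean: float = 2.5,
    duration_sd: float = 0.5,
    seed: int | None = None,
    **trace_params,
) -> list[AreaTrace]:
    """Simulate a cohort: each animal responds independently with ``p_ct``.

    Responder magnitude and hold duration are drawn per animal from clipped
    normal distributions; remaining keyword arguments are forwarded to
    :func:`simulate_area_trace`.
    """
    if n_animals < 1:
        raise ParameterError("n_animals must be >= 1")
    if not (0.0 <= p_ct <= 1.0):
        raise ParameterError("p_ct must lie in [0, 1]")
    ss = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    child_seeds = ss.spawn(n_animals)
    traces = []
    for i in range(n_animals):
        responder = bool(rng.random() < p_ct)
        mag = float(np.clip(rng.normal(magnitude_mean, magnitude_sd), 0.15, 0.95))
        dur = float(np.clip(rng.normal(duration_mean, duration_sd), 0.7, None))
        traces.append(simulate_area_trace(
            responder=responder, magnitude=mag, ct_duration=dur,
            animal_id=f"animal{i}", seed=child_seeds[i], **trace_params))
    return traces


# --------------------------------------------------------------------------
# Spike trains
# --------------------------------------------------------------------------


def simulate_spike_train(
    profile: TemperatureProfile,
    *,
    tonic_base_hz: float = 1.0,
    tonic_cold_gain: float = 0.25,
    cold_threshold_c: float = 18.0,
    burst_rate_per_degc: float = 0.5,
    burst_spikes_mean: float = 5.0,
    burst_spikes_min: int = 3,
    intra_burst_isi: tuple[float, float] = (0.02, 0.12),
    tonic_min_isi: float = 0.2,
    seed: int | None = None,
) -> SpikeTrain:
    """Simulate temperature-coupled spiking: a tonic renewal process plus
    bursts triggered during cooling ramps.

    The tonic process fires at hazard ``tonic_base_hz + tonic_cold_gain *
    max(0, cold_threshold_c - T(t))`` Hz with a refractory floor of
    ``tonic_min_isi`` seconds (inter-spike intervals are the floor plus an
    exponential, so the mean rate matches the hazard exactly).  Burst events
    arrive at rate ``burst_rate_per_degc * max(0, -dT/dt)`` per second —
    i.e. ``burst_rate_per_degc`` bursts per degC dropped — each a run of
    ``>= burst_spikes_min`` spikes with intra-burst ISIs drawn uniformly from
    ``intra_burst_isi``.  Tonic spikes falling within one intra-burst bound
    of a burst are removed so generator labels are exactly recoverable by an
    ISI classifier with its cutoff between ``intra_burst_isi[1]`` and
    ``tonic_min_isi``.
    """
    lo, hi = intra_burst_isi
    if not (0 < lo < hi):
        raise ParameterError("intra-burst ISI range must satisfy 0 < lo < hi")
    if hi >= 0.15:
        raise ParameterError("intra-burst ISI upper bound must be < 0.15 s")
    if tonic_min_isi <= 0.15:
        raise ParameterError("tonic minimum ISI must be > 0.15 s")
    if burst_spikes_min < 3:
        raise ParameterError("bursts need at least 3 spikes")
    rng = np.random.default_rng(seed)
    t0, t1 = float(profile.times[0]), float(profile.times[-1])

    def tonic_rate(time: float) -> float:
        temp = float(np.interp(time, profile.times, profile.temperature))
        return tonic_base_hz + tonic_cold_gain * max(0.0, cold_threshold_c - temp)

    max_rate = tonic_base_hz + tonic_cold_gain * max(
        0.0, cold_threshold_c - float(profile.temperature.min()))
    if max_rate * tonic_min_isi >= 1.0:
        raise ParameterError(
            "tonic rate too high for the refractory floor (rate * min_isi >= 1)")

    # Tonic renewal process: ISI = floor + Exp(1/r - floor) so E[ISI] = 1/r.
    tonic: list[float] = []
    t = t0 + rng.exponential(1.0 / tonic_rate(t0))
    while t < t1:
        tonic.append(t)
        r = tonic_rate(t)
        t += tonic_min_isi + rng.exponential(1.0 / r - tonic_min_isi)

    # Burst events: inhomogeneous Poisson on the cooling hazard, by thinning.
    cooling = profile.cooling_rate()
    lam = burst_rate_per_degc * cooling
    lam_max = float(lam.max())
    burst_starts: list[float] = []
    if lam_max > 0 and burst_rate_per_degc > 0:
        t = t0
        while True:
            t += rng.exponential(1.0 / lam_max)
            if t >= t1:
                break
            if rng.random() < np.interp(t, profile.times, lam) / lam_max:
                burst_starts.append(t)

    burst_spikes: list[float] = []
    bursts_kept: list[np.ndarray] = []
    prev_end = -np.inf
    for bs in burst_starts:
        if bs < prev_end + tonic_min_isi:
            continue  # keep bursts separated beyond the classifier cutoff
        n_spk = burst_spikes_min + int(rng.poisson(
            max(0.0, burst_spikes_mean - burst_spikes_min)))
        isis = rng.uniform(lo, hi, size=n_spk - 1)
        times = bs + np.concatenate([[0.0], np.cumsum(isis)])
        times = times[times < t1]
        if times.size < burst_spikes_min:
            continue
        bursts_kept.append(times)
        burst_spikes.extend(times.tolist())
        prev_end = times[-1]

    burst_arr = np.asarray(burst_spikes)
    tonic_arr = np.asarray(tonic)
    if burst_arr.size and tonic_arr.size:
        # drop tonic spikes too close to a burst (labels stay recoverable)
        d = np.min(np.abs(tonic_arr[:, None] - burst_arr[None, :]), axis=1)
        tonic_arr = tonic_arr[d > hi + (0.15 - hi) + 1e-6]

    times = np.concatenate([tonic_arr, burst_arr])
    labels = np.concatenate([np.full(tonic_arr.size, "tonic"),
                             np.full(burst_arr.size, "burst")])
    order = np.argsort(times)
    return SpikeTrain(times=times[order], window=(t0, t1),
                      labels=labels[order], profile=profile)


# --------------------------------------------------------------------------
# Two-channel neuron images
# --------------------------------------------------------------------------


def simulate_neuron_image(
    *,
    shape: tuple[int, int] = (256, 256),
    soma_center: tuple[float, float] = (128.0, 128.0),
    soma_radius: float = 10.0,
    n_dendrites: int = 6,
    dendrite_length: float = 80.0,
    dendrite_width: float = 3.0,
    soma_level: float = 200.0,
    dendrite_level: float = 120.0,
    background: float = 5.0,
    rho: float | Callable[[np.ndarray], np.ndarray] | np.ndarray = 1.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> TwoChannelImage:
    """Simulate a two-channel neuron image: soma disk plus radial dendrites.

    The green channel is ``background`` plus ``soma_level`` on the soma disk
    and ``dendrite_level`` on ``n_dendrites`` evenly spaced straight dendrites
    of the given length and width.  The red channel is ``rho * green``
    pixelwise before noise, where ``rho`` is a constant, a callable of radial
    distance from the soma center (in pixels), or a full 2-D field.  Gaussian
    noise of standard deviation ``noise_sd`` is added independently to both
    channels (clipped at 0).  Ground truth (foreground mask, soma center,
    true ratio field) is stored on the result.
    """
    h, w = shape
    cy, cx = soma_center
    if soma_radius < 2:
        raise ParameterError("soma radius must be >= 2 px")
    if not (0 <= cy < h and 0 <= cx < w):
        raise ParameterError("soma center must lie inside the image")
    if cy - soma_radius < 0 or cy + soma_radius >= h \
            or cx - soma_radius < 0 or cx + soma_radius >= w:
        raise ParameterError("soma disk must fit inside the image")
    if min(soma_level, dendrite_level, background) < 0:
        raise ParameterError("intensity levels must be non-negative")

    yy, xx = np.mgrid[0:h, 0:w]
    dy, dx = yy - cy, xx - cx
    r = np.hypot(dy, dx)
    soma_mask = r <= soma_radius

    dend_mask = np.zeros(shape, dtype=bool)
    for k in range(n_dendrites):
        theta = 2 * np.pi * k / max(n_dendrites, 1)
        uy, ux = np.sin(theta), np.cos(theta)
        along = dy * uy + dx * ux            # projection onto the ray
        perp = np.abs(dy * ux - dx * uy)     # distance from the ray line
        dend_mask |= (along >= 0) & (along <= dendrite_length) \
            & (perp <= dendrite_width / 2.0)
    dend_mask &= ~soma_mask

    green = np.full(shape, float(background))
    green[dend_mask] = background + dendrite_level
    green[soma_mask] = background + soma_level

    if callable(rho):
        rho_field = np.asarray(rho(r), dtype=float)
    elif np.isscalar(rho):
        rho_field = np.full(shape, float(rho))
    else:
        rho_field = np.asarray(rho, dtype=float)
        if rho_field.shape != shape:
            raise ParameterError("rho field shape must match the image")
    if np.any(rho_field < 0):
        raise ParameterError("rho must be non-negative")
    red = rho_field * green

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        green = np.clip(green + rng.normal(0, noise_sd, shape), 0, None)
        red = np.clip(red + rng.normal(0, noise_sd, shape), 0, None)

    return TwoChannelImage(green=green, red=red, mask=soma_mask | dend_mask,
                           soma_centers=[(float(cy), float(cx))],
                           rho=rho_field)


# --------------------------------------------------------------------------
# Larva video frames
# --------------------------------------------------------------------------


def simulate_larva_frames(
    traces: AreaTrace | Sequence[AreaTrace],
    *,
    arena: tuple[int, int] = (600, 600),
    positions: Sequence[tuple[float, float]] | None = None,
    aspect_ratio: float = 3.0,
    orientations: Sequence[float] | None = None,
    foreground: float = 200.0,
    background: float = 20.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> tuple[np.ndarray, dict]:
    """Rasterize one or more area traces as ellipses in a gray-scale video.

    Each larva is an ellipse of fixed ``aspect_ratio`` (major/minor axis)
    whose pixel area tracks its :class:`AreaTrace` frame by frame (up to
    rasterization error, about 1%).  Returns ``(frames, ground_truth)`` where
    ``frames`` has shape (n_frames, H, W) and ``ground_truth`` holds the
    requested and the exact rasterized per-frame areas and the centers.
    """
    from skimage.draw import ellipse as draw_ellipse

    if isinstance(traces, AreaTrace):
        traces = [traces]
    if not traces:
        raise ParameterError("need at least one trace")
    n_frames = traces[0].areas.size
    if any(tr.areas.size != n_frames for tr in traces):
        raise ParameterError("all traces must have the same length")
    h, w = arena
    if positions is None:
        # spread larvae along the diagonal
        positions = [((i + 1) * h / (len(traces) + 1),
                      (i + 1) * w / (len(traces) + 1))
                     for i in range(len(traces))]
    if orientations is None:
        orientations = [0.0] * len(traces)
    if aspect_ratio < 1:
        raise ParameterError("aspect_ratio must be >= 1")

    for tr, (cy, cx) in zip(traces, positions):
        a_max = np.sqrt(float(tr.areas.max()) * aspect_ratio / np.pi)
        if cy - a_max < 1 or cy + a_max >= h - 1 or cx - a_max < 1 \
                or cx + a_max >= w - 1:
            raise ParameterError("ellipse exceeds the arena at maximum area")

    rng = np.random.default_rng(seed)
    frames = np.full((n_frames, h, w), float(background))
    raster_areas = np.zeros((len(traces), n_frames))
    for f in range(n_frames):
        for i, (tr, (cy, cx), ang) in enumerate(
                zip(traces, positions, orientations)):
            area = float(tr.areas[f])
            a = np.sqrt(area * aspect_ratio / np.pi)  # semi-major
            b = a / aspect_ratio                      # semi-minor
            rr, cc = draw_ellipse(cy, cx, b, a, shape=(h, w), rotation=ang)
            frames[f, rr, cc] = foreground
            raster_areas[i, f] = rr.size
    if noise_sd > 0:
        frames = np.clip(frames + rng.normal(0, noise_sd, frames.shape), 0, None)

    truth = dict(requested_areas=np.array([tr.areas for tr in traces]),
                 raster_areas=raster_areas,
                 positions=[tuple(map(float, p)) for p in positions],
                 frame_rate=traces[0].frame_rate, onset=traces[0].onset)
    return frames, truth


# --------------------------------------------------------------------------
# Gentle-touch cohorts
# --------------------------------------------------------------------------


def simulate_touch_cohort(
    n_animals: int,
    probabilities: Sequence[float] = (0.6, 0.6, 0.6, 0.6),
    *,
    seed: int | None = None,
) -> TouchCohort:
    """Simulate a gentle-touch cohort: 3 trials per animal, each of the four
    behaviors (pause, head withdrawal, turn, reverse locomotion) an
    independent Bernoulli draw with its own probability."""
    if n_animals < 1:
        raise ParameterError("n_animals must be >= 1")
    p = np.asarray(probabilities, dtype=float)
    if p.shape != (4,) or np.any(p < 0) or np.any(p > 1):
        raise ParameterError("need 4 probabilities in [0, 1]")
    rng = np.random.default_rng(seed)
    outcomes = (rng.random((n_animals, 3, 4)) < p).astype(int)
    return TouchCohort(outcomes=outcomes, probabilities=p)
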