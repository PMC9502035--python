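"""Extracellular spike-train analysis: burst/tonic decomposition and rates.

Single-unit suction-electrode recordings of larval cold-sensing neurons show
two firing modes: **bursts** — groups of three or more consecutive spikes
whose every inter-spike interval is below 0.15 s — and **tonic** spikes, the
remainder.  Classification is global over the whole recording (a burst that
straddles a bin edge keeps its label), after which rates are reported in
10-s bins aligned to stimulus onset, in named epochs (e.g. the first 10 s of
stimulus delivery), and as percent change from a control mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidSignalError, InvalidTrainError, ParameterError
from .synthgen import SpikeTrain

ISI_MAX = 0.15      # s, strict upper bound on intra-burst intervals
MIN_BURST_SPIKES = 3
BIN_WIDTH = 10.0    # s

# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------


@dataclass
class BurstSegmentation:
    """A burst/tonic label for every spike of a train."""

    train: SpikeTrain
    labels: np.ndarray                 # 'burst' | 'tonic' per spike
    bursts: list[np.ndarray] = field(default_factory=list)  # index runs

    def __post_init__(self) -> None:
        if self.labels.shape != self.train.times.shape:
            raise InvalidTrainError("one label per spike required")

    def times_of(self, kind: str) -> np.ndarray:
        """Spike times of one class: 'all', 'burst', or 'tonic'."""
        if kind == "all":
            return self.train.times
        return self.train.times[self.labels == kind]

    @property
    def n_burst(self) -> int:
        return int(np.sum(self.labels == "burst"))

    @property
    def n_tonic(self) -> int:
        return int(np.sum(self.labels == "tonic"))


@dataclass
class BinnedRates:
    """Firing rates per fixed-width bin, split by spike class."""

    edges: np.ndarray                  # bin edges, s
    total: np.ndarray                  # spikes/s per bin
    burst: np.ndarray
    tonic: np.ndarray
    counts_total: np.ndarray
    counts_burst: np.ndarray
    counts_tonic: np.ndarray
    partial_last: bool


@dataclass
class EpochRates:
    """Mean rate of one spike class over a named epoch."""

    label: str
    start: float
    end: float
    n_spikes: int
    rate: float                        # spikes/s

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ParameterError("epoch must have positive length")


# --------------------------------------------------------------------------
# Spike detection
# --------------------------------------------------------------------------


def detect_spike_times(
    signal: np.ndarray,
    sample_rate: float,
    threshold: float,
    polarity: str = "positive",
    refractory: float = 0.002,
    t0: float = 0.0,
) -> SpikeTrain:
    """Threshold-crossing spike detection with a refractory period.

    One spike is recorded at each sample where the signal crosses
    ``threshold`` in the configured ``polarity`` ('positive' or 'negative'),
    suppressing crossings within ``refractory`` seconds of the previous
    accepted spike.  Deliberately minimal: recordings are single-unit, so no
    waveform sorting is attempted.
    """
    signal = np.asarray(signal, dtype=float)
    if sample_rate <= 0:
        raise ParameterError("sample_rate must be positive")
    if not np.all(np.isfinite(signal)):
        raise InvalidSignalError("signal contains non-finite samples")
    if polarity == "negative":
        signal, threshold = -signal, -threshold
    elif polarity != "positive":
        raise ParameterError("polarity must be 'positive' or 'negative'")
    above = signal > threshold
    crossings = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    if above.size and above[0]:
        crossings = np.concatenate([[0], crossings])
    times = []
    last = -np.inf
    for idx in crossings:
        t = t0 + idx / sample_rate
        if t - last >= refractory:
            times.append(t)
            last = t
    window = (t0, t0 + signal.size / sample_rate)
    return SpikeTrain(times=np.asarray(times), window=window)


# --------------------------------------------------------------------------
# Burst / tonic classification
# --------------------------------------------------------------------------


def classify_spikes(
    train: SpikeTrain,
    isi_max: float = ISI_MAX,
    min_count: int = MIN_BURST_SPIKES,
) -> BurstSegmentation:
    """Partition a spike train into bursting and tonic spikes.

    The train is split into maximal runs of consecutive spikes whose every
    inter-spike interval is strictly below ``isi_max``; runs of at least
    ``min_count`` spikes are bursts and all their member spikes are labeled
    'burst', every other spike 'tonic'.  An ISI exactly equal to ``isi_max``
    does not join a burst.  Because runs are maximal, any qualifying group
    of spikes is contained in exactly one run, so the labeling is unique.
    """
    t = np.asarray(train.times, dtype=float)
    if t.size and np.any(np.diff(t) < 0):
        raise InvalidTrainError("spike times must be sorted")
    labels = np.full(t.size, "tonic", dtype=object)
    bursts: list[np.ndarray] = []
    if t.size:
        short = np.diff(t) < isi_max          # strict comparison
        # maximal runs: spike i joins spike i+1 when short[i]
        run_start = 0
        for i in range(t.size):
            end_of_run = i == t.size - 1 or not short[i]
            if end_of_run:
                run = np.arange(run_start, i + 1)
                if run.size >= min_count:
                    labels[run] = "burst"
                    bursts.append(run)
                run_start = i + 1
    return BurstSegmentation(train=train, labels=np.asarray(labels, dtype=object),
                             bursts=bursts)


# --------------------------------------------------------------------------
# Rates
# --------------------------------------------------------------------------


def bin_rates(
    seg: BurstSegmentation,
    bin_width: float = BIN_WIDTH,
    start: float | None = None,
    end: float | None = None,
) -> BinnedRates:
    """Per-bin total, bursting, and tonic firing rates.

    Bins of ``bin_width`` seconds are laid from ``start`` (default: stimulus
    onset if the train carries a temperature profile, else the window start)
    to ``end`` (default: window end).  Spikes keep their global labels;
    per-bin counts therefore conserve total = burst + tonic exactly.  A
    trailing bin shorter than ``bin_width`` is flagged and its rate uses the
    actual bin duration.
    """
    if bin_width <= 0:
        raise ParameterError("bin_width must be positive")
    w0, w1 = seg.train.window
    if start is None:
        start = seg.train.profile.onset if seg.train.profile is not None else w0
    if end is None:
        end = w1
    if not (w0 - 1e-9 <= start < end <= w1 + 1e-9):
        raise ParameterError("binning window must lie within the recording")
    edges = np.arange(start, end, bin_width)
    edges = np.append(edges, end)
    durations = np.diff(edges)
    partial = bool(abs(durations[-1] - bin_width) > 1e-9)

    def counts(times: np.ndarray) -> np.ndarray:
        return np.histogram(times, bins=edges)[0]

    c_tot = counts(seg.times_of("all"))
    c_b = counts(seg.times_of("burst"))
    c_t = counts(seg.times_of("tonic"))
    return BinnedRates(edges=edges, total=c_tot / durations,
                       burst=c_b / durations, tonic=c_t / durations,
                       counts_total=c_tot, counts_burst=c_b, counts_tonic=c_t,
                       partial_last=partial)


def epoch_rate(
    seg: BurstSegmentation,
    start: float,
    end: float,
    spike_class: str = "all",
    label: str = "",
) -> EpochRates:
    """Mean rate of one spike class over ``[start, end)``."""
    if end <= start:
        raise ParameterError("epoch must have positive length")
    w0, w1 = seg.train.window
    if start < w0 - 1e-9 or end > w1 + 1e-9:
        raise ParameterError("epoch must lie within the recording")
    if spike_class not in ("all", "burst", "tonic"):
        raise ParameterError("spike_class must be 'all', 'burst' or 'tonic'")
    times = seg.times_of(spike_class)
    n = int(np.sum((times >= start) & (times < end)))
    return EpochRates(label=label or spike_class, start=start, end=end,
                      n_spikes=n, rate=n / (end - start))


def percent_change_vs_control(test_mean: float, control_mean: float) -> float:
    """Percent change of a test-group mean from the control mean."""
    if control_mean == 0:
        raise ParameterError("control mean must be non-zero")
    return 100.0 * (test_mean - control_mean) / control_mean
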