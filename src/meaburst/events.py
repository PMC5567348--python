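"""Burst, network-burst and leadership detection.

Single-channel bursts are found with the logISI method: the histogram of
log10 inter-spike intervals of a channel is typically bimodal, with an
intra-burst peak below ~100 ms and an inter-burst peak at much longer
intervals; the ISI threshold is placed at the deepest valley between the
two, provided the valley is deep enough (void parameter >= 0.7).

Network bursts (NBs) are chains of temporally overlapping (or nearly
overlapping) single-channel bursts involving at least 20% of the active
channels.  For each NB we keep the rank order of electrode activation
and each electrode's delay from the first-firing electrode (the leader).
Electrodes leading at least 4% of all NBs are major leaders (MLs).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .config import AnalysisConfig
from .io import SpikeTrainSet

log = logging.getLogger("meaburst.events")


@dataclass
class Burst:
    electrode: str
    start_ms: float
    end_ms: float
    spike_times: np.ndarray

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times.size)

    @property
    def duration_ms(self) -> float:
        return self.end_ms - self.start_ms


@dataclass
class NetworkBurst:
    id: int
    onset_ms: float
    offset_ms: float
    leader: str
    #: electrodes in order of first-spike time within the NB
    order: list[str]
    #: first-spike delay (ms) from the leader, same order as ``order``
    delays: dict[str, float]
    tie_broken: bool = False

    @property
    def participants(self) -> list[str]:
        return list(self.order)


@dataclass
class LeadershipTable:
    n_nbs: int
    led: dict[str, int]
    #: leadership score, percent of all NBs led
    score: dict[str, float]
    major_leaders: list[str]
    activity: dict[str, dict] = field(default_factory=dict)


def logisi_threshold(isis_ms, config: AnalysisConfig | None = None) -> float | None:
    """ISI threshold (ms) separating intra- from inter-burst intervals.

    Builds the histogram of log10(ISI) on a fixed grid
    (``logisi_bins_per_decade`` bins per decade), smooths it with a
    short moving average, and searches the valley between the largest
    peak below ``intra_burst_peak_max_ms`` and each later peak.  Among
    valleys whose depth (void parameter)

        void = 1 - h_min / sqrt(h_peak1 * h_peak2)

    reaches ``void_threshold``, the deepest is returned (ties broken
    toward the shorter ISI).  Returns None when the histogram has no
    sub-100 ms peak or no sufficiently deep valley.
    """
    cfg = config or AnalysisConfig()
    isis = np.asarray(isis_ms, dtype=float)
    if isis.size == 0:
        raise ValueError("empty ISI list")
    isis = isis[isis > 0]
    if isis.size < 10:
        return None

    step = 1.0 / cfg.logisi_bins_per_decade
    lo = math.floor(np.log10(isis.min()) / step) * step
    hi = math.ceil(np.log10(isis.max()) / step) * step + step
    edges = np.arange(lo, hi + step / 2, step)
    hist, _ = np.histogram(np.log10(isis), bins=edges)

    w = cfg.logisi_smooth_bins
    kernel = np.ones(w) / w
    sm = np.convolve(hist.astype(float), kernel, mode="same")
    centers = (edges[:-1] + edges[1:]) / 2.0

    # local maxima of the smoothed histogram; a prominence floor keeps
    # sub-bin noise in the tails from posing as peaks
    floor = cfg.logisi_peak_prominence_frac * float(sm.max())
    peaks, _ = find_peaks(sm, prominence=max(floor, 1e-9))
    if peaks.size < 2:
        return None

    intra = [p for p in peaks if 10 ** centers[p] < cfg.intra_burst_peak_max_ms]
    if not intra:
        return None
    p1 = max(intra, key=lambda p: (sm[p], -p))

    # walk outward from the intra-burst peak; the valley is the deepest
    # point between it and the candidate inter-burst peak, accepted at
    # the first peak whose valley is deep enough (void >= threshold)
    for p2 in peaks[peaks > p1]:
        seg = sm[p1 + 1:p2]
        if seg.size == 0:
            continue
        imin = p1 + 1 + int(np.argmin(seg))
        void = 1.0 - sm[imin] / math.sqrt(sm[p1] * sm[p2])
        if void >= cfg.void_threshold:
            return float(10 ** centers[imin])
    return None


def detect_bursts(spike_times, threshold_ms: float,
                  min_spikes: int = 3, electrode: str = "") -> list[Burst]:
    """Maximal runs of spikes whose consecutive ISIs are all <= threshold."""
    if threshold_ms <= 0:
        raise ValueError("threshold must be positive")
    t = np.asarray(spike_times, dtype=float)
    bursts: list[Burst] = []
    if t.size < min_spikes:
        return bursts
    breaks = np.flatnonzero(np.diff(t) > threshold_ms)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [t.size - 1]))
    for s, e in zip(starts, ends):
        if e - s + 1 >= min_spikes:
            bursts.append(Burst(electrode=electrode, start_ms=float(t[s]),
                                end_ms=float(t[e]), spike_times=t[s:e + 1]))
    return bursts


def channel_isi_thresholds(sts: SpikeTrainSet,
                           config: AnalysisConfig) -> dict[str, float]:
    """Per-channel burst-detection ISI threshold.

    The logISI valley where found (configured fallback otherwise),
    capped at ``max_isi_threshold_ms``: intra-burst intervals are short,
    so a valley above the cap would let stray background spikes attach
    to burst fronts and bridge separate events.
    """
    out = {}
    for e, t in sts.spikes.items():
        if t.size < 2:
            out[e] = min(config.fallback_isi_ms, config.max_isi_threshold_ms)
            continue
        try:
            thr = logisi_threshold(np.diff(t), config)
        except ValueError:
            thr = None
        if thr is None:
            thr = config.fallback_isi_ms
        out[e] = min(thr, config.max_isi_threshold_ms)
    return out


def detect_channel_bursts(sts: SpikeTrainSet, config: AnalysisConfig,
                          thresholds: dict[str, float] | None = None,
                          ) -> dict[str, list[Burst]]:
    thresholds = thresholds or channel_isi_thresholds(sts, config)
    return {
        e: detect_bursts(sts.spikes[e], thresholds[e],
                         config.min_spikes_per_burst, electrode=e)
        for e in sts.spikes
    }


def detect_network_bursts(bursts_by_channel: dict[str, list[Burst]],
                          active_channels: int,
                          config: AnalysisConfig) -> list[NetworkBurst]:
    """Chain single-channel bursts into network bursts.

    Bursts are chained when they overlap in time or the gap between one
    burst's end and the next burst's start is at most
    ``nb_chain_gap_ms``.  A chain qualifies as an NB when it involves at
    least ``ceil(nb_participation_frac * active_channels)`` distinct
    channels.
    """
    if active_channels <= 0:
        raise ValueError("active_channels must be positive")
    min_ch = math.ceil(config.nb_participation_frac * active_channels)
    all_bursts = sorted(
        (b for bl in bursts_by_channel.values() for b in bl),
        key=lambda b: (b.start_ms, b.electrode),
    )
    nbs: list[NetworkBurst] = []
    chain: list[Burst] = []
    chain_end = -math.inf

    def flush(chain: list[Burst]) -> None:
        channels = {b.electrode for b in chain}
        if len(channels) < min_ch:
            return
        first_spike = {}
        for b in chain:
            t0 = float(b.spike_times[0])
            if b.electrode not in first_spike or t0 < first_spike[b.electrode]:
                first_spike[b.electrode] = t0
        order = sorted(first_spike, key=lambda e: (first_spike[e], e))
        tie = len({first_spike[e] for e in order}) < len(order)
        leader = order[0]
        t_lead = first_spike[leader]
        delays = {e: first_spike[e] - t_lead for e in order}
        nbs.append(NetworkBurst(
            id=len(nbs),
            onset_ms=t_lead,
            offset_ms=max(b.end_ms for b in chain),
            leader=leader,
            order=order,
            delays=delays,
            tie_broken=tie,
        ))

    for b in all_bursts:
        if chain and b.start_ms > chain_end + config.nb_chain_gap_ms:
            flush(chain)
            chain = []
            chain_end = -math.inf
        chain.append(b)
        chain_end = max(chain_end, b.end_ms)
    if chain:
        flush(chain)
    for i, nb in enumerate(nbs):
        nb.id = i
    return nbs


def extract_activation_pattern(nb: NetworkBurst) -> list[str]:
    """Activation rank order: distinct electrodes sorted by delay, ties
    broken lexicographically by label (flagged on the NB)."""
    if nb.tie_broken:
        log.debug("NB %d: activation-time tie broken lexicographically", nb.id)
    return list(nb.order)


def leadership_scores(nbs: list[NetworkBurst],
                      config: AnalysisConfig | None = None) -> LeadershipTable:
    """Leadership score LS(e) = percent of NBs led by electrode e; MLs are
    electrodes with LS at or above the 4% cutoff (inclusive)."""
    cfg = config or AnalysisConfig()
    if not nbs:
        raise ValueError("no network bursts")
    led: dict[str, int] = {}
    for nb in nbs:
        led[nb.leader] = led.get(nb.leader, 0) + 1
    n = len(nbs)
    score = {e: 100.0 * c / n for e, c in led.items()}
    cutoff = 100.0 * cfg.ml_leadership_frac
    mls = sorted(e for e, s in score.items() if s >= cutoff - 1e-12)
    return LeadershipTable(n_nbs=n, led=led, score=score, major_leaders=mls)


def channel_activity_stats(sts: SpikeTrainSet,
                           bursts_by_channel: dict[str, list[Burst]],
                           config: AnalysisConfig | None = None,
                           ) -> tuple[dict[str, dict], list[str]]:
    """Per-electrode firing rate, fraction of spikes inside bursts and
    mean burst duration; the active set is rate strictly above the
    ``active_rate_min`` cutoff."""
    cfg = config or AnalysisConfig()
    if sts.duration_ms <= 0:
        raise ValueError("recording duration must be positive")
    stats = {}
    for e, t in sts.spikes.items():
        bl = bursts_by_channel.get(e, [])
        in_burst = sum(b.n_spikes for b in bl)
        stats[e] = {
            "firing_rate_hz": sts.firing_rate(e),
            "in_burst_frac": in_burst / t.size if t.size else 0.0,
            "mean_burst_duration_ms":
                float(np.mean([b.duration_ms for b in bl])) if bl else 0.0,
            "n_bursts": len(bl),
        }
    active = sorted(e for e, s in stats.items()
                    if s["firing_rate_hz"] > cfg.active_rate_min)
    return stats, active
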