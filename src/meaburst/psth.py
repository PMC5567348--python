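"""Post-stimulus time histograms and early/late response separation.

The PSTH of a recording electrode is the trial-averaged spike count in
2 ms bins over the 500 ms following each stimulation pulse.  Its area
(mean spikes per stimulus in the window) measures response size;
channels with area below 1 are non-responding and excluded.

Evoked responses have an early, temporally precise component (direct
electrical activation, < ~35 ms) and a late network-burst component
(~35-500 ms).  They are separated adaptively per stimulating electrode:
the network PSTH (sum of responding channels) is smoothed with a 20 ms
moving average; if a peak exists within the first 50 ms and another
between 50 and 500 ms, the lowest local minimum between them (x_min)
splits the phases, accepted when the separation index

    s_j = 1 - PSTH_j(x_min) / sqrt(PSTH_j(x_peak1) * PSTH_j(x_peak2))

reaches 0.3.  Evoked NB patterns are then extracted from the late
window only, with delays referenced to the stimulus onset.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .config import AnalysisConfig
from .events import detect_bursts
from .io import SpikeTrainSet, StimulationSession

log = logging.getLogger("meaburst.psth")


@dataclass
class PSTH:
    stim_electrode: str
    electrode: str
    #: mean spike count per trial in each 2 ms bin
    counts: np.ndarray
    #: mean spikes per stimulus in the whole window (= counts.sum())
    area: float
    #: per-trial first-spike latency (ms); NaN for trials with no spike
    first_spike_latency_ms: np.ndarray

    @property
    def mean_latency_ms(self) -> float:
        lat = self.first_spike_latency_ms
        ok = lat[~np.isnan(lat)]
        return float(np.mean(ok)) if ok.size else float("nan")


@dataclass
class EarlyLateSplit:
    stim_electrode: str
    x_peak1_ms: float | None
    x_peak2_ms: float | None
    x_min_ms: float | None
    s: float | None
    accepted: bool
    smoothed: np.ndarray = field(default_factory=lambda: np.empty(0))


@dataclass
class EvokedPattern:
    stim_electrode: str
    trial: int
    order: list[str]
    #: first-spike delay from stimulus onset (ms) per electrode in order
    delays: dict[str, float]


def compute_psth(sts: SpikeTrainSet, session: StimulationSession,
                 config: AnalysisConfig | None = None) -> dict[str, PSTH]:
    """PSTHs of all recording electrodes for one stimulation session."""
    cfg = config or AnalysisConfig()
    onsets = np.asarray(session.onsets_ms, dtype=float)
    if onsets.size == 0:
        raise ValueError("session has no pulses")
    n_bins = cfg.n_psth_bins
    edges = np.arange(n_bins + 1) * cfg.psth_bin_ms
    out = {}
    for e, t in sts.spikes.items():
        counts = np.zeros(n_bins)
        latencies = np.full(onsets.size, np.nan)
        for k, t0 in enumerate(onsets):
            rel = t[(t > t0) & (t <= t0 + cfg.psth_window_ms)] - t0
            if rel.size:
                counts += np.histogram(rel, bins=edges)[0]
                latencies[k] = rel[0]
        counts /= onsets.size
        out[e] = PSTH(stim_electrode=session.electrode, electrode=e,
                      counts=counts, area=float(counts.sum()),
                      first_spike_latency_ms=latencies)
    return out


def select_responding_channels(psths: dict[str, PSTH],
                               config: AnalysisConfig | None = None) -> list[str]:
    """Channels with PSTH area >= 1 (exclusion is strictly 'lower than 1')."""
    cfg = config or AnalysisConfig()
    kept = sorted(e for e, p in psths.items() if p.area >= cfg.psth_area_min)
    if not kept:
        log.warning("stim %s: no responding channels",
                    next(iter(psths.values())).stim_electrode if psths else "?")
    return kept


def normalize_metric(values: dict[str, dict[str, float]],
                     view: str) -> dict[str, dict[str, float]]:
    """Normalize a per-(stim, channel) metric two ways.

    ``values``: stim electrode -> {recording electrode -> value} for the
    responding channels only.

    view "per_channel" (A): each recording channel's values across stim
    sites divided by that channel's maximum — compares stimulation from
    different sites.
    view "per_stim" (B): each stim site's values across channels divided
    by the site maximum — compares responses of different channels.

    Channels/sites whose maximum is 0 (or NaN) are dropped with a log
    message.
    """
    out: dict[str, dict[str, float]] = {}
    if view == "per_stim":
        for j, per_ch in values.items():
            ok = {e: v for e, v in per_ch.items() if np.isfinite(v)}
            if not ok:
                continue
            m = max(ok.values())
            if m <= 0:
                log.info("stim %s dropped from per-stim normalization (max 0)", j)
                continue
            out[j] = {e: v / m for e, v in ok.items()}
    elif view == "per_channel":
        channels = sorted({e for per_ch in values.values() for e in per_ch})
        for e in channels:
            vals = {j: values[j][e] for j in values
                    if e in values[j] and np.isfinite(values[j][e])}
            if not vals:
                continue
            m = max(vals.values())
            if m <= 0:
                log.info("channel %s dropped from per-channel normalization (max 0)", e)
                continue
            for j, v in vals.items():
                out.setdefault(j, {})[e] = v / m
    else:
        raise ValueError(f"unknown view {view!r}")
    return out


def separation_index(peak1: float, peak2: float, valley: float) -> float:
    """Separation between two PSTH peaks with a valley value between them:
    1 when the valley reaches 0, 0 when it equals the geometric mean of
    the peaks (i.e. peaks not separated)."""
    if peak1 <= 0 or peak2 <= 0:
        raise ValueError("peak values must be positive")
    return 1.0 - valley / math.sqrt(peak1 * peak2)


def smooth_network_psth(psths: dict[str, PSTH], responding: list[str],
                        config: AnalysisConfig | None = None) -> np.ndarray:
    """Sum responding channels' PSTHs and apply a centered moving average
    of ``smooth_bin_ms`` (edges truncated to the available bins)."""
    cfg = config or AnalysisConfig()
    if not responding:
        raise ValueError("no responding channels")
    network = np.sum([psths[e].counts for e in responding], axis=0)
    w = max(1, round(cfg.smooth_bin_ms / cfg.psth_bin_ms))
    kernel = np.ones(w)
    sm = np.convolve(network, kernel, mode="same")
    norm = np.convolve(np.ones_like(network), kernel, mode="same")
    return sm / norm


def split_from_smoothed(smoothed: np.ndarray, stim_electrode: str = "",
                        config: AnalysisConfig | None = None) -> EarlyLateSplit:
    """Early/late separation on an already-smoothed network PSTH."""
    cfg = config or AnalysisConfig()
    bin_ms = cfg.psth_bin_ms
    centers = (np.arange(smoothed.size) + 0.5) * bin_ms
    prominence = cfg.peak_prominence_frac * float(smoothed.max()) \
        if smoothed.max() > 0 else None
    # pad one zero per side so a peak near the window edge keeps its
    # full prominence (there is no evoked response outside the window)
    padded = np.concatenate(([0.0], smoothed, [0.0]))
    peaks, _ = find_peaks(padded, prominence=prominence)
    peaks = peaks - 1

    early = [p for p in peaks if centers[p] <= cfg.early_peak_max_ms]
    late = [p for p in peaks if cfg.early_peak_max_ms < centers[p] <= cfg.psth_window_ms]
    if not early or not late:
        return EarlyLateSplit(stim_electrode, None, None, None, None,
                              accepted=False, smoothed=smoothed)
    # highest peak in each phase
    p1 = max(early, key=lambda p: smoothed[p])
    p2 = max(late, key=lambda p: smoothed[p])
    between = smoothed[p1 + 1:p2]
    if between.size == 0:
        return EarlyLateSplit(stim_electrode, float(centers[p1]), float(centers[p2]),
                              None, None, accepted=False, smoothed=smoothed)
    imin = p1 + 1 + int(np.argmin(between))
    s = separation_index(float(smoothed[p1]), float(smoothed[p2]),
                         float(smoothed[imin]))
    accepted = s >= cfg.separation_threshold
    return EarlyLateSplit(
        stim_electrode=stim_electrode,
        x_peak1_ms=float(centers[p1]),
        x_peak2_ms=float(centers[p2]),
        x_min_ms=float(centers[imin]),
        s=float(s),
        accepted=accepted,
        smoothed=smoothed,
    )


def split_early_late(psths: dict[str, PSTH], responding: list[str],
                     config: AnalysisConfig | None = None) -> EarlyLateSplit:
    """Adaptive early/late separation for one stimulating electrode."""
    cfg = config or AnalysisConfig()
    stim = next(iter(psths.values())).stim_electrode if psths else ""
    sm = smooth_network_psth(psths, responding, cfg)
    return split_from_smoothed(sm, stim_electrode=stim, config=cfg)


def extract_evoked_patterns(sts: SpikeTrainSet, session: StimulationSession,
                            split: EarlyLateSplit, active_channels: list[str],
                            isi_thresholds: dict[str, float],
                            config: AnalysisConfig | None = None,
                            ) -> list[EvokedPattern]:
    """Evoked NB patterns from the late response window of each trial.

    For every pulse, single-channel burst detection is run on the spikes
    falling in (x_min, 500] ms after the pulse; a trial yields a pattern
    only when bursts occur on at least ``nb_participation_frac`` of the
    active channels.  Delays are measured from stimulus onset.
    """
    cfg = config or AnalysisConfig()
    if not split.accepted or split.x_min_ms is None:
        raise ValueError("early/late split not accepted for this session")
    min_ch = math.ceil(cfg.nb_participation_frac * len(active_channels))
    out = []
    for k, t0 in enumerate(np.asarray(session.onsets_ms, dtype=float)):
        first_spike = {}
        for e in active_channels:
            t = sts.spikes.get(e)
            if t is None or t.size == 0:
                continue
            rel = t[(t > t0 + split.x_min_ms) & (t <= t0 + cfg.psth_window_ms)] - t0
            if rel.size == 0:
                continue
            bursts = detect_bursts(rel, isi_thresholds.get(e, cfg.fallback_isi_ms),
                                   cfg.min_spikes_per_burst, electrode=e)
            if bursts:
                first_spike[e] = float(bursts[0].spike_times[0])
        if len(first_spike) < min_ch:
            continue
        order = sorted(first_spike, key=lambda e: (first_spike[e], e))
        out.append(EvokedPattern(stim_electrode=session.electrode, trial=k,
                                 order=order, delays=first_spike))
    return out


def response_reliability(n_patterns: int, n_pulses: int,
                         config: AnalysisConfig | None = None,
                         ) -> tuple[float, bool]:
    """Fraction of pulses that evoked an NB, and whether the stimulation
    site is kept (at least 50% of trials, inclusive)."""
    cfg = config or AnalysisConfig()
    if n_pulses < 1:
        raise ValueError("n_pulses must be >= 1")
    frac = n_patterns / n_pulses
    return frac, frac >= cfg.min_response_frac
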