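"""Synthetic MEA recordings with planted ground truth.

Generates spontaneous and stimulated spike data with the statistical
features the analysis chain assumes: a pool of ~50 active channels with
lognormal background rates, network bursts arriving as a gamma-renewal
process at a configurable rate, a small set of recurring propagation
templates each led by a few planted leader electrodes, and stimulation
sessions (pulse trains at 0.2 Hz) with an early direct response on
channels near the stimulation site followed by a late network burst
instantiated from the template whose leaders are geometrically closest
to the stimulated electrode.

Every simulation returns a :class:`GroundTruth` recording the template,
leader and realized activation order of each event, so that detection,
clustering and evaluation can be scored against known answers.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .io import SpikeTrainSet, StimulationLog, StimulationSession
from .layout import MEALayout
from .rng import substream

#: spike-time resolution (10 kHz acquisition)
TIME_RESOLUTION_MS = 0.1
#: refractory floor between consecutive network-burst onsets
NB_REFRACTORY_MS = 300.0
#: background spiking is suppressed in this window before each NB onset
#: (cultured networks are briefly quiescent before a burst ignites)
PRE_NB_QUIET_MS = 200.0
#: inter-pulse interval of the stimulation protocol
PULSE_PERIOD_MS = 5000.0


@dataclass
class PropagationTemplate:
    """One recurring spatiotemporal activation motif.

    ``order`` lists member electrodes in canonical activation order;
    ``delays`` are the matching nominal activation delays (ms, first
    entry 0).  On each instantiation a leader is drawn from
    ``leader_pool`` and moved to the front; the positional delays are
    then applied to the reordered sequence, so different leaders share
    the same propagation tail.
    """

    id: int
    order: list[str]
    delays: list[float]
    leader_pool: dict[str, float]
    participation_prob: dict[str, float]
    jitter_sd_ms: float

    def __post_init__(self) -> None:
        if len(self.order) != len(self.delays):
            raise ValueError("order and delays must have equal length")
        if any(d2 < d1 for d1, d2 in zip(self.delays, self.delays[1:])):
            raise ValueError("delays must be non-decreasing")
        if self.delays and self.delays[0] != 0:
            raise ValueError("leader delay must be 0")
        if not set(self.leader_pool) <= set(self.order):
            raise ValueError("leader pool must be a subset of template electrodes")
        total = sum(self.leader_pool.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("leader pool probabilities must sum to 1")


@dataclass
class NBRecord:
    onset_ms: float
    template_id: int
    leader: str
    order: list[str]
    times_ms: dict[str, float]


@dataclass
class StimulusRecord:
    pulse: int
    onset_ms: float
    responded: bool
    template_id: int | None = None
    late_onset_ms: float | None = None
    early: dict[str, float] = field(default_factory=dict)


@dataclass
class GroundTruth:
    templates: list[PropagationTemplate] = field(default_factory=list)
    nbs: list[NBRecord] = field(default_factory=list)
    stimuli: list[StimulusRecord] = field(default_factory=list)
    base_rates: dict[str, float] = field(default_factory=dict)


def generate_templates(layout: MEALayout, k: int, spread_ms: float = 60.0,
                       seed: int = 0, n_leaders: int = 1,
                       support_frac: float = 0.9,
                       participation: float = 0.9,
                       jitter_sd_ms: float = 5.0,
                       disjoint: bool = False) -> list[PropagationTemplate]:
    """Plant ``k`` propagation templates with distinct leader pools.

    In the default mode every template spans ``support_frac`` of the
    recording electrodes (supports overlap heavily, orders differ); in
    ``disjoint`` mode supports are partitioned so any two templates
    share at most ~10% of their members — a negative control in which
    different templates involve different parts of the array.

    Non-leader delays start at 15% of ``spread_ms`` so that under
    moderate jitter the planted leader remains the first firing
    electrode in almost every event.
    """
    if not 1 <= k <= 10:
        raise ValueError("k must be in [1, 10]")
    if not 1 <= n_leaders <= 3:
        raise ValueError("n_leaders must be in [1, 3]")
    rng = substream(seed, "templates")
    electrodes = list(layout.recording_electrodes)
    if k * n_leaders > len(electrodes):
        raise ValueError("k exceeds available electrodes")

    # distinct (disjoint) leader pools
    leader_draw = list(rng.choice(electrodes, size=k * n_leaders, replace=False))
    pools = [leader_draw[i * n_leaders:(i + 1) * n_leaders] for i in range(k)]

    if disjoint:
        rest = [e for e in electrodes if e not in leader_draw]
        rng.shuffle(rest)
        per_template = len(rest) // k
        # keep a small shared support so permutation nulls stay informative
        shared_n = max(1, round(0.1 * per_template))
        shared, rest = rest[:shared_n], rest[shared_n:]
        c = len(rest) // k
        supports = [pools[i] + rest[i * c:(i + 1) * c] + shared for i in range(k)]
    else:
        n_support = max(n_leaders + 2, round(support_frac * len(electrodes)))
        supports = []
        for i in range(k):
            others = [e for e in electrodes if e not in pools[i]]
            n_pick = min(n_support - n_leaders, len(others))
            picked = list(rng.choice(others, size=n_pick, replace=False))
            supports.append(pools[i] + picked)

    templates = []
    for i in range(k):
        support = supports[i]
        followers = [e for e in support if e not in pools[i]]
        rng.shuffle(followers)
        order = pools[i] + followers
        n = len(order)
        lead_delays = np.sort(rng.uniform(2.0, 0.15 * spread_ms, n_leaders - 1)) \
            if n_leaders > 1 else np.empty(0)
        follower_delays = np.sort(rng.uniform(0.15 * spread_ms, spread_ms,
                                              n - n_leaders))
        delays = _distinct_on_grid(np.concatenate(
            ([0.0], lead_delays, follower_delays)))
        weights = np.array([1.0 / (j + 1) for j in range(n_leaders)])
        weights /= weights.sum()
        pool = {e: float(w) for e, w in zip(pools[i], weights)}
        part = {e: (1.0 if e in pool else participation) for e in order}
        templates.append(PropagationTemplate(
            id=i, order=order, delays=delays, leader_pool=pool,
            participation_prob=part, jitter_sd_ms=jitter_sd_ms))
    return templates


def _distinct_on_grid(delays: np.ndarray, step: float = 0.2) -> list[float]:
    """Sorted delays, strictly separated on the 0.1 ms acquisition grid so
    nominal activation times never collide after rounding."""
    v = np.sort(np.asarray(delays, dtype=float))
    for i in range(1, v.size):
        v[i] = max(v[i], v[i - 1] + step)
    return [float(x) for x in np.round(v / TIME_RESOLUTION_MS) * TIME_RESOLUTION_MS]


def _draw_base_rates(layout: MEALayout, rng: np.random.Generator,
                     median_hz: float = 0.5, sigma: float = 1.0) -> dict[str, float]:
    """Lognormal background rates (pseudo-lognormal overall rate profile)."""
    rates = rng.lognormal(mean=np.log(median_hz), sigma=sigma,
                          size=len(layout.recording_electrodes))
    return {e: float(r) for e, r in zip(layout.recording_electrodes, rates)}


def _instantiate_nb(template: PropagationTemplate, onset_ms: float,
                    rng: np.random.Generator,
                    leader: str | None = None) -> tuple[str, dict[str, float]]:
    """Realized activation times of one NB (leader choice, dropout, jitter)."""
    if leader is None:
        pool = list(template.leader_pool)
        probs = np.array([template.leader_pool[e] for e in pool])
        leader = str(rng.choice(pool, p=probs / probs.sum()))
    order = [leader] + [e for e in template.order if e != leader]
    times = {}
    for pos, e in enumerate(order):
        if e != leader and rng.random() > template.participation_prob.get(e, 1.0):
            continue
        jit = rng.normal(0.0, template.jitter_sd_ms) if pos > 0 else 0.0
        times[e] = onset_ms + template.delays[pos] + jit
    return leader, times


def _burst_spikes(t_start: float, rng: np.random.Generator,
                  mean_isi_ms: float = 10.0,
                  n_range: tuple[int, int] = (6, 24)) -> np.ndarray:
    n = int(rng.integers(n_range[0], n_range[1] + 1))
    isis = np.maximum(rng.exponential(mean_isi_ms, n - 1), 0.5)
    return t_start + np.concatenate(([0.0], np.cumsum(isis)))


def _background(rate_hz: float, duration_ms: float,
                rng: np.random.Generator) -> np.ndarray:
    n = rng.poisson(rate_hz * duration_ms / 1000.0)
    return rng.uniform(0.0, duration_ms, n)


def _suppress_before(times: np.ndarray, onsets: np.ndarray,
                     quiet_ms: float = PRE_NB_QUIET_MS) -> np.ndarray:
    """Drop background spikes inside the quiescent window before each
    NB onset (pre-burst network silence)."""
    if times.size == 0 or onsets.size == 0:
        return times
    keep = np.ones(times.size, dtype=bool)
    for t in onsets:
        keep &= ~((times > t - quiet_ms) & (times <= t))
    return times[keep]


def _finalize(spike_lists: dict[str, list[np.ndarray]], layout: MEALayout,
              duration_ms: float, meta: dict) -> SpikeTrainSet:
    spikes = {}
    for e in layout.recording_electrodes:
        parts = spike_lists.get(e, [])
        if parts:
            t = np.concatenate(parts)
            t = t[(t >= 0) & (t <= duration_ms)]
            t = np.unique(np.round(t / TIME_RESOLUTION_MS) * TIME_RESOLUTION_MS)
        else:
            t = np.empty(0)
        spikes[e] = t
    return SpikeTrainSet(spikes=spikes, duration_ms=duration_ms, meta=meta)


def _record_nb(template: PropagationTemplate, leader: str,
               times: dict[str, float], onset_ms: float) -> NBRecord:
    # times on the acquisition grid, ties by label: matches what a
    # detector sees in the emitted spike trains
    snapped = {e: float(np.round(t / TIME_RESOLUTION_MS) * TIME_RESOLUTION_MS)
               for e, t in times.items()}
    order = sorted(snapped, key=lambda e: (snapped[e], e))
    return NBRecord(onset_ms=onset_ms, template_id=template.id,
                    leader=order[0], order=order, times_ms=snapped)


def simulate_spontaneous(templates: list[PropagationTemplate],
                         layout: MEALayout,
                         duration_ms: float = 600_000.0,
                         nb_rate_per_min: float = 19.3,
                         base_rates: dict[str, float] | None = None,
                         seed: int = 0,
                         ) -> tuple[SpikeTrainSet, GroundTruth]:
    """Spontaneous recording: renewal-process NBs over background spiking.

    NB onsets follow a gamma(shape 2) renewal process with a 300 ms
    refractory floor and mean interval 60000/``nb_rate_per_min`` ms; each
    NB instantiates a uniformly chosen template.  Background activity is
    per-electrode Poisson at ``base_rates`` (drawn lognormal when not
    supplied).
    """
    if not 1.0 <= nb_rate_per_min <= 60.0:
        raise ValueError("nb_rate_per_min must be in [1, 60]")
    mean_interval = 60_000.0 / nb_rate_per_min
    if duration_ms < mean_interval:
        raise ValueError("duration too short for one NB at the requested rate")
    rng = substream(seed, "spontaneous")
    if base_rates is None:
        base_rates = _draw_base_rates(layout, rng)
    gt = GroundTruth(templates=list(templates), base_rates=dict(base_rates))
    background = {e: _background(r, duration_ms, rng)
                  for e, r in base_rates.items()}
    spike_lists: dict[str, list[np.ndarray]] = {e: [] for e in base_rates}

    # NB onsets: shifted-gamma renewal
    scale = max((mean_interval - NB_REFRACTORY_MS) / 2.0, 1.0)
    margin = max(t.delays[-1] for t in templates) + 200.0
    t = float(rng.uniform(0.0, mean_interval))
    while t + margin < duration_ms:
        template = templates[int(rng.integers(len(templates)))]
        leader, times = _instantiate_nb(template, t, rng)
        for e, act in times.items():
            spike_lists.setdefault(e, []).append(_burst_spikes(act, rng))
        gt.nbs.append(_record_nb(template, leader, times, t))
        t += NB_REFRACTORY_MS + float(rng.gamma(2.0, scale))

    onsets = np.array([nb.onset_ms for nb in gt.nbs])
    for e, bg in background.items():
        spike_lists.setdefault(e, []).append(_suppress_before(bg, onsets))

    sts = _finalize(spike_lists, layout, duration_ms,
                    meta={"phase": "spontaneous", "seed": seed})
    return sts, gt


def closest_template(templates: list[PropagationTemplate], stim_electrode: str,
                     layout: MEALayout) -> PropagationTemplate:
    """Template whose leader pool is geometrically closest to the
    stimulated electrode (ties toward the lower template id)."""
    def pool_distance(t: PropagationTemplate) -> float:
        return min(layout.distance_um(stim_electrode, e) for e in t.leader_pool)
    return min(templates, key=lambda t: (pool_distance(t), t.id))


def simulate_stimulated_session(templates: list[PropagationTemplate],
                                layout: MEALayout,
                                stim_electrode: str,
                                n_pulses: int = 100,
                                response_prob: float = 0.8,
                                early_channels: list[str] | None = None,
                                early_latency_range: tuple[float, float] = (2.0, 20.0),
                                late_onset_range: tuple[float, float] = (40.0, 150.0),
                                early_reliability: float = 0.9,
                                base_rates: dict[str, float] | None = None,
                                duration_ms: float | None = None,
                                first_pulse_ms: float = 1000.0,
                                seed: int = 0,
                                ) -> tuple[SpikeTrainSet, StimulationLog, GroundTruth]:
    """One stimulation session: ``n_pulses`` pulses at 0.2 Hz.

    Each pulse responds with probability ``response_prob``: early spikes
    on ``early_channels`` (default: the stimulated electrode's grid
    neighborhood plus the nearest planted leader) at short uniform
    latencies, followed by a late NB instantiated from the template
    whose leader pool is closest to the stimulation site.
    """
    if stim_electrode not in layout:
        raise ValueError(f"unknown stimulated electrode {stim_electrode!r}")
    if n_pulses < 1:
        raise ValueError("n_pulses must be >= 1")
    needed = first_pulse_ms + n_pulses * PULSE_PERIOD_MS
    if duration_ms is None:
        duration_ms = needed
    elif duration_ms < needed:
        raise ValueError("duration too short for the requested pulse count")

    rng = substream(seed, "stimulated", stim_electrode)
    if base_rates is None:
        base_rates = _draw_base_rates(layout, rng)
    template = closest_template(templates, stim_electrode, layout)
    if early_channels is None:
        nearest_leader = min(template.leader_pool,
                             key=lambda e: (layout.distance_um(stim_electrode, e), e))
        early_channels = sorted(set(layout.neighbors(stim_electrode)) |
                                {nearest_leader})

    gt = GroundTruth(templates=list(templates), base_rates=dict(base_rates))
    background = {e: _background(r, duration_ms, rng)
                  for e, r in base_rates.items()}
    spike_lists: dict[str, list[np.ndarray]] = {e: [] for e in base_rates}

    onsets = first_pulse_ms + PULSE_PERIOD_MS * np.arange(n_pulses)
    for k, t0 in enumerate(onsets):
        if rng.random() >= response_prob:
            gt.stimuli.append(StimulusRecord(pulse=k, onset_ms=float(t0),
                                             responded=False))
            continue
        early = {}
        for e in early_channels:
            if rng.random() < early_reliability:
                lat = float(rng.uniform(*early_latency_range))
                early[e] = lat
                spike_lists.setdefault(e, []).append(
                    t0 + lat + np.array([0.0, float(rng.uniform(1.0, 3.0))]))
        late_onset = float(rng.uniform(*late_onset_range))
        leader, times = _instantiate_nb(template, t0 + late_onset, rng)
        for e, act in times.items():
            spike_lists.setdefault(e, []).append(_burst_spikes(act, rng))
        rec = _record_nb(template, leader, times, t0 + late_onset)
        gt.nbs.append(rec)
        gt.stimuli.append(StimulusRecord(
            pulse=k, onset_ms=float(t0), responded=True,
            template_id=template.id, late_onset_ms=late_onset, early=early))

    nb_onsets = np.array([nb.onset_ms for nb in gt.nbs])
    for e, bg in background.items():
        spike_lists.setdefault(e, []).append(_suppress_before(bg, nb_onsets))

    sts = _finalize(spike_lists, layout, duration_ms,
                    meta={"phase": "stimulated", "stim_electrode": stim_electrode,
                          "seed": seed})
    slog = StimulationLog(sessions=[StimulationSession(
        electrode=stim_electrode, onsets_ms=onsets.astype(float))])
    return sts, slog, gt


def export_ground_truth(gt: GroundTruth, path: str | Path) -> None:
    Path(path).write_text(json.dumps(asdict(gt), indent=1, sort_keys=True))


def load_ground_truth(path: str | Path) -> GroundTruth:
    data = json.loads(Path(path).read_text())
    return GroundTruth(
        templates=[PropagationTemplate(**t) for t in data["templates"]],
        nbs=[NBRecord(**r) for r in data["nbs"]],
        stimuli=[StimulusRecord(**s) for s in data["stimuli"]],
        base_rates=data["base_rates"],
    )
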