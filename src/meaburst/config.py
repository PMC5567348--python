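"""Analysis configuration.

Every threshold used by the pipeline lives here, with the defaults used
throughout: burst-detection internals (logISI histogram binning, void
parameter), network-burst participation, major-leader cutoff, PSTH
windowing and early/late separation, shuffle-null sizes and significance
levels.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path


@dataclass
class AnalysisConfig:
    # -- channel activity -------------------------------------------------
    #: channels with firing rate strictly above this (spikes/s) are "active"
    active_rate_min: float = 0.1

    # -- single-channel burst detection (logISI) --------------------------
    min_spikes_per_burst: int = 3
    logisi_bins_per_decade: int = 10
    logisi_smooth_bins: int = 3
    #: the intra-burst peak of the logISI histogram must lie below this ISI
    intra_burst_peak_max_ms: float = 100.0
    #: minimum valley depth (void parameter) separating the two peaks
    void_threshold: float = 0.7
    #: ISI threshold used when a channel's logISI histogram yields none
    fallback_isi_ms: float = 100.0
    #: logISI histogram peaks need this prominence (fraction of max)
    logisi_peak_prominence_frac: float = 0.05
    #: burst detection never uses an ISI threshold above this cap, even
    #: when the logISI valley lies higher (intra-burst ISIs are short)
    max_isi_threshold_ms: float = 100.0

    # -- network bursts ---------------------------------------------------
    #: an NB involves at least this fraction of active channels
    nb_participation_frac: float = 0.20
    #: single-channel bursts are chained when overlapping or closer than this
    nb_chain_gap_ms: float = 100.0

    # -- leadership -------------------------------------------------------
    #: major leader = electrode leading at least this fraction of all NBs
    ml_leadership_frac: float = 0.04

    # -- PSTH / evoked responses ------------------------------------------
    psth_window_ms: float = 500.0
    psth_bin_ms: float = 2.0
    #: responding channel = PSTH area (mean spikes per stimulus) >= this
    psth_area_min: float = 1.0
    #: moving-average window for the network PSTH
    smooth_bin_ms: float = 20.0
    #: the early peak must occur within this many ms of the stimulus
    early_peak_max_ms: float = 50.0
    #: minimum separation index s_j to accept an early/late split
    separation_threshold: float = 0.3
    #: peak prominence as a fraction of the global smoothed-PSTH maximum
    peak_prominence_frac: float = 0.05
    #: keep a stimulation site only if >= this fraction of pulses evoke an NB
    min_response_frac: float = 0.50

    # -- pattern distances ------------------------------------------------
    n_shuffles: int = 200
    distance_alpha: float = 0.05
    #: at most this many spontaneous NBs enter the distance matrix
    max_spont_nbs: int = 2500
    #: reuse shuffle nulls across pairs with the same length/overlap profile
    cache_nulls: bool = True
    #: cached nulls draw this many times n_shuffles samples: one cached
    #: null serves many pairs, so its estimation error is correlated
    #: across pairs and is kept small by a larger draw
    cache_null_boost: int = 10
    #: shuffle both strings of a pair (False: only the second)
    shuffle_both: bool = True

    # -- clustering -------------------------------------------------------
    min_core_size: int = 5
    #: a core candidate must be significantly similar to at least this
    #: fraction of the other candidates (guards cores against
    #: chance-level links to the seed)
    core_consistency_frac: float = 0.5
    #: template-matching statistic: "median" distance to core members or
    #: "centroid" distance to the core seed pattern
    template_match_stat: str = "median"
    #: delay-map electrodes present in fewer than this fraction of cluster
    #: members are flagged low-support
    delay_map_support_frac: float = 0.5

    # -- evaluation -------------------------------------------------------
    #: evoked patterns are "similar to spontaneous" if the best
    #: spontaneous/evoked similar-pair ratio strictly exceeds this
    similarity_frac_threshold: float = 0.10
    shuffle_control_repeats: int = 100
    normality_alpha: float = 0.01

    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "active_rate_min",
            "nb_participation_frac",
            "ml_leadership_frac",
            "min_response_frac",
            "distance_alpha",
            "similarity_frac_threshold",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_shuffles < 1:
            raise ValueError("n_shuffles must be >= 1")
        n_bins = self.psth_window_ms / self.psth_bin_ms
        if abs(n_bins - round(n_bins)) > 1e-9:
            raise ValueError("psth_window_ms must be divisible by psth_bin_ms")

    @property
    def n_psth_bins(self) -> int:
        return round(self.psth_window_ms / self.psth_bin_ms)

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True))

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        data = json.loads(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**data)

    def replace(self, **kwargs) -> "AnalysisConfig":
        return dataclasses.replace(self, **kwargs)
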