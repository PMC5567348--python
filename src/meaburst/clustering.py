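"""Unsupervised clustering of activation patterns.

Two-stage procedure over a normalized distance matrix.  Stage 1 (core
finding, after Raichman & Ben-Jacob's correlated-ensemble idea): the
pattern with the most significant neighbors (normalized distance below
alpha) seeds a core made of itself plus those neighbors; the core is
kept if large enough, its members are removed, and the search repeats.
Stage 2 (template matching): each leftover pattern is assigned to the
core with the smallest median distance to core members, provided that
median is itself significant; everything else is discarded as
unclassified and excluded from downstream ratios.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .config import AnalysisConfig
from .distance import DistanceMatrix

log = logging.getLogger("meaburst.clustering")

UNCLASSIFIED = "unclassified"


@dataclass
class ClusterSet:
    #: pattern id -> cluster label (int as str) or "unclassified"
    labels: dict[str, str]
    #: cluster label -> ids of the core members found in stage 1
    cores: dict[str, list[str]]
    #: cluster label -> all member ids (core + template-matched)
    members: dict[str, list[str]] = field(default_factory=dict)

    @property
    def n_clusters(self) -> int:
        return len(self.cores)

    def classified_ids(self) -> list[str]:
        return [i for i, c in self.labels.items() if c != UNCLASSIFIED]

    def unclassified_ids(self) -> list[str]:
        return [i for i, c in self.labels.items() if c == UNCLASSIFIED]


def find_cluster_cores(dm: DistanceMatrix,
                       config: AnalysisConfig | None = None) -> ClusterSet:
    """Greedy extraction of pattern cores from a distance matrix."""
    cfg = config or AnalysisConfig()
    alpha = cfg.distance_alpha
    n = len(dm.ids)
    sig = dm.values < alpha
    np.fill_diagonal(sig, False)
    remaining = np.ones(n, dtype=bool)
    cores: dict[str, list[str]] = {}
    labels = {i: UNCLASSIFIED for i in dm.ids}
    while True:
        counts = (sig & remaining).sum(axis=1)
        counts[~remaining] = -1
        seed = int(np.argmax(counts))  # ties: smallest index
        if counts[seed] < max(cfg.min_core_size - 1, 1):
            break
        cand = [seed] + [int(j) for j in np.flatnonzero(sig[seed] & remaining)
                         if j != seed]
        # consistency check: keep candidates significantly similar to a
        # majority of the candidate set, so sporadic chance-level links
        # to the seed cannot drag in members of other clusters
        cand_arr = np.array(cand)
        core_idx = [int(j) for j in cand
                    if sig[j, cand_arr].sum() >= cfg.core_consistency_frac
                    * (len(cand) - 1)]
        if seed not in core_idx:
            core_idx = [seed] + core_idx
        if len(core_idx) < cfg.min_core_size:
            remaining[seed] = False
            continue
        label = str(len(cores))
        cores[label] = [dm.ids[j] for j in sorted(core_idx)]
        for j in core_idx:
            labels[dm.ids[j]] = label
            remaining[j] = False
        if not remaining.any():
            break
    cs = ClusterSet(labels=labels, cores=cores)
    cs.members = {c: list(ids) for c, ids in cores.items()}
    return cs


def assign_by_template_matching(cs: ClusterSet, dm: DistanceMatrix,
                                config: AnalysisConfig | None = None) -> ClusterSet:
    """Assign leftover patterns to cores; unassignable ones stay
    unclassified and are discarded downstream."""
    cfg = config or AnalysisConfig()
    if not cs.cores:
        raise ValueError("no cores to match against")
    core_idx = {c: [dm.index(i) for i in ids] for c, ids in cs.cores.items()}
    for pid in cs.unclassified_ids():
        i = dm.index(pid)
        best, best_d = None, np.inf
        for c, idx in core_idx.items():
            if cfg.template_match_stat == "centroid":
                d = float(dm.values[i, idx[0]])
            else:
                d = float(np.median(dm.values[i, idx]))
            if d < best_d - 1e-15 or (abs(d - best_d) <= 1e-15 and best is not None
                                      and c < best):
                best, best_d = c, d
        if best is not None and best_d < cfg.distance_alpha:
            cs.labels[pid] = best
            cs.members.setdefault(best, []).append(pid)
    n_un = len(cs.unclassified_ids())
    if n_un:
        log.info("%d pattern(s) left unclassified and discarded", n_un)
    return cs


def cluster_patterns(dm: DistanceMatrix,
                     config: AnalysisConfig | None = None) -> ClusterSet:
    """Full two-stage clustering (core finding + template matching)."""
    cs = find_cluster_cores(dm, config)
    if cs.cores:
        cs = assign_by_template_matching(cs, dm, config)
    return cs


def cluster_delay_map(delay_dicts: list[dict[str, float]],
                      config: AnalysisConfig | None = None) -> dict[str, dict]:
    """Median per-electrode delay over the NBs of one cluster.

    ``delay_dicts``: one {electrode -> delay ms} per member NB, delays
    referenced to the leader (spontaneous) or to the stimulus onset
    (evoked).  Electrodes participating in fewer than half of the
    members are flagged low-support.
    """
    cfg = config or AnalysisConfig()
    if not delay_dicts:
        raise ValueError("empty cluster")
    n = len(delay_dicts)
    electrodes = sorted({e for d in delay_dicts for e in d})
    out = {}
    for e in electrodes:
        vals = [d[e] for d in delay_dicts if e in d]
        out[e] = {
            "median_delay_ms": float(np.median(vals)),
            "support": len(vals),
            "low_support": len(vals) < cfg.delay_map_support_frac * n,
        }
    return out
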