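"""Headline quantifications of pattern similarity.

Group-level similarity is measured as the ratio of significantly
similar pattern pairs (normalized distance below alpha) over all pairs,
within or between groupings (same vs different leader, cluster or
stimulation site).  Chance levels come from shuffle controls: the
symbol orders of the patterns are permuted, the ratio recomputed, and
the 95th percentile of the resulting null taken as the chance ceiling.

Spontaneous-vs-evoked similarity is summarized per stimulated channel
by the maximum cross-cluster ratio of similar pairs over spontaneous
clusters; channels whose maximum exceeds a conservative 10% threshold
are classed "similar to spontaneous".  Major-leader involvement links
the evoked dynamics back to the planted/endogenous leaders: relative
recruitment order in evoked patterns, normalized early-response PSTH
area, and geometric distance between leader and stimulation site.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .clustering import ClusterSet
from .config import AnalysisConfig
from .distance import DistanceMatrix, cross_distances
from .layout import MEALayout
from .rng import substream

log = logging.getLogger("meaburst.evaluate")


def similar_pair_ratio(dm: DistanceMatrix, group_a: list[str],
                       group_b: list[str] | None = None,
                       alpha: float = 0.05) -> float:
    """Fraction of significantly similar pairs.

    Within-group (``group_b`` None or identical): unordered pairs
    excluding self-pairs.  Between-group: all cross pairs.
    """
    if group_b is None or set(group_a) == set(group_b):
        ids = list(group_a)
        if len(ids) < 2:
            raise ValueError("need at least 2 patterns for within-group pairs")
        sub = dm.submatrix(ids, ids)
        iu = np.triu_indices(len(ids), k=1)
        vals = sub[iu]
    else:
        if not group_a or not group_b:
            raise ValueError("empty group")
        vals = dm.submatrix(group_a, group_b).ravel()
    if vals.size == 0:
        raise ValueError("no valid pairs")
    return float(np.mean(vals < alpha))


def cross_pair_ratio(cross: np.ndarray, alpha: float = 0.05) -> float:
    if cross.size == 0:
        raise ValueError("no valid pairs")
    return float(np.mean(cross < alpha))


def _shuffled(patterns: dict[str, list[str]],
              rng: np.random.Generator) -> dict[str, list[str]]:
    return {k: [v[i] for i in rng.permutation(len(v))]
            for k, v in patterns.items()}


def shuffle_control_cross(patterns_a: dict[str, list[str]],
                          patterns_b: dict[str, list[str]],
                          config: AnalysisConfig,
                          seed: int,
                          n_repeats: int | None = None) -> dict:
    """Null distribution of the cross similar-pair ratio under symbol-order
    shuffling of the first collection; returns the distribution and its
    95th percentile."""
    if len(patterns_a) < 1 or len(patterns_b) < 1:
        raise ValueError("need patterns on both sides")
    n_repeats = n_repeats or config.shuffle_control_repeats
    rng = substream(seed, "shuffle-control")
    from .distance import make_null_cache
    cache = make_null_cache(config, seed) if config.cache_nulls else None
    ratios = []
    for _ in range(n_repeats):
        shuf = _shuffled(patterns_a, rng)
        cross, _, _ = cross_distances(shuf, patterns_b, config, seed=seed,
                                      cache=cache)
        ratios.append(cross_pair_ratio(cross, config.distance_alpha))
    ratios = np.array(ratios)
    return {"ratios": ratios, "p95": float(np.percentile(ratios, 95))}


def shuffle_control_within(patterns: dict[str, list[str]],
                           groups: dict[str, list[str]],
                           config: AnalysisConfig,
                           seed: int,
                           n_repeats: int | None = None) -> dict:
    """Null distribution of the mean within-group similar-pair ratio under
    symbol-order shuffling of all patterns."""
    if len(patterns) < 2:
        raise ValueError("need at least 2 patterns")
    n_repeats = n_repeats or config.shuffle_control_repeats
    rng = substream(seed, "shuffle-control-within")
    from .distance import distance_matrix, make_null_cache
    cache = make_null_cache(config, seed) if config.cache_nulls else None
    ratios = []
    for _ in range(n_repeats):
        shuf = _shuffled(patterns, rng)
        dm = distance_matrix(shuf, config, seed=seed, cache=cache)
        per_group = [similar_pair_ratio(dm, ids, alpha=config.distance_alpha)
                     for ids in groups.values() if len(ids) >= 2]
        ratios.append(float(np.mean(per_group)) if per_group else 0.0)
    ratios = np.array(ratios)
    return {"ratios": ratios, "p95": float(np.percentile(ratios, 95))}


@dataclass
class SpontEvokedSimilarity:
    stim_electrode: str
    #: per spontaneous cluster: ratio of similar cross pairs
    ratios: dict[str, float]
    max_ratio: float
    matched_cluster: str | None
    #: "similar" iff max_ratio strictly exceeds the 10% threshold
    classification: str


def spont_evoked_similarity(spont_patterns: dict[str, list[str]],
                            spont_clusters: ClusterSet,
                            evoked_patterns: dict[str, list[str]],
                            stim_electrode: str,
                            config: AnalysisConfig,
                            seed: int) -> SpontEvokedSimilarity:
    """Best cross-cluster similarity of one stimulation site's evoked
    patterns against the spontaneous clusters."""
    if not spont_clusters.cores:
        raise ValueError("no spontaneous clusters")
    if not evoked_patterns:
        raise ValueError("no evoked patterns")
    ratios = {}
    for c, ids in spont_clusters.members.items():
        sub = {i: spont_patterns[i] for i in ids}
        cross, _, _ = cross_distances(sub, evoked_patterns, config, seed=seed)
        ratios[c] = cross_pair_ratio(cross, config.distance_alpha)
    matched = max(ratios, key=lambda c: (ratios[c], c))
    max_ratio = ratios[matched]
    similar = max_ratio > config.similarity_frac_threshold
    return SpontEvokedSimilarity(
        stim_electrode=stim_electrode,
        ratios=ratios,
        max_ratio=max_ratio,
        matched_cluster=matched if similar else None,
        classification="similar_to_spontaneous" if similar else "different",
    )


def reliability_correlation(cross_ratios: list[float],
                            within_ratios: list[float]) -> dict:
    """Pearson correlation between spontaneous/evoked cross-similarity and
    the mean within-cluster reliability, with a linear fit for plotting."""
    x = np.asarray(within_ratios, dtype=float)
    y = np.asarray(cross_ratios, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        return {"r": float("nan"), "p": float("nan"),
                "slope": float("nan"), "intercept": float("nan"),
                "error": "degenerate variance"}
    r, p = stats.pearsonr(x, y)
    slope, intercept = np.polyfit(x, y, 1)
    return {"r": float(r), "p": float(p),
            "slope": float(slope), "intercept": float(intercept)}


@dataclass
class MLInvolvement:
    stim_electrode: str
    ml: str
    #: median over trials of (rank - 1)/(n - 1); 0 = recruited first
    relative_order: float | None
    #: per-stim-site normalized PSTH area of the early response
    early_area_norm: float | None
    distance_um: float
    #: "matched" (leads the matched spontaneous cluster), "unmatched"
    #: (leads other clusters), or "no_match" (stim site classed different)
    category: str


def _cluster_leaders(spont_clusters: ClusterSet,
                     nb_leaders: dict[str, str]) -> dict[str, set[str]]:
    """Leaders of the NBs belonging to each spontaneous cluster."""
    out: dict[str, set[str]] = {c: set() for c in spont_clusters.members}
    for c, ids in spont_clusters.members.items():
        for i in ids:
            if i in nb_leaders:
                out[c].add(nb_leaders[i])
    return out


def ml_involvement_metrics(evoked_by_stim: dict[str, list],
                           similarity_by_stim: dict[str, SpontEvokedSimilarity],
                           early_areas_norm: dict[str, dict[str, float]],
                           major_leaders: list[str],
                           spont_clusters: ClusterSet,
                           nb_leaders: dict[str, str],
                           layout: MEALayout,
                           relative: bool = True) -> list[MLInvolvement]:
    """Per (stimulation site, major leader) involvement record.

    ``evoked_by_stim``: stim electrode -> list of EvokedPattern;
    ``early_areas_norm``: stim electrode -> per-channel normalized early
    PSTH area (per-stim-site view); ``nb_leaders``: spontaneous NB id ->
    leader electrode.
    """
    leaders_by_cluster = _cluster_leaders(spont_clusters, nb_leaders)
    records = []
    for stim, patterns in evoked_by_stim.items():
        sim = similarity_by_stim.get(stim)
        for ml in major_leaders:
            orders = []
            for pat in patterns:
                if ml in pat.order:
                    rank = pat.order.index(ml)
                    n = len(pat.order)
                    if relative:
                        orders.append(rank / (n - 1) if n > 1 else 0.0)
                    else:
                        orders.append(float(rank))
            if not orders:
                log.info("ML %s absent from all evoked patterns of stim %s", ml, stim)
            if sim is None or sim.classification == "different":
                category = "no_match"
            elif ml in leaders_by_cluster.get(sim.matched_cluster, set()):
                category = "matched"
            else:
                category = "unmatched"
            records.append(MLInvolvement(
                stim_electrode=stim,
                ml=ml,
                relative_order=float(np.median(orders)) if orders else None,
                early_area_norm=early_areas_norm.get(stim, {}).get(ml),
                distance_um=layout.distance_um(stim, ml),
                category=category,
            ))
    return records


def group_tests(samples: dict[str, np.ndarray],
                config: AnalysisConfig | None = None) -> dict:
    """Two-group or multi-group location comparison.

    Normality of every group is pre-checked (Kolmogorov-Smirnov against
    a fitted normal at the 0.01 level); if any group fails, the
    nonparametric path is taken (Mann-Whitney / Kruskal-Wallis with
    Bonferroni-corrected pairwise follow-ups), otherwise t-test/ANOVA.
    """
    cfg = config or AnalysisConfig()
    groups = {k: np.asarray(v, dtype=float) for k, v in samples.items()}
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for k, v in groups.items():
        if v.size < 2:
            raise ValueError(f"group {k!r} has fewer than 2 observations")

    def is_normal(v: np.ndarray) -> bool:
        if np.std(v) == 0:
            return False
        _, p = stats.kstest((v - v.mean()) / v.std(ddof=1), "norm")
        return p >= cfg.normality_alpha

    parametric = all(is_normal(v) for v in groups.values())
    names = list(groups)
    out: dict = {"parametric": parametric, "groups": names}
    if len(groups) == 2:
        a, b = groups[names[0]], groups[names[1]]
        if parametric:
            s, p = stats.ttest_ind(a, b, equal_var=False)
            out["test"] = "welch_t"
        else:
            s, p = stats.mannwhitneyu(a, b, alternative="two-sided")
            out["test"] = "mann_whitney"
        out["statistic"], out["p"] = float(s), float(p)
    else:
        if parametric:
            s, p = stats.f_oneway(*groups.values())
            out["test"] = "anova"
        else:
            s, p = stats.kruskal(*groups.values())
            out["test"] = "kruskal_wallis"
        out["statistic"], out["p"] = float(s), float(p)
        pairwise = {}
        n_pairs = len(names) * (len(names) - 1) // 2
        for ka, kb in itertools.combinations(names, 2):
            if parametric:
                _, pp = stats.ttest_ind(groups[ka], groups[kb], equal_var=False)
            else:
                _, pp = stats.mannwhitneyu(groups[ka], groups[kb],
                                           alternative="two-sided")
            pairwise[f"{ka}|{kb}"] = float(min(1.0, pp * n_pairs))
        out["pairwise_p_bonferroni"] = pairwise
    return out


def mds_embedding(dm: DistanceMatrix, dims: int = 2) -> dict:
    """Classical (Torgerson) metric multidimensional scaling.

    Double-centers the squared distance matrix, embeds on the top
    ``dims`` eigenvectors, and reports Kruskal stress-1 between input
    and embedded distances.
    """
    d = np.asarray(dm.values, dtype=float)
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    w, v = np.linalg.eigh(b)
    idx = np.argsort(w)[::-1][:dims]
    lam = np.clip(w[idx], 0.0, None)
    coords = v[:, idx] * np.sqrt(lam)
    emb = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
    iu = np.triu_indices(n, k=1)
    denom = float((d[iu] ** 2).sum())
    stress = float(np.sqrt(((d[iu] - emb[iu]) ** 2).sum() / denom)) if denom > 0 else 0.0
    return {"coordinates": coords, "ids": list(dm.ids), "stress": stress}
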