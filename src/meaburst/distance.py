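"""Shuffle-normalized Levenshtein distances between activation patterns.

An activation pattern is an ordered sequence of distinct electrode
labels.  The raw dissimilarity of two patterns is the unit-cost
Levenshtein edit distance (insertions, deletions, substitutions), which
is bounded by the longer pattern's length and therefore not comparable
across pairs of different lengths.  It is normalized by a permutation
null: both sequences are shuffled uniformly many times, the edit
distance recorded each time, and the normalized distance is the
fraction of null distances *strictly lower* than the observed one — an
empirical p-value in [0, 1].  Distances below a significance level
(default 0.05) mark pairs significantly more similar than chance.

The null distribution depends only on the two lengths and the number of
shared symbols, so nulls can be cached across pairs with the same
profile (validated by tests; disable with ``cache_nulls=False``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import numpy as np

from .config import AnalysisConfig
from .rng import substream

# printable, stable symbol alphabet for edlib (covers >64 electrodes)
_ALPHABET = [chr(c) for c in range(33, 33 + 96)]


def _encode(a, b) -> tuple[str, str]:
    table: dict[str, str] = {}
    for sym in list(a) + list(b):
        if sym not in table:
            table[sym] = _ALPHABET[len(table)]
    return "".join(table[s] for s in a), "".join(table[s] for s in b)


def edit_distance(a, b) -> int:
    """Unit-cost Levenshtein distance between two symbol sequences."""
    if len(a) == 0 or len(b) == 0:
        return max(len(a), len(b))
    ea, eb = _encode(a, b)
    return int(edlib.align(ea, eb, mode="NW", task="distance")["editDistance"])


def _null_distances(ea: str, eb: str, n_shuffles: int,
                    rng: np.random.Generator, shuffle_both: bool) -> np.ndarray:
    la, lb = len(ea), len(eb)
    aa = np.frombuffer(ea.encode(), dtype=np.uint8)
    bb = np.frombuffer(eb.encode(), dtype=np.uint8)
    out = np.empty(n_shuffles, dtype=np.int64)
    for i in range(n_shuffles):
        sa = rng.permutation(aa).tobytes().decode() if shuffle_both else ea
        sb = rng.permutation(bb).tobytes().decode()
        out[i] = edlib.align(sa, sb, mode="NW", task="distance")["editDistance"]
    return out


def pair_null_distribution(a, b, n_shuffles: int, seed: int,
                           shuffle_both: bool = True) -> np.ndarray:
    """Edit distances of ``n_shuffles`` independently shuffled copies of
    the pair — the chance distribution for patterns of these lengths."""
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    ea, eb = _encode(a, b)
    rng = substream(seed, "pair-null", ea, eb)
    return _null_distances(ea, eb, n_shuffles, rng, shuffle_both)


@dataclass
class PairDistance:
    raw: int
    normalized: float
    n_shuffles: int

    def significant(self, alpha: float = 0.05) -> bool:
        return self.normalized < alpha


class _NullCache:
    """Cache of null distributions keyed by (len_a, len_b, n_shared).

    Two patterns with the same length profile and shared-symbol count
    have identical null distributions up to relabeling, so one canonical
    null per profile suffices.
    """

    def __init__(self, n_shuffles: int, seed: int, shuffle_both: bool,
                 boost: int = 10):
        self.n_draws = n_shuffles * max(1, boost)
        self.seed = seed
        self.shuffle_both = shuffle_both
        self._store: dict[tuple[int, int, int], np.ndarray] = {}

    def get(self, la: int, lb: int, shared: int) -> np.ndarray:
        key = (la, lb, shared)
        if key not in self._store:
            a = [f"s{i}" for i in range(la)]
            b = [f"s{i}" for i in range(shared)] + \
                [f"t{i}" for i in range(lb - shared)]
            rng = substream(self.seed, "null-cache", la, lb, shared)
            ea, eb = _encode(a, b)
            self._store[key] = np.sort(
                _null_distances(ea, eb, self.n_draws, rng, self.shuffle_both))
        return self._store[key]


def normalized_distance(a, b, n_shuffles: int = 200, seed: int = 0,
                        shuffle_both: bool = True,
                        _cache: _NullCache | None = None) -> PairDistance:
    """Permutation-normalized distance between two patterns.

    ``normalized`` = fraction of null distances strictly lower than the
    raw distance (ties favor similarity).
    """
    raw = edit_distance(a, b)
    if _cache is not None:
        shared = len(set(a) & set(b))
        null = _cache.get(len(a), len(b), shared)
        lower = int(np.searchsorted(null, raw, side="left"))
        n_draws = int(null.size)
    else:
        null = pair_null_distribution(a, b, n_shuffles, seed, shuffle_both)
        lower = int(np.sum(null < raw))
        n_draws = n_shuffles
    return PairDistance(raw=raw, normalized=lower / n_draws,
                        n_shuffles=n_draws)


@dataclass
class DistanceMatrix:
    ids: list[str]
    values: np.ndarray
    #: per-pattern grouping metadata (leader, cluster, stim electrode, ...)
    meta: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("distance matrix shape does not match ids")
        self.values = v

    def index(self, pid: str) -> int:
        return self.ids.index(pid)

    def submatrix(self, ids_a: list[str], ids_b: list[str]) -> np.ndarray:
        ia = [self.index(i) for i in ids_a]
        ib = [self.index(i) for i in ids_b]
        return self.values[np.ix_(ia, ib)]

    def significance_mask(self, alpha: float = 0.05) -> np.ndarray:
        mask = self.values < alpha
        np.fill_diagonal(mask, False)
        return mask


def make_null_cache(config: AnalysisConfig, seed: int) -> "_NullCache":
    """A shareable null cache (e.g. across shuffle-control repeats)."""
    return _NullCache(config.n_shuffles, seed, config.shuffle_both,
                      config.cache_null_boost)


def distance_matrix(patterns: dict[str, list[str]],
                    config: AnalysisConfig | None = None,
                    seed: int | None = None,
                    meta: dict[str, dict] | None = None,
                    cache: "_NullCache | None" = None) -> DistanceMatrix:
    """Symmetric matrix of normalized distances over all pattern pairs.

    ``patterns`` maps pattern id -> activation order.  Insertion order of
    the dict fixes row order.
    """
    cfg = config or AnalysisConfig()
    if seed is None:
        seed = cfg.rng_seed
    ids = list(patterns)
    if len(ids) < 2:
        raise ValueError("need at least 2 patterns")
    if cache is None and cfg.cache_nulls:
        cache = make_null_cache(cfg, seed)
    n = len(ids)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            pd_ = normalized_distance(
                patterns[ids[i]], patterns[ids[j]],
                n_shuffles=cfg.n_shuffles,
                seed=seed if cache is not None else _pair_seed(seed, ids[i], ids[j]),
                shuffle_both=cfg.shuffle_both,
                _cache=cache,
            )
            values[i, j] = values[j, i] = pd_.normalized
    return DistanceMatrix(ids=ids, values=values, meta=meta or {})


def cross_distances(patterns_a: dict[str, list[str]],
                    patterns_b: dict[str, list[str]],
                    config: AnalysisConfig | None = None,
                    seed: int | None = None,
                    cache: "_NullCache | None" = None
                    ) -> tuple[np.ndarray, list[str], list[str]]:
    """Normalized distances between two pattern collections (rows: a)."""
    cfg = config or AnalysisConfig()
    if seed is None:
        seed = cfg.rng_seed
    ids_a, ids_b = list(patterns_a), list(patterns_b)
    if cache is None and cfg.cache_nulls:
        cache = make_null_cache(cfg, seed)
    out = np.zeros((len(ids_a), len(ids_b)))
    for i, ia in enumerate(ids_a):
        for j, ib in enumerate(ids_b):
            out[i, j] = normalized_distance(
                patterns_a[ia], patterns_b[ib],
                n_shuffles=cfg.n_shuffles,
                seed=seed if cache is not None else _pair_seed(seed, ia, ib),
                shuffle_both=cfg.shuffle_both,
                _cache=cache,
            ).normalized
    return out, ids_a, ids_b


def _pair_seed(seed: int, ia: str, ib: str) -> int:
    import zlib
    key = "|".join(sorted((ia, ib)))
    return (int(seed) ^ zlib.crc32(key.encode())) & 0x7FFFFFFF


def truncate_spontaneous(patterns: dict[str, list[str]],
                         max_n: int) -> dict[str, list[str]]:
    """Keep at most ``max_n`` patterns (the first in time, i.e. insertion
    order of the dict)."""
    if len(patterns) <= max_n:
        return patterns
    ids = list(patterns)[:max_n]
    return {i: patterns[i] for i in ids}
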