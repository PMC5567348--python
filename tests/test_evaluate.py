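import numpy as np
import pytest

from meaburst import AnalysisConfig
from meaburst.clustering import ClusterSet
from meaburst.distance import DistanceMatrix
from meaburst.evaluate import (MLInvolvement, group_tests, mds_embedding,
                               ml_involvement_metrics, reliability_correlation,
                               shuffle_control_cross, similar_pair_ratio,
                               spont_evoked_similarity)


def _dm(ids, values):
    return DistanceMatrix(ids=list(ids), values=np.asarray(values, float))


def block_dm(sizes, within=0.0, between=0.5):
    n = sum(sizes)
    v = np.full((n, n), between)
    start = 0
    for s in sizes:
        v[start:start + s, start:start + s] = within
        start += s
    np.fill_diagonal(v, 0.0)
    return _dm([f"p{i}" for i in range(n)], v)


class TestSimilarPairRatio:
    def test_identical_within_group_is_one(self):
        dm = block_dm([3])
        assert similar_pair_ratio(dm, dm.ids) == pytest.approx(1.0)

    def test_separated_between_groups_is_zero(self):
        dm = block_dm([3, 3])
        a, b = dm.ids[:3], dm.ids[3:]
        assert similar_pair_ratio(dm, a, b) == pytest.approx(0.0)

    def test_within_excludes_self_pairs(self):
        v = np.array([[0.0, 0.5], [0.5, 0.0]])
        dm = _dm(["a", "b"], v)
        assert similar_pair_ratio(dm, ["a", "b"]) == pytest.approx(0.0)

    def test_too_small_group_rejected(self):
        dm = block_dm([2])
        with pytest.raises(ValueError):
            similar_pair_ratio(dm, dm.ids[:1])


class TestShuffleControl:
    def test_identical_patterns_observed_far_above_null(self, fast_cfg):
        pats = {f"p{i}": [f"e{k}" for k in range(20)] for i in range(6)}
        other = dict(pats)
        ctrl = shuffle_control_cross(pats, other, fast_cfg, seed=1,
                                     n_repeats=10)
        assert ctrl["p95"] < 1.0
        # the un-shuffled observed ratio is 1.0 (identical patterns)
        assert 1.0 > ctrl["p95"]

    def test_single_repeat(self, fast_cfg):
        pats = {"a": list("ABCDEFGH"), "b": list("ABCDEFGH")}
        ctrl = shuffle_control_cross(pats, pats, fast_cfg, seed=2, n_repeats=1)
        assert ctrl["ratios"].shape == (1,)

    def test_seeded_rerun_identical(self, fast_cfg):
        pats = {f"p{i}": [f"e{k}" for k in range(15)] for i in range(4)}
        a = shuffle_control_cross(pats, pats, fast_cfg, seed=3, n_repeats=5)
        b = shuffle_control_cross(pats, pats, fast_cfg, seed=3, n_repeats=5)
        np.testing.assert_array_equal(a["ratios"], b["ratios"])


class TestSpontEvoked:
    def _clusters(self, ids):
        labels = {i: "0" for i in ids}
        return ClusterSet(labels=labels, cores={"0": list(ids)},
                          members={"0": list(ids)})

    def test_identical_evoked_cluster_classed_similar(self, fast_cfg):
        pat = [f"e{k}" for k in range(25)]
        spont = {f"s{i}": pat for i in range(6)}
        evoked = {f"v{i}": pat for i in range(4)}
        sim = spont_evoked_similarity(spont, self._clusters(spont), evoked,
                                      "32", fast_cfg, seed=4)
        assert sim.max_ratio == pytest.approx(1.0)
        assert sim.classification == "similar_to_spontaneous"
        assert sim.matched_cluster == "0"

    def test_reversed_orders_classed_different(self, fast_cfg, rng):
        # evoked orders are the reverses of the spontaneous ones: raw
        # distance is near-maximal, well inside the null bulk
        pat = [f"e{k}" for k in range(25)]
        spont = {f"s{i}": pat for i in range(6)}
        evoked = {f"v{i}": pat[::-1] for i in range(4)}
        sim = spont_evoked_similarity(spont, self._clusters(spont), evoked,
                                      "32", fast_cfg, seed=5)
        assert sim.classification == "different"
        assert sim.matched_cluster is None

    def test_empty_inputs_rejected(self, fast_cfg):
        spont = {"s0": list("ABCDE")}
        with pytest.raises(ValueError):
            spont_evoked_similarity(spont, self._clusters(spont), {}, "32",
                                    fast_cfg, seed=6)


class TestReliabilityCorrelation:
    def test_perfect_linear_relation(self):
        x = [0.1, 0.4, 0.8, 0.9]
        out = reliability_correlation(x, x)
        assert out["r"] == pytest.approx(1.0)
        assert out["slope"] == pytest.approx(1.0)

    def test_degenerate_variance_flagged(self):
        out = reliability_correlation([0.5, 0.5, 0.5], [0.1, 0.2, 0.3])
        assert "error" in out and np.isnan(out["r"])

    def test_independent_vectors_rarely_significant(self, rng):
        hits = 0
        for _ in range(20):
            x, y = rng.random(50), rng.random(50)
            out = reliability_correlation(list(x), list(y))
            hits += out["p"] < 0.01
        assert hits <= 1

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            reliability_correlation([0.1], [0.2])


class TestGroupTests:
    def test_identical_groups_not_significant(self, rng):
        a = rng.exponential(1.0, 100)
        out = group_tests({"g1": a, "g2": a.copy()})
        assert out["p"] > 0.05

    def test_shifted_groups_detected(self, rng):
        hits = 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            a = r.exponential(1.0, 100)
            b = r.exponential(1.0, 100) + 1.0
            out = group_tests({"g1": a, "g2": b})
            hits += out["p"] < 0.001
        assert hits >= 9

    def test_nonnormal_data_takes_nonparametric_path(self, rng):
        a = rng.exponential(1.0, 200)
        b = rng.exponential(1.0, 200)
        out = group_tests({"g1": a, "g2": b})
        assert not out["parametric"]
        assert out["test"] == "mann_whitney"

    def test_three_groups_omnibus_and_pairwise(self, rng):
        a = rng.exponential(1.0, 100)
        b = rng.exponential(1.0, 100)
        c = rng.exponential(1.0, 100) + 2.0
        out = group_tests({"a": a, "b": b, "c": c})
        assert out["p"] < 0.001
        pw = out["pairwise_p_bonferroni"]
        assert pw["a|c"] < 0.01 and pw["b|c"] < 0.01
        assert pw["a|b"] > 0.05

    def test_tiny_group_rejected(self):
        with pytest.raises(ValueError):
            group_tests({"a": np.array([1.0]), "b": np.array([1.0, 2.0])})


class TestMDS:
    def test_equidistant_triple_embeds_as_equilateral(self):
        v = np.full((3, 3), 0.8)
        np.fill_diagonal(v, 0.0)
        out = mds_embedding(_dm(list("abc"), v), dims=2)
        c = out["coordinates"]
        d = [np.linalg.norm(c[i] - c[j]) for i, j in ((0, 1), (0, 2), (1, 2))]
        np.testing.assert_allclose(d, d[0], rtol=1e-6)
        assert out["stress"] < 1e-6

    def test_identical_patterns_coincide(self):
        v = np.zeros((4, 4))
        out = mds_embedding(_dm(list("abcd"), v), dims=2)
        assert np.allclose(out["coordinates"], 0.0)

    def test_two_groups_visibly_separated(self):
        from sklearn.metrics import silhouette_score
        dm = block_dm([6, 6], within=0.05, between=0.9)
        out = mds_embedding(dm, dims=2)
        labels = [0] * 6 + [1] * 6
        assert silhouette_score(out["coordinates"], labels) > 0.5

    def test_asymmetric_rejected(self):
        v = np.array([[0.0, 0.1], [0.3, 0.0]])
        with pytest.raises(ValueError):
            mds_embedding(_dm(["a", "b"], v))


class TestMLInvolvement:
    def _pattern(self, order):
        class P:
            pass
        p = P()
        p.order = order
        return p

    def test_first_recruited_ml_has_zero_relative_order(self, layout):
        pats = [self._pattern(["44", "45", "46"]) for _ in range(3)]
        cs = ClusterSet(labels={"s0": "0"}, cores={"0": ["s0"]},
                        members={"0": ["s0"]})
        from meaburst.evaluate import SpontEvokedSimilarity
        sim = SpontEvokedSimilarity("54", {"0": 0.6}, 0.6, "0",
                                    "similar_to_spontaneous")
        recs = ml_involvement_metrics({"54": pats}, {"54": sim},
                                      {"54": {"44": 0.9}}, ["44"], cs,
                                      {"s0": "44"}, layout)
        assert len(recs) == 1
        r = recs[0]
        assert r.relative_order == pytest.approx(0.0)
        assert r.early_area_norm == pytest.approx(0.9)
        assert r.category == "matched"
        # horizontally adjacent electrodes are one pitch apart
        assert r.distance_um == pytest.approx(200.0)

    def test_absent_ml_yields_missing_order(self, layout):
        pats = [self._pattern(["45", "46"])]
        cs = ClusterSet(labels={}, cores={"0": []}, members={"0": []})
        from meaburst.evaluate import SpontEvokedSimilarity
        sim = SpontEvokedSimilarity("54", {"0": 0.05}, 0.05, None, "different")
        recs = ml_involvement_metrics({"54": pats}, {"54": sim}, {}, ["44"],
                                      cs, {}, layout)
        assert recs[0].relative_order is None
        assert recs[0].category == "no_match"
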