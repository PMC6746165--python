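"""tSNE embedding, elbow rule, k-means and subcluster bookkeeping."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score, silhouette_score

from plastphen.clustering import (
    SubclusterProfile,
    annotate_subclusters,
    choose_k,
    cluster_samples,
    embed_tsne,
    fit_elbow,
    kmeans_assign,
    subcluster_similarity,
    zscore_features,
)


def blobs(n_per, centers, sd=1.0, seed=0, dims=8):
    rng = np.random.default_rng(seed)
    rows, labels = [], []
    for i, c in enumerate(centers):
        center = np.zeros(dims)
        center[: len(c)] = c
        rows.append(rng.normal(center, sd, size=(n_per, dims)))
        labels += [i] * n_per
    x = np.vstack(rows)
    return pd.DataFrame(x, index=[f"s{i}" for i in range(len(x))]), np.array(labels)


class TestEmbedding:
    def test_deterministic_for_fixed_seed(self):
        x, _ = blobs(20, [(0,), (8,)], seed=1)
        e1 = embed_tsne(x, perplexity=10, seed=3)
        e2 = embed_tsne(x, perplexity=10, seed=3)
        pd.testing.assert_frame_equal(e1, e2)

    def test_centered_near_origin(self):
        x, _ = blobs(30, [(0,), (6,)], seed=2)
        emb = embed_tsne(x, perplexity=10, seed=0)
        np.testing.assert_allclose(emb.mean(axis=0), 0.0, atol=1e-5)

    def test_separated_blobs_stay_separable(self):
        x, labels = blobs(30, [(0, 0), (10, 0)], sd=1.0, seed=3)
        emb = embed_tsne(x, perplexity=12, seed=0)
        assert silhouette_score(emb, labels) > 0.5

    def test_perplexity_bound(self):
        x, _ = blobs(10, [(0,)], seed=4)
        with pytest.raises(ValueError, match="perplexity"):
            embed_tsne(x, perplexity=15, seed=0)

    def test_accepts_study_scale_input_at_default_perplexity(self):
        x, _ = blobs(55, [(0,), (5,)], seed=5)  # n=110 vs. default perplexity 15
        emb = embed_tsne(x.iloc[:109], seed=0)
        assert emb.shape == (109, 2)


class TestElbow:
    def test_exact_exponential_recovers_tau(self):
        wss = {k: 100.0 * np.exp(-k / 1.5) + 10.0 for k in range(2, 10)}
        res = fit_elbow(wss)
        assert res.tau == pytest.approx(1.5, abs=1e-6)
        assert res.k == 6

    def test_three_blob_elbow_agrees_with_second_difference_oracle(self):
        x, _ = blobs(25, [(0, 0), (9, 0), (0, 9)], sd=0.8, seed=6, dims=2)
        res = choose_k(x, k_range=range(2, 8), seed=0, restarts=10)
        ks = sorted(res.wss_by_k)
        ys = np.array([res.wss_by_k[k] for k in ks])
        oracle_k = ks[int(np.argmax(np.diff(ys, 2))) + 1]
        assert abs(res.k - oracle_k) <= 1

    def test_k_always_within_range(self):
        wss = {k: 1000.0 * np.exp(-k / 10.0) for k in range(2, 10)}  # tau=10 -> 4tau=40
        res = fit_elbow(wss, k_range=range(2, 10))
        assert 2 <= res.k <= 9

    def test_flat_curve_uses_fallback(self):
        wss = {k: 100.0 + 5 * ((k % 3) - 1) for k in range(2, 10)}  # non-decreasing
        res = fit_elbow(wss)
        assert res.k in range(2, 10)

    def test_k_range_must_stay_below_n(self):
        x, _ = blobs(3, [(0,)], seed=7)
        with pytest.raises(ValueError, match="below n"):
            choose_k(x, k_range=range(2, 10))


class TestKMeans:
    def test_k1_total_scatter_and_kn_zero(self):
        x, _ = blobs(10, [(0, 0), (5, 5)], seed=8)
        a1 = kmeans_assign(x, k=1, restarts=5)
        assert set(a1) == {1}
        an = kmeans_assign(x, k=len(x), restarts=5)
        assert len(set(an)) == len(x)

    def test_two_blob_recovery(self):
        x, labels = blobs(25, [(0, 0), (10, 0)], sd=1.0, seed=9)
        a = kmeans_assign(x, k=2, seed=0, restarts=10)
        assert adjusted_rand_score(labels, a) == 1.0

    def test_labels_canonicalized_by_size(self):
        x, _ = blobs(30, [(0, 0)], sd=0.5, seed=10)
        y, _ = blobs(10, [(20, 0)], sd=0.5, seed=11)
        y.index = [f"t{i}" for i in range(len(y))]
        both = pd.concat([x, y])
        a = kmeans_assign(both, k=2, seed=0, restarts=10)
        sizes = a.value_counts()
        assert sizes[1] == 30 and sizes[2] == 10

    def test_k_above_n_rejected(self):
        x, _ = blobs(5, [(0,)], seed=12)
        with pytest.raises(ValueError):
            kmeans_assign(x, k=6)


class TestSubclusterRule:
    def make(self, cluster_sizes, group_spec):
        """group_spec: list of (condition, cluster, n, region)."""
        rows = []
        assignments = []
        i = 0
        filled = {c: 0 for c in cluster_sizes}
        for cond, clu, n, region in group_spec:
            for _ in range(n):
                rows.append({"condition": cond, "region": region, "age_wks": 5.0, "animal_id": "a"})
                assignments.append(clu)
                filled[clu] += 1
                i += 1
        for clu, total in cluster_sizes.items():
            for _ in range(total - filled[clu]):
                rows.append({"condition": "filler", "region": "P", "age_wks": 5.0, "animal_id": "a"})
                assignments.append(clu)
                i += 1
        idx = [f"s{j}" for j in range(len(rows))]
        meta = pd.DataFrame(rows, index=idx)
        assign = pd.Series(assignments, index=idx)
        feats = pd.DataFrame(
            np.random.default_rng(0).normal(size=(len(rows), 8)),
            index=idx,
            columns=[f"f{j}" for j in range(8)],
        )
        return assign, meta, feats

    def test_exactly_20_percent_excluded(self):
        a, m, f = self.make({1: 10}, [("X", 1, 2, "C")])
        labels = [s.condition for s in annotate_subclusters(a, m, f)]
        assert "X" not in labels  # 2/10 = 20% exactly: strict inequality

    def test_just_over_20_percent_included(self):
        a, m, f = self.make({1: 39}, [("X", 1, 8, "C")])
        subs = annotate_subclusters(a, m, f)
        assert any(s.condition == "X" and s.n == 8 for s in subs)  # 8/39 = 20.5%

    def test_singleton_excluded(self):
        a, m, f = self.make({1: 2}, [("X", 1, 1, "C")])
        assert all(s.condition != "X" for s in annotate_subclusters(a, m, f))

    def test_region_subscripts(self):
        a, m, f = self.make(
            {1: 10}, [("X", 1, 2, "C"), ("X", 1, 2, "P")]
        )
        subs = [s for s in annotate_subclusters(a, m, f) if s.condition == "X"]
        assert subs[0].label == "X 1_CP"

    def test_full_region_span_has_no_subscript(self):
        a, m, f = self.make(
            {1: 10}, [("X", 1, 2, "C"), ("X", 1, 2, "P"), ("X", 1, 2, "M")]
        )
        subs = [s for s in annotate_subclusters(a, m, f) if s.condition == "X"]
        assert subs[0].label == "X 1"

    def test_pure_function_of_inputs(self):
        a, m, f = self.make({1: 20}, [("X", 1, 6, "C"), ("Y", 1, 5, "P")])
        s1 = annotate_subclusters(a, m, f)
        s2 = annotate_subclusters(a, m, f)
        assert [x.label for x in s1] == [x.label for x in s2]


def make_subcluster(label, vector):
    return SubclusterProfile(
        label=label,
        condition=label.split()[0],
        cluster=1,
        member_rows=["r1", "r2"],
        n=2,
        regions=("C",),
        mean_features=pd.Series(vector, index=[f"f{i}" for i in range(len(vector))]),
    )


class TestSubclusterSimilarity:
    def test_bonferroni_arithmetic(self):
        rng = np.random.default_rng(13)
        subs = [make_subcluster(f"S{i} 1", rng.normal(size=8)) for i in range(4)]
        sim = subcluster_similarity(subs)
        assert sim.n_pairs == 6
        assert sim.alpha_adjusted == pytest.approx(0.05 / 6)

    def test_thirteen_subclusters_give_78_pairs(self):
        rng = np.random.default_rng(14)
        subs = [make_subcluster(f"S{i} 1", rng.normal(size=8)) for i in range(13)]
        sim = subcluster_similarity(subs)
        assert sim.n_pairs == 78
        assert sim.alpha_adjusted == pytest.approx(0.05 / 78)
        assert sim.alpha_adjusted == pytest.approx(0.0006, abs=5e-5)

    def test_identical_vectors_correlate_perfectly_and_sit_adjacent(self):
        rng = np.random.default_rng(15)
        v = rng.normal(size=8)
        subs = [
            make_subcluster("A 1", v),
            make_subcluster("B 1", v),
            make_subcluster("C 1", rng.normal(size=8)),
        ]
        sim = subcluster_similarity(subs)
        assert sim.r.loc["A 1", "B 1"] == pytest.approx(1.0)
        ia, ib = sim.leaf_order.index("A 1"), sim.leaf_order.index("B 1")
        assert abs(ia - ib) == 1

    def test_requires_three_subclusters(self):
        rng = np.random.default_rng(16)
        subs = [make_subcluster(f"S{i} 1", rng.normal(size=8)) for i in range(2)]
        with pytest.raises(ValueError, match=">= 3"):
            subcluster_similarity(subs)

    def test_constant_vector_flagged(self):
        rng = np.random.default_rng(17)
        subs = [
            make_subcluster("A 1", np.ones(8)),
            make_subcluster("B 1", rng.normal(size=8)),
            make_subcluster("C 1", rng.normal(size=8)),
        ]
        with pytest.raises(ValueError, match="constant"):
            subcluster_similarity(subs)


class TestEndToEndRecovery:
    def test_planted_conditions_recovered(self, default_features, default_matrix, default_screening):
        res = cluster_samples(
            default_features[default_screening.clustering_features], seed=11, k=6
        )
        ari = adjusted_rand_score(default_matrix.metadata["condition"], res.assignments)
        assert ari > 0.6

    def test_elbow_matches_planted_group_count(self, default_features, default_screening):
        res = choose_k(
            zscore_features(default_features[default_screening.clustering_features]),
            seed=0,
            restarts=20,
        )
        assert abs(res.k - 6) <= 1  # six planted conditions
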