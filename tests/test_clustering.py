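"""Associative clustering: adjacency, equivalence classes, protocols."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import sparsesynergy as ss
from sparsesynergy.clustering import Q_COINCIDENT
from sparsesynergy.errors import InsufficientDataError, InvalidClusterError


def make_stats(label, x, y, sx=0.02, sy=0.02, rho=0.0, n=30):
    return ss.BurstStatistics(label=label, x=x, y=y, sx=sx, sy=sy, rho=rho, n=n)


def brute_force_q(a, b):
    """Enumerate all 16 vertex sign choices of the overlap criterion."""
    d = np.array([a.x - b.x, a.y - b.y])
    norm = np.hypot(*d)
    if norm == 0:
        return np.inf
    u = d / norm
    best = -np.inf
    for s1 in (1, -1):
        for s2 in (1, -1):
            for s3 in (1, -1):
                for s4 in (1, -1):
                    val = (np.dot([s1 * a.sx, s2 * a.sy], u)
                           + np.dot([s3 * b.sx, s4 * b.sy], u))
                    best = max(best, val)
    return best - norm


class TestScreenOutliers:
    def test_identical_points_keep_all(self):
        pts = np.tile([0.1, 0.3], (30, 1))
        kept, removed = ss.screen_outliers(pts)
        assert removed == 0 and kept.shape[0] == 30

    def test_gross_onset_outlier_removed(self):
        rng = np.random.default_rng(2)
        pts = np.column_stack([rng.normal(0.1, 0.01, 30),
                               rng.normal(0.3, 0.01, 30)])
        sd = pts[:, 0].std(ddof=1)
        outlier = np.array([[0.1 + 5 * sd + 0.05, 0.3]])
        all_pts = np.vstack([pts, outlier])
        kept, removed = ss.screen_outliers(all_pts)
        assert removed >= 1
        assert not np.any(np.all(np.isclose(kept, outlier), axis=1))
        # the planted point is the brute-force maximum deviation
        mean, s = all_pts.mean(0), all_pts.std(0, ddof=1)
        dev = np.abs(all_pts - mean) / s
        assert int(np.argmax(dev.max(axis=1))) == 30

    def test_symmetric_square_untouched(self):
        pts = np.array([[0.0, 0.0], [0.0, 1.0], [1.0, 0.0], [1.0, 1.0]])
        kept, removed = ss.screen_outliers(pts)
        assert removed == 0 and kept.shape[0] == 4

    def test_small_sample_returned_unchanged(self):
        pts = np.array([[0.0, 0.1], [10.0, 0.2]])
        kept, removed = ss.screen_outliers(pts)
        assert removed == 0 and kept.shape[0] == 2

    def test_removal_capped_at_ten_percent(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(0, 1, size=(40, 2))
        _, removed = ss.screen_outliers(pts)
        assert removed <= 4


class TestSummarizeBurst:
    def test_hand_computed_two_points(self):
        s = ss.summarize_burst("b", np.array([[0.0, 0.2], [0.1, 0.3]]))
        assert (s.x, s.y) == (0.05, 0.25)
        assert s.sx == pytest.approx(0.0707107, abs=1e-6)
        assert s.sy == pytest.approx(0.0707107, abs=1e-6)
        assert s.rho == pytest.approx(1.0)

    def test_degenerate_rho_is_zero(self):
        s = ss.summarize_burst("b", np.tile([0.1, 0.3], (5, 1)))
        assert s.sx == 0 and s.sy == 0 and s.rho == 0.0

    def test_translation_equivariance(self):
        rng = np.random.default_rng(4)
        pts = np.column_stack([rng.normal(0.1, 0.02, 20),
                               rng.normal(0.3, 0.02, 20)])
        a = ss.summarize_burst("a", pts)
        b = ss.summarize_burst("b", pts + 0.1)
        assert (b.x, b.y) == pytest.approx((a.x + 0.1, a.y + 0.1))
        assert (b.sx, b.sy, b.rho) == pytest.approx((a.sx, a.sy, a.rho))

    def test_single_trial_rejected(self):
        with pytest.raises(InsufficientDataError):
            ss.summarize_burst("b", np.array([[0.0, 0.2]]))


class TestAdjacencyQ:
    def test_separated_rectangles_not_adjacent(self):
        a = make_stats("a", 0.0, 0.10, sx=0.04, sy=0.04)
        b = make_stats("b", 0.10, 0.20, sx=0.04, sy=0.04)
        q = ss.adjacency_q(a, b)
        assert q == pytest.approx(0.1131 - 0.1414, abs=1e-3)
        assert q < 0

    def test_wider_rectangles_adjacent(self):
        a = make_stats("a", 0.0, 0.10, sx=0.06, sy=0.06)
        b = make_stats("b", 0.10, 0.20, sx=0.06, sy=0.06)
        q = ss.adjacency_q(a, b)
        assert q == pytest.approx(0.1697 - 0.1414, abs=1e-3)
        assert q > 0

    def test_coincident_centroids_sentinel(self):
        a = make_stats("a", 0.0, 0.10)
        b = make_stats("b", 0.0, 0.10, sx=0.01)
        assert ss.adjacency_q(a, b) == Q_COINCIDENT

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(500):
            x1, x2 = rng.uniform(-0.5, 1.0, 2)
            a = make_stats("a", x1, x1 + rng.uniform(0.05, 0.5),
                           sx=rng.uniform(0, 0.1), sy=rng.uniform(0, 0.1))
            b = make_stats("b", x2, x2 + rng.uniform(0.05, 0.5),
                           sx=rng.uniform(0, 0.1), sy=rng.uniform(0, 0.1))
            assert ss.adjacency_q(a, b) == pytest.approx(
                brute_force_q(a, b), abs=1e-12)

    @settings(derandomize=True, max_examples=100)
    @given(
        x1=st.floats(-0.4, 0.8), d1=st.floats(0.05, 0.4),
        x2=st.floats(-0.4, 0.8), d2=st.floats(0.05, 0.4),
        s=st.tuples(*[st.floats(0.001, 0.08)] * 4),
        shift=st.floats(-0.5, 0.5), scale=st.floats(0.1, 5.0),
    )
    def test_symmetry_translation_and_scaling(self, x1, d1, x2, d2, s, shift, scale):
        a = make_stats("a", x1, x1 + d1, sx=s[0], sy=s[1])
        b = make_stats("b", x2, x2 + d2, sx=s[2], sy=s[3])
        q = ss.adjacency_q(a, b)
        assert ss.adjacency_q(b, a) == pytest.approx(q, abs=1e-12)
        at = make_stats("a", x1 + shift, x1 + d1 + shift, sx=s[0], sy=s[1])
        bt = make_stats("b", x2 + shift, x2 + d2 + shift, sx=s[2], sy=s[3])
        assert ss.adjacency_q(at, bt) == pytest.approx(q, abs=1e-9)
        if np.isfinite(q):
            asc = make_stats("a", x1 * scale, (x1 + d1) * scale,
                             sx=s[0] * scale, sy=s[1] * scale)
            bsc = make_stats("b", x2 * scale, (x2 + d2) * scale,
                             sx=s[2] * scale, sy=s[3] * scale)
            assert ss.adjacency_q(asc, bsc) == pytest.approx(
                scale * q, rel=1e-9, abs=1e-12)


class TestAdjacencyMatrixAndClasses:
    def chain_stats(self):
        # A-B and B-C overlap; A-C do not
        return [
            make_stats("A", 0.00, 0.10, sx=0.03, sy=0.03),
            make_stats("B", 0.05, 0.15, sx=0.03, sy=0.03),
            make_stats("C", 0.10, 0.20, sx=0.03, sy=0.03),
        ]

    def test_chain_adjacency_pattern(self):
        adj = ss.build_adjacency(self.chain_stats())
        i = {l: k for k, l in enumerate(adj.labels)}
        assert adj.entries[i["A"], i["B"]]
        assert adj.entries[i["B"], i["C"]]
        assert not adj.entries[i["A"], i["C"]]

    def test_chain_is_one_class(self):
        adj = ss.build_adjacency(self.chain_stats())
        classes = ss.equivalence_classes(adj)
        assert classes == [{"A", "B", "C"}]

    def test_distant_bursts_are_singletons(self):
        stats = [make_stats(l, 0.3 * k, 0.3 * k + 0.05, sx=0.01, sy=0.01)
                 for k, l in enumerate("ABCDE")]
        adj = ss.build_adjacency(stats)
        assert len(ss.equivalence_classes(adj)) == 5

    def test_duplicate_labels_rejected(self):
        with pytest.raises(InvalidClusterError):
            ss.build_adjacency([make_stats("A", 0, 0.1),
                                make_stats("A", 0.5, 0.6)])

    def test_matches_networkx_components(self):
        import networkx as nx

        rng = np.random.default_rng(6)
        for _ in range(100):
            n = int(rng.integers(2, 30))
            dense = rng.random((n, n)) < 0.1
            m = np.triu(dense, 1)
            m = m | m.T | np.eye(n, dtype=bool)
            labels = tuple(f"b{i}" for i in range(n))
            adj = ss.AdjacencyMatrix(labels=labels, entries=m)
            ours = {frozenset(c) for c in ss.equivalence_classes(adj)}
            g = nx.Graph()
            g.add_nodes_from(labels)
            g.add_edges_from((labels[i], labels[j])
                             for i in range(n) for j in range(i + 1, n)
                             if m[i, j])
            theirs = {frozenset(c) for c in nx.connected_components(g)}
            assert ours == theirs


class TestOrderClusters:
    def test_ascending_mean_onset(self):
        stats = [make_stats("late", 0.3, 0.4), make_stats("early", -0.1, 0.0),
                 make_stats("mid", 0.1, 0.2)]
        sol = ss.order_clusters([{"late"}, {"early"}, {"mid"}], stats)
        assert [c.members[0] for c in sol.clusters] == ["early", "mid", "late"]
        assert [c.id for c in sol.clusters] == [1, 2, 3]

    def test_tie_broken_lexicographically_and_deterministic(self):
        stats = [make_stats("zz", 0.1, 0.2), make_stats("aa", 0.1, 0.3)]
        for partition in ([{"zz"}, {"aa"}], [{"aa"}, {"zz"}]):
            sol = ss.order_clusters(partition, stats)
            assert [c.members[0] for c in sol.clusters] == ["aa", "zz"]

    def test_input_order_invariance(self, fig2_control_stats):
        base = ss.cluster_bursts(fig2_control_stats)
        flipped = ss.cluster_bursts(list(reversed(fig2_control_stats)))
        assert base.label_sets() == flipped.label_sets()
        assert [c.members for c in base.clusters] == [
            c.members for c in flipped.clusters]


class TestTwoStage:
    def cluster_of_three(self):
        return [
            make_stats("m1", 0.00, 0.10, sx=0.03, sy=0.03),
            make_stats("m2", 0.01, 0.11, sx=0.03, sy=0.03),
            make_stats("m3", 0.02, 0.12, sx=0.03, sy=0.03),
        ]

    def test_joins_with_two_overlaps(self):
        add = make_stats("new", 0.05, 0.15, sx=0.03, sy=0.03)
        assert ss.adjacency_q(add, self.cluster_of_three()[0]) > 0
        sol = ss.cluster_two_stage(self.cluster_of_three(), [add])
        assert {"m1", "m2", "m3", "new"} in [set(c.members) for c in sol.clusters]

    def test_single_overlap_insufficient_for_multimember(self):
        # overlaps only m3 (barely), far from m1/m2
        add = make_stats("new", 0.068, 0.168, sx=0.02, sy=0.02)
        members = self.cluster_of_three()
        overlaps = [ss.adjacency_q(add, m) > 0 for m in members]
        assert overlaps == [False, False, True]
        sol = ss.cluster_two_stage(members, [add])
        assert {"new"} in [set(c.members) for c in sol.clusters]

    def test_singleton_cluster_joined_with_one_overlap(self):
        primary = [make_stats("solo", 0.0, 0.1, sx=0.03, sy=0.03)]
        add = make_stats("new", 0.03, 0.13, sx=0.03, sy=0.03)
        sol = ss.cluster_two_stage(primary, [add])
        assert [set(c.members) for c in sol.clusters] == [{"solo", "new"}]

    def test_no_additional_equals_stage_one(self, fig2_control_stats):
        direct = ss.cluster_bursts(fig2_control_stats)
        staged = ss.cluster_two_stage(fig2_control_stats, [])
        assert direct.label_sets() == staged.label_sets()

    def test_overlapping_label_sets_rejected(self):
        with pytest.raises(InvalidClusterError):
            ss.cluster_two_stage([make_stats("x", 0, 0.1)],
                                 [make_stats("x", 0.5, 0.6)])


class TestConstrained:
    def test_idempotent_on_reference_data(self, fig2_control_stats, fig2_reference):
        sol = ss.assign_constrained(fig2_control_stats, fig2_reference)
        assert sol.label_sets() == fig2_reference.label_sets()
        for c in sol.clusters:
            ref = fig2_reference[c.id]
            assert c.centroid == pytest.approx(ref.centroid)
            assert c.pooled.x == pytest.approx(ref.pooled.x)

    def test_novel_burst_joins_most_adjacent_cluster(self):
        stats = [
            make_stats("a1", 0.00, 0.10, sx=0.03, sy=0.03),
            make_stats("a2", 0.01, 0.11, sx=0.03, sy=0.03),
            make_stats("a3", 0.02, 0.12, sx=0.03, sy=0.03),
            make_stats("b1", 0.40, 0.50, sx=0.03, sy=0.03),
        ]
        reference = ss.cluster_bursts(stats)
        novel = make_stats("nv", 0.03, 0.13, sx=0.03, sy=0.03)
        sol = ss.assign_constrained(stats + [novel], reference)
        assert "nv" in sol[1].members

    def test_constant_shift_keeps_membership(self, fig2_control_stats,
                                             fig2_reference):
        shifted = [
            ss.BurstStatistics(label=s.label, x=s.x + 0.2, y=s.y + 0.2,
                               sx=s.sx, sy=s.sy, rho=s.rho, n=s.n)
            for s in fig2_control_stats
        ]
        sol = ss.assign_constrained(shifted, fig2_reference)
        assert sol.label_sets() == fig2_reference.label_sets()
        for c in sol.clusters:
            ref = fig2_reference[c.id]
            assert c.centroid[0] == pytest.approx(ref.centroid[0] + 0.2)
            assert c.centroid[1] == pytest.approx(ref.centroid[1] + 0.2)


class TestPooledStats:
    def test_matches_concatenated_trials(self):
        rng = np.random.default_rng(7)
        groups = [
            np.column_stack([rng.normal(0.1, 0.02, n), rng.normal(0.3, 0.03, n)])
            for n in (12, 30, 7)
        ]
        stats = [ss.summarize_burst(f"b{i}", g) for i, g in enumerate(groups)]
        pooled = ss.pool_statistics(stats)
        allpts = np.vstack(groups)
        assert pooled.n == allpts.shape[0]
        assert pooled.x == pytest.approx(allpts[:, 0].mean(), abs=1e-12)
        assert pooled.sx == pytest.approx(allpts[:, 0].std(ddof=1), abs=1e-12)
        assert pooled.sy == pytest.approx(allpts[:, 1].std(ddof=1), abs=1e-12)
        expected_rho = np.corrcoef(allpts[:, 0], allpts[:, 1])[0, 1]
        assert pooled.rho == pytest.approx(expected_rho, abs=1e-10)


class TestCentroidDistance:
    def test_examples(self, fig2_reference):
        c1 = fig2_reference.clusters[0]
        assert ss.centroid_distance(c1, c1) == 0.0
        a = ss.Cluster(1, ("x",), (0.0, 0.0), c1.pooled)
        b = ss.Cluster(2, ("y",), (0.3, 0.4), c1.pooled)
        assert ss.centroid_distance(a, b) == pytest.approx(0.5)
        assert ss.centroid_distance(b, a) == pytest.approx(0.5)
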