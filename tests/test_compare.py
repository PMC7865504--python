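import numpy as np
import pandas as pd
import pytest

from canetx.compare import (
    Dendrogram,
    cophenetic_correlation,
    collapse_centroids,
    hcluster,
    loocv_logistic_auc,
    mann_whitney_auc,
    pca_scores,
    prune_to_common,
)
from canetx.tables import load_gene_topology, load_metabolite_topology


def brute_upgma(points, labels):
    """Naive average-linkage on Euclidean distances: clusters merge at the
    mean pairwise distance between their members."""
    points = np.asarray(points, float)
    clusters = {i: [i] for i in range(len(points))}
    merges = []
    active = list(clusters)
    while len(active) > 1:
        best = None
        for ai in range(len(active)):
            for bi in range(ai + 1, len(active)):
                a, b = active[ai], active[bi]
                d = np.mean([
                    np.linalg.norm(points[i] - points[j])
                    for i in clusters[a] for j in clusters[b]
                ])
                if best is None or d < best[0]:
                    best = (d, a, b)
        d, a, b = best
        new = max(clusters) + 1
        clusters[new] = clusters[a] + clusters[b]
        merges.append((sorted((a, b)), d))
        active = [c for c in active if c not in (a, b)] + [new]
    return merges


class TestPCA:
    def test_rank_one_matrix(self, rng):
        v = rng.normal(size=5)
        m = np.outer(rng.normal(size=6), v) + 7.0
        scores, model = pca_scores(m, ncomp=1, return_model=True)
        ev = model["eigenvalues"]
        assert ev[0] / ev.sum() == pytest.approx(1.0, abs=1e-10)

    def test_scores_orthogonal(self, rng):
        m = rng.normal(size=(10, 6))
        s = pca_scores(m, ncomp=3).to_numpy()
        g = s.T @ s
        off = g[~np.eye(3, dtype=bool)]
        assert np.max(np.abs(off)) < 1e-8

    def test_eigenvalues_match_correlation_eigendecomposition(self, rng):
        m = rng.normal(size=(12, 5))
        _, model = pca_scores(m, ncomp=3, return_model=True)
        corr = np.corrcoef(m.T)
        ev = np.sort(np.linalg.eigvalsh(corr))[::-1]
        # SVD of standardized data: eigenvalues of corr scaled by (n-1)/(n-1)
        np.testing.assert_allclose(model["eigenvalues"][:3], ev[:3], atol=1e-8)

    def test_ncomp_beyond_rank_raises(self, rng):
        m = np.outer(rng.normal(size=4), rng.normal(size=4))
        with pytest.raises(ValueError, match="rank"):
            pca_scores(m, ncomp=3)

    def test_deterministic_sign_convention(self, rng):
        m = rng.normal(size=(8, 4))
        s1 = pca_scores(m, ncomp=2)
        s2 = pca_scores(m.copy(), ncomp=2)
        pd.testing.assert_frame_equal(s1, s2)


class TestHCluster:
    def test_collinear_points_merge_order(self):
        pts = np.array([[0.0], [1.0], [10.0]])
        d = hcluster(pts, ["a", "b", "c"])
        assert d.linkage[0, 2] == pytest.approx(1.0)
        first = {int(d.linkage[0, 0]), int(d.linkage[0, 1])}
        assert first == {0, 1}

    def test_identical_points_merge_at_zero(self):
        pts = np.array([[1.0, 2.0], [1.0, 2.0], [5.0, 5.0]])
        d = hcluster(pts, ["a", "b", "c"])
        assert d.linkage[0, 2] == 0.0

    def test_matches_bruteforce_upgma(self, rng):
        pts = rng.normal(size=(5, 3))
        labels = list("abcde")
        d = hcluster(pts, labels)
        brute = brute_upgma(pts, labels)
        np.testing.assert_allclose(
            d.linkage[:, 2], [h for _, h in brute], atol=1e-10
        )

    def test_duplicate_labels_raise(self):
        with pytest.raises(ValueError, match="duplicate"):
            hcluster(np.zeros((2, 2)), ["a", "a"])


class TestCollapseCentroids:
    def test_identity_when_unique(self, rng):
        pts = rng.normal(size=(3, 2))
        out, labels = collapse_centroids(pts, ["a", "b", "c"])
        np.testing.assert_array_equal(out, pts)

    def test_duplicate_rows_averaged(self):
        pts = np.array([[0.0, 0.0, 0.0], [2.0, 2.0, 2.0], [5.0, 5.0, 5.0]])
        out, labels = collapse_centroids(pts, ["x", "x", "y"])
        np.testing.assert_array_equal(out[0], [1.0, 1.0, 1.0])
        assert labels == ["x", "y"]

    def test_collapse_then_cluster_equals_manual_average(self):
        pts = np.array([[0.0], [2.0], [10.0], [12.0]])
        out, labels = collapse_centroids(pts, ["a", "a", "b", "b"])
        d = hcluster(out, labels)
        manual = hcluster(np.array([[1.0], [11.0]]), ["a", "b"])
        np.testing.assert_allclose(d.linkage[:, 2], manual.linkage[:, 2])


class TestPruneAndCophenetic:
    def make_tree(self, pts, labels):
        return hcluster(np.asarray(pts, float).reshape(len(labels), -1), labels)

    def test_identical_leaf_sets_unchanged(self):
        d = self.make_tree([0, 1, 5, 6], list("abcd"))
        p1, p2 = prune_to_common(d, d)
        np.testing.assert_allclose(p1.linkage, d.linkage)

    def test_pruned_subtree_preserves_cophenetic_heights(self):
        d = self.make_tree([0.0, 1.0, 5.0, 6.0, 20.0], list("abcde"))
        other = self.make_tree([0.0, 1.0, 2.0], list("abc"))
        p1, _ = prune_to_common(d, other)
        assert set(p1.labels) == {"a", "b", "c"}
        full = d.cophenetic_matrix()
        sub = p1.cophenetic_matrix()
        for x in "abc":
            for y in "abc":
                assert sub.loc[x, y] == pytest.approx(full.loc[x, y], abs=1e-10)

    def test_disjoint_leaves_raise(self):
        d1 = self.make_tree([0, 1, 2], list("abc"))
        d2 = self.make_tree([0, 1, 2], list("xyz"))
        with pytest.raises(ValueError, match="shared"):
            prune_to_common(d1, d2)

    def test_tree_against_itself_is_one(self):
        d = self.make_tree([0, 1.5, 7, 9], list("abcd"))
        assert cophenetic_correlation(d, d) == pytest.approx(1.0)

    def test_invariant_to_leaf_order(self):
        d1 = self.make_tree([0.0, 1.0, 5.0, 9.0], list("abcd"))
        pts = np.array([9.0, 5.0, 1.0, 0.0])
        d2 = self.make_tree(pts, list("dcba"))
        assert cophenetic_correlation(d1, d2) == pytest.approx(1.0)

    def test_hand_computed_cophenetic_correlation(self):
        # tree 1: (a,b) at 1, +c at 4, +d at 8 -> coph (ab,ac,ad,bc,bd,cd)
        d1 = Dendrogram(
            linkage=np.array([[0, 1, 1.0, 2], [4, 2, 4.0, 3], [5, 3, 8.0, 4]]),
            labels=("a", "b", "c", "d"),
        )
        # tree 2: (a,c) at 2, +b at 3, +d at 10
        d2 = Dendrogram(
            linkage=np.array([[0, 2, 2.0, 2], [4, 1, 3.0, 3], [5, 3, 10.0, 4]]),
            labels=("a", "b", "c", "d"),
        )
        c1 = np.array([1.0, 4.0, 8.0, 4.0, 8.0, 8.0])
        c2 = np.array([3.0, 2.0, 10.0, 3.0, 10.0, 10.0])
        expect = np.corrcoef(c1, c2)[0, 1]
        assert cophenetic_correlation(d1, d2) == pytest.approx(expect, abs=1e-12)

    def test_linear_vs_nonlinear_height_transforms(self):
        d = self.make_tree([0.0, 1.0, 5.0, 6.0, 20.0], list("abcde"))
        z_lin = d.linkage.copy()
        z_lin[:, 2] = 3.0 * z_lin[:, 2] + 2.0
        d_lin = Dendrogram(linkage=z_lin, labels=d.labels)
        assert cophenetic_correlation(d, d_lin) == pytest.approx(1.0, abs=1e-12)
        z_nl = d.linkage.copy()
        z_nl[:, 2] = z_nl[:, 2] ** 3  # rank-preserving, nonlinear
        d_nl = Dendrogram(linkage=z_nl, labels=d.labels)
        assert cophenetic_correlation(d, d_nl) < 1.0 - 1e-6

    def test_newick_branch_lengths_reconstruct_cophenetic(self):
        d = self.make_tree([0.0, 1.0, 5.0, 9.0], list("abcd"))
        nwk = d.to_newick()
        assert nwk.endswith(";") and nwk.count("(") == 3
        import dendropy

        tree = dendropy.Tree.get(data=nwk, schema="newick")
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.taxon_namespace}
        coph = d.cophenetic_matrix()
        for x in "abc":
            for y in "bcd":
                if x == y:
                    continue
                assert pdm.distance(taxa[x], taxa[y]) == pytest.approx(
                    coph.loc[x, y], abs=1e-6
                )


class TestLOOCVAUC:
    def test_uninformative_measure_near_half(self):
        df = pd.DataFrame({"m": [1.0] * 10})
        labels = ["cancer"] * 5 + ["control"] * 5
        res = loocv_logistic_auc(df, labels, "m")
        assert res.auc == pytest.approx(0.5, abs=0.01)

    def test_perfect_separation(self):
        df = pd.DataFrame({"m": [0, 1, 2, 3, 10, 11, 12, 13.0]})
        labels = ["control"] * 4 + ["cancer"] * 4
        res = loocv_logistic_auc(df, labels, "m")
        assert res.auc == 1.0

    def test_negation_symmetry_of_mann_whitney(self, rng):
        x = rng.normal(size=20)
        y = rng.random(20) < 0.5
        y[0], y[1] = True, False
        assert mann_whitney_auc(x, y) + mann_whitney_auc(-x, y) == pytest.approx(1.0)

    def test_loocv_close_to_raw_on_fixture_tables(self):
        met = load_metabolite_topology()
        gen = load_gene_topology()
        for df, measure in [(met, "mean_closeness"), (gen, "edges"), (gen, "hub_nodes")]:
            res = loocv_logistic_auc(df, df["group"], measure)
            # the logistic model is direction-free; orient the raw AUC
            raw = max(res.raw_auc, 1.0 - res.raw_auc)
            assert abs(res.auc - raw) < 0.02

    def test_single_method_exposed(self):
        met = load_metabolite_topology()
        res = loocv_logistic_auc(met, met["group"], "mean_closeness", method="single")
        assert res.heldout_probs.shape == (28,)
        assert 0 <= res.auc <= 1

    def test_one_class_raises(self):
        df = pd.DataFrame({"m": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="class"):
            loocv_logistic_auc(df, ["cancer"] * 3, "m")
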