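"""Centered-Pearson distances, Ward agglomeration and H-cluster extraction."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import wntsig as w


def cohort_from(values: np.ndarray, subtypes: list[str]) -> w.ExpressionCohort:
    g, s = values.shape
    genes = [f"g{i}" for i in range(g)]
    samples = [f"s{i}" for i in range(s)]
    return w.ExpressionCohort(
        values=pd.DataFrame(values, index=genes, columns=samples),
        subtype=pd.Series(subtypes, index=samples),
    )


class TestGeneDistance:
    def test_duplicated_gene_distance_zero(self):
        x = np.random.default_rng(0).normal(size=(1, 10))
        values = np.vstack([x, x, np.random.default_rng(1).normal(size=(1, 10))])
        cohort = cohort_from(values, ["A"] * 5 + ["B"] * 5)
        d = w.gene_distance(cohort, ["g0", "g1", "g2"])
        assert d.loc["g0", "g1"] == pytest.approx(0.0, abs=1e-12)

    def test_reflected_profile_distance_two(self):
        x = np.random.default_rng(0).normal(size=10)
        cohort = cohort_from(np.vstack([x, -x]), ["A"] * 5 + ["B"] * 5)
        d = w.gene_distance(cohort, ["g0", "g1"])
        assert d.loc["g0", "g1"] == pytest.approx(2.0)

    @given(st.integers(0, 2**31 - 1))
    def test_matches_elementwise_formula(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.normal(size=(5, 12))
        cohort = cohort_from(values, ["A"] * 6 + ["B"] * 6)
        genes = [f"g{i}" for i in range(5)]
        d = w.gene_distance(cohort, genes)
        for i, j in itertools.combinations(range(5), 2):
            xi, xj = values[i] - values[i].mean(), values[j] - values[j].mean()
            r = (xi * xj).sum() / np.sqrt((xi**2).sum() * (xj**2).sum())
            assert d.iloc[i, j] == pytest.approx(1 - r, abs=1e-10)
        # symmetry and zero diagonal
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0)

    def test_constant_gene_named_in_error(self):
        values = np.vstack([np.ones(8), np.random.default_rng(0).normal(size=8)])
        cohort = cohort_from(values, ["A"] * 4 + ["B"] * 4)
        with pytest.raises(w.DegenerateDataError, match="g0"):
            w.gene_distance(cohort, ["g0", "g1"])


def brute_force_ward(D: np.ndarray):
    """Stepwise re-computation of the Ward criterion on squared distances."""
    n = D.shape[0]
    S = {(i, j): D[i, j] ** 2 for i, j in itertools.combinations(range(n), 2)}
    sizes = {i: 1 for i in range(n)}
    merges = []
    next_id = n
    while len(sizes) > 1:
        best = min(S.items(), key=lambda kv: (kv[1], kv[0]))
        (ci, cj), crit = best
        merges.append((ci, cj, np.sqrt(crit)))
        ni, nj = sizes[ci], sizes[cj]
        new_S = {}
        for ck in sizes:
            if ck in (ci, cj):
                continue
            nk = sizes[ck]
            dik = S[tuple(sorted((ci, ck)))]
            djk = S[tuple(sorted((cj, ck)))]
            new_S[tuple(sorted((next_id, ck)))] = (
                (ni + nk) * dik + (nj + nk) * djk - nk * crit
            ) / (ni + nj + nk)
        S = {
            k: v for k, v in S.items() if ci not in k and cj not in k
        } | new_S
        del sizes[ci], sizes[cj]
        sizes[next_id] = ni + nj
        next_id += 1
    return merges


class TestWardTree:
    def test_two_items_single_merge(self):
        D = np.array([[0.0, 3.0], [3.0, 0.0]])
        tree = w.ward_tree(D)
        assert tree.linkage.shape == (1, 4)
        assert tree.linkage[0, 2] == pytest.approx(3.0)

    def test_separated_blocks_join_last(self):
        rng = np.random.default_rng(0)
        # two tight blocks far apart
        pts = np.vstack([rng.normal(0, 0.1, (4, 2)), rng.normal(20, 0.1, (4, 2))])
        D = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        tree = w.ward_tree(D)
        last_i, last_j = int(tree.linkage[-1, 0]), int(tree.linkage[-1, 1])
        # the two children of the root are the two 4-item blocks
        sizes = {8 + k: int(tree.linkage[k, 3]) for k in range(7)}
        assert sizes.get(last_i, 1) == 4 and sizes.get(last_j, 1) == 4

    @pytest.mark.parametrize("n", [3, 4, 5, 6, 7])
    def test_matches_stepwise_brute_force(self, n):
        rng = np.random.default_rng(n)
        pts = rng.normal(size=(n, 3))
        D = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        tree = w.ward_tree(D)
        expected = brute_force_ward(D)
        for row, (ci, cj, h) in zip(tree.linkage, expected):
            assert {int(row[0]), int(row[1])} == {ci, cj}
            assert row[2] == pytest.approx(h, rel=1e-10)

    def test_matches_scipy_ward_on_euclidean_input(self):
        from scipy.cluster.hierarchy import linkage
        from scipy.spatial.distance import pdist, squareform

        rng = np.random.default_rng(21)
        pts = rng.normal(size=(15, 4))
        D = squareform(pdist(pts))
        mine = w.ward_tree(D).linkage
        ref = linkage(squareform(D), method="ward")
        assert np.allclose(np.sort(mine[:, 2]), np.sort(ref[:, 2]), rtol=1e-8)

    @given(st.integers(0, 2**31 - 1))
    def test_heights_monotone(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(10, 3))
        D = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        heights = w.ward_tree(D).linkage[:, 2]
        assert np.all(np.diff(heights) >= -1e-12)

    def test_partition_stable_under_input_permutation(self):
        rng = np.random.default_rng(8)
        values = rng.normal(size=(9, 30))
        cohort = cohort_from(values, ["A"] * 15 + ["B"] * 15)
        genes = [f"g{i}" for i in range(9)]
        d1 = w.gene_distance(cohort, genes)
        perm = list(reversed(genes))
        d2 = w.gene_distance(cohort, perm)
        c1 = w.extract_h_clusters(w.ward_tree(d1), cohort, k=3, focal="A")
        c2 = w.extract_h_clusters(w.ward_tree(d2), cohort, k=3, focal="A")
        parts1 = {frozenset(g) for g in c1.clusters.values()}
        parts2 = {frozenset(g) for g in c2.clusters.values()}
        assert parts1 == parts2

    def test_single_item_rejected(self):
        with pytest.raises(w.UsageError):
            w.ward_tree(np.zeros((1, 1)))

    def test_newick_round_trips_through_dendropy(self):
        import dendropy

        rng = np.random.default_rng(2)
        pts = rng.normal(size=(6, 3))
        D = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        tree = w.ward_tree(D)
        parsed = dendropy.Tree.get(data=tree.to_newick(), schema="newick")
        assert len(parsed.leaf_nodes()) == 6


class TestHClusters:
    def make_block_cohort(self, seed=3):
        cfg = w.SimConfig(
            seed=seed, n_blocks=2, block_rho=0.8, delta=0.5, sigma=1.0,
            subtype_sizes={"MLIA": 25, "LAR": 25}, focal_subtype="MLIA",
            n_background_genes=0,
        )
        sig = w.GeneSignature(
            "s", up=frozenset(f"u{i:02d}" for i in range(20)),
        )
        return w.generate_cohort(cfg, sig)

    def test_singleton_and_single_cluster_cuts(self):
        cohort, truth = self.make_block_cohort()
        genes = sorted(truth.block_assignment)
        tree = w.ward_tree(w.gene_distance(cohort, genes))
        all_k = w.extract_h_clusters(tree, cohort, k=len(genes), focal="MLIA")
        assert all(len(g) == 1 for g in all_k.clusters.values())
        one = w.extract_h_clusters(tree, cohort, k=1, focal="MLIA")
        assert set(one.clusters) == {"H1"}
        assert set(one.clusters["H1"]) == set(genes)

    def test_k_exceeding_leaves_rejected(self):
        cohort, truth = self.make_block_cohort()
        genes = sorted(truth.block_assignment)
        tree = w.ward_tree(w.gene_distance(cohort, genes))
        with pytest.raises(w.UsageError):
            w.extract_h_clusters(tree, cohort, k=len(genes) + 1, focal="MLIA")

    def test_recovers_planted_blocks(self):
        from sklearn.metrics import adjusted_rand_score

        cohort, truth = self.make_block_cohort()
        genes = sorted(truth.block_assignment)
        dist = w.gene_distance(cohort, genes)
        cl = w.extract_h_clusters(w.ward_tree(dist), cohort, k=2, focal="MLIA")
        ari = adjusted_rand_score(
            [truth.block_assignment[g] for g in genes],
            [cl.assignment[g] for g in genes],
        )
        assert ari >= 0.9

    def test_auto_k_selects_two_for_two_blocks(self):
        cohort, truth = self.make_block_cohort(seed=5)
        genes = sorted(truth.block_assignment)
        dist = w.gene_distance(cohort, genes)
        cl = w.extract_h_clusters(
            w.ward_tree(dist), cohort, focal="MLIA", auto_k=True, distances=dist
        )
        assert cl.k == 2 and cl.chosen_by == "silhouette"

    def test_h1_is_most_focal_elevated(self):
        """With a planted focal shift on up-genes, H1 has the higher focal mean."""
        cfg = w.SimConfig(
            seed=9, n_blocks=2, block_rho=0.6, delta=2.0, sigma=1.0,
            subtype_sizes={"MLIA": 30, "LAR": 30}, focal_subtype="MLIA",
            n_background_genes=0,
        )
        sig = w.GeneSignature(
            "s",
            up=frozenset(f"u{i:02d}" for i in range(10)),
            down=frozenset(f"d{i:02d}" for i in range(10)),
        )
        cohort, truth = self.make_up_down_cohort(cfg, sig)
        genes = sorted(sig.genes)
        dist = w.gene_distance(cohort, genes)
        cl = w.extract_h_clusters(w.ward_tree(dist), cohort, k=2, focal="MLIA")
        profile, cluster_sigs = w.subtype_cluster_profile(cohort, cl)
        pivot = profile.pivot(index="cluster", columns="subtype",
                              values="mean_expression")
        assert pivot.loc["H1", "MLIA"] - pivot.loc["H2", "MLIA"] >= 0
        assert {s.name for s in cluster_sigs} == {"H1", "H2"}

    @staticmethod
    def make_up_down_cohort(cfg, sig):
        return w.generate_cohort(cfg, sig)


class TestSubtypeClusterProfile:
    def test_single_gene_cluster_means(self):
        rng = np.random.default_rng(0)
        values = rng.normal(size=(3, 10))
        cohort = cohort_from(values, ["A"] * 5 + ["B"] * 5)
        tree = w.ward_tree(w.gene_distance(cohort, ["g0", "g1", "g2"]))
        cl = w.extract_h_clusters(tree, cohort, k=3, focal="A")
        profile, _ = w.subtype_cluster_profile(cohort, cl)
        for _, row in profile.iterrows():
            (gene,) = cl.clusters[row["cluster"]]
            cols = cohort.samples_of(row["subtype"])
            assert row["mean_expression"] == pytest.approx(
                float(cohort.values.loc[gene, cols].mean())
            )

    def test_constant_matrix_uniform_profile(self):
        values = np.full((4, 8), 2.0)
        values += np.random.default_rng(0).normal(0, 1e-9, values.shape)  # avoid 0 var
        cohort = cohort_from(values, ["A"] * 4 + ["B"] * 4)
        tree = w.ward_tree(w.gene_distance(cohort, [f"g{i}" for i in range(4)]))
        cl = w.extract_h_clusters(tree, cohort, k=2, focal="A")
        profile, _ = w.subtype_cluster_profile(cohort, cl)
        assert np.allclose(profile["mean_expression"], 2.0, atol=1e-8)
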