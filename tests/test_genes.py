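import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import linkage as scipy_linkage
from scipy.spatial.distance import squareform

from deepsav.genes import (
    cluster_genes,
    complete_linkage,
    correlation_distance_matrix,
    flat_clusters,
    linkage_to_newick,
    set_overlap,
    zscore,
)


def _bruteforce_complete_linkage(dist):
    """All-pairs agglomeration oracle, tracking max inter-cluster distance."""
    n = dist.shape[0]
    clusters = {i: frozenset([i]) for i in range(n)}
    merges = []
    next_id = n
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            d = max(dist[i, j] for i in clusters[a] for j in clusters[b])
            if best is None or d < best[0] - 1e-15:
                best = (d, a, b)
        d, a, b = best
        clusters[next_id] = clusters.pop(a) | clusters.pop(b)
        merges.append((a, b, d))
        next_id += 1
    return merges


class TestZscore:
    def test_column_convention_sample_sd(self):
        m = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 4.0]})
        z = zscore(m)
        # column a -> [-1, 0, 1] before row centering
        col_a = (m["a"] - m["a"].mean()) / m["a"].std(ddof=1)
        np.testing.assert_allclose(col_a.to_numpy(), [-1, 0, 1])
        # row centering applied afterwards
        np.testing.assert_allclose(z.mean(axis=1), 0.0, atol=1e-12)

    def test_constant_column_dropped(self):
        m = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [5.0, 5.0, 5.0]})
        z = zscore(m)
        assert list(z.columns) == ["a"]

    def test_column_standardisation_idempotent_before_centering(self):
        rng = np.random.default_rng(0)
        m = pd.DataFrame(rng.normal(size=(10, 4)), columns=list("abcd"))
        z1 = (m - m.mean()) / m.std(ddof=1)
        z2 = (z1 - z1.mean()) / z1.std(ddof=1)
        np.testing.assert_allclose(z1.to_numpy(), z2.to_numpy(), atol=1e-12)


class TestCompleteLinkage:
    def test_identical_rows_merge_first_at_zero(self):
        m = pd.DataFrame(
            [[1.0, 2.0, 3.0], [2.0, 4.0, 6.0], [3.0, 1.0, -2.0]],
            index=["g1", "g2", "g3"],
        )
        # rows g1,g2 perfectly correlated -> distance 0
        D = correlation_distance_matrix(m)
        assert D[0, 1] == pytest.approx(0.0, abs=1e-12)
        Z = complete_linkage(D)
        assert {int(Z[0, 0]), int(Z[0, 1])} == {0, 1}
        assert Z[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_rows_distance_two(self):
        m = pd.DataFrame([[1.0, 2.0, 3.0], [3.0, 2.0, 1.0]])
        D = correlation_distance_matrix(m)
        assert D[0, 1] == pytest.approx(2.0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_merge_sequence_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        D = squareform(rng.random(10))  # 5 genes
        Z = complete_linkage(D)
        oracle = _bruteforce_complete_linkage(D)
        for row, (a, b, d) in zip(Z, oracle):
            assert {int(row[0]), int(row[1])} == {a, b}
            assert row[2] == pytest.approx(d, abs=1e-9)

    @pytest.mark.parametrize("seed", [3, 4])
    def test_heights_match_scipy(self, seed):
        rng = np.random.default_rng(seed)
        D = squareform(rng.random(28))  # 8 genes
        ours = complete_linkage(D)
        theirs = scipy_linkage(squareform(D), method="complete")
        np.testing.assert_allclose(np.sort(ours[:, 2]), np.sort(theirs[:, 2]), atol=1e-9)

    def test_row_permutation_invariance_up_to_relabel(self):
        rng = np.random.default_rng(9)
        m = pd.DataFrame(rng.normal(size=(6, 4)), index=[f"g{i}" for i in range(6)])
        out1 = cluster_genes(m, n_clusters=3)
        perm = rng.permutation(6)
        out2 = cluster_genes(m.iloc[perm], n_clusters=3)
        lab1 = out1.set_index("gene")["cluster"]
        lab2 = out2.set_index("gene")["cluster"]
        # same partition: co-membership matrices agree
        genes = list(m.index)
        for a, b in itertools.combinations(genes, 2):
            assert (lab1[a] == lab1[b]) == (lab2[a] == lab2[b])


class TestClusterGenes:
    def test_flat_cut_counts(self):
        rng = np.random.default_rng(2)
        m = pd.DataFrame(rng.normal(size=(12, 5)), index=[f"g{i}" for i in range(12)])
        out = cluster_genes(m, n_clusters=4)
        assert out["cluster"].nunique() == 4
        assert len(out) == 12

    def test_too_few_genes_rejected(self):
        m = pd.DataFrame(np.ones((2, 3)))
        with pytest.raises(ValueError):
            cluster_genes(m)

    def test_gene_with_missing_measures_excluded(self):
        rng = np.random.default_rng(6)
        m = pd.DataFrame(rng.normal(size=(5, 4)), index=[f"g{i}" for i in range(5)])
        m.iloc[0, 1:] = np.nan  # keeps a single non-missing value
        out = cluster_genes(m, n_clusters=2)
        assert "g0" not in set(out["gene"])

    def test_newick_export_parses(self):
        rng = np.random.default_rng(7)
        D = squareform(rng.random(10))
        Z = complete_linkage(D)
        tree = linkage_to_newick(Z, [f"g{i}" for i in range(5)])
        assert tree.endswith(";") and tree.count("(") == 4
        import io

        from Bio import Phylo

        t = Phylo.read(io.StringIO(tree), "newick")
        assert sorted(cl.name for cl in t.get_terminals()) == [f"g{i}" for i in range(5)]


class TestSetOverlap:
    def test_disjoint(self):
        out = set_overlap({1, 2}, {3}, {4, 5})
        assert out["AB"] == out["AC"] == out["BC"] == out["ABC"] == 0
        assert out["A_only"] == 2 and out["C_only"] == 2

    def test_identical_sets(self):
        out = set_overlap({1, 2, 3}, {1, 2, 3}, {1, 2, 3})
        assert out["ABC"] == 3
        assert sum(v for k, v in out.items() if k != "ABC") == 0

    def test_matches_membership_enumeration(self):
        rng = np.random.default_rng(10)
        universe = list(range(40))
        A = set(rng.choice(universe, 15, replace=False))
        B = set(rng.choice(universe, 18, replace=False))
        C = set(rng.choice(universe, 12, replace=False))
        out = set_overlap(A, B, C)
        regions = {k: 0 for k in out}
        for x in universe:
            ina, inb, inc = x in A, x in B, x in C
            if ina and inb and inc:
                regions["ABC"] += 1
            elif ina and inb:
                regions["AB"] += 1
            elif ina and inc:
                regions["AC"] += 1
            elif inb and inc:
                regions["BC"] += 1
            elif ina:
                regions["A_only"] += 1
            elif inb:
                regions["B_only"] += 1
            elif inc:
                regions["C_only"] += 1
        assert out == regions
        assert sum(out.values()) == len(A | B | C)
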