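"""Heterozygosity, SNP counts, site thinning, IBS distances, NJ trees."""

import numpy as np
import pytest

import loadscape as ls
from loadscape.diversity import DistanceMatrix, distance_matrix, nj_tree, thin_sites
from loadscape.genotype_io import MISSING

from conftest import make_matrix


class TestHeterozygosity:
    def test_one_het_in_300kb_regime(self):
        """One het among 300,000 callable sites is the 3.3e-6 regime of an
        almost-clonal population."""
        G = np.zeros((300_000, 1), dtype=np.int8)
        G[0, 0] = 1
        m = make_matrix(G, site_types=["snp"] + ["invariant"] * 299_999,
                        positions=list(range(1, 300_001)), spacing=1)
        rate = ls.heterozygosity(m)["S1"]
        assert rate == pytest.approx(3.33e-6, rel=0.01)

    def test_all_homozygous_is_zero(self):
        m = make_matrix(np.full((50, 2), 2, dtype=np.int8))
        assert (ls.heterozygosity(m) == 0).all()

    def test_missing_sites_excluded_from_denominator(self):
        G = np.array([[1], [MISSING], [0], [MISSING]], dtype=np.int8)
        m = make_matrix(G)
        assert ls.heterozygosity(m)["S1"] == pytest.approx(0.5)

    def test_binomial_oracle(self):
        """Genotypes drawn at known per-site het probability are recovered
        within three binomial standard deviations."""
        rng = np.random.default_rng(15)
        h = 2e-3
        n = 50_000
        G = (rng.random((n, 3)) < h).astype(np.int8)
        m = make_matrix(G, positions=list(range(1, n + 1)))
        sd = np.sqrt(h * (1 - h) / n)
        for rate in ls.heterozygosity(m):
            assert abs(rate - h) < 3 * sd


class TestSnpCount:
    def test_polymorphism_definition(self):
        pops = {"S1": "P", "S2": "P", "S3": "Q"}
        G = np.array(
            [
                [1, 0, 0],  # het in P -> counted for P
                [2, 2, 0],  # hom-alt in all P -> monomorphic within P
                [0, 2, 1],  # both homozygotes in P -> counted
                [0, 0, 1],  # monomorphic in P, het in Q
            ],
            dtype=np.int8,
        )
        m = make_matrix(G, populations=pops)
        assert ls.snp_count(m, "P") == 2
        assert ls.snp_count(m, "Q") == 2
        assert ls.snp_count(m, "ABSENT") == 0

    def test_matches_bruteforce_scan(self):
        rng = np.random.default_rng(6)
        pops = {f"S{i+1}": ("P" if i < 3 else "Q") for i in range(6)}
        G = rng.choice([0, 1, 2, MISSING], size=(500, 6), p=[0.4, 0.1, 0.4, 0.1])
        m = make_matrix(G, populations=pops)
        for pop, cols in (("P", [0, 1, 2]), ("Q", [3, 4, 5])):
            expected = 0
            for row in G[:, cols]:
                called = row[row != MISSING]
                if len(called) and (1 in called or (0 in called and 2 in called)):
                    expected += 1
            assert ls.snp_count(m, pop) == expected

    def test_additive_over_disjoint_site_sets(self):
        rng = np.random.default_rng(66)
        G = rng.choice([0, 1, 2], size=(200, 4)).astype(np.int8)
        m = make_matrix(G)
        first = m.take_sites(np.arange(100))
        second = m.take_sites(np.arange(100, 200))
        assert ls.snp_count(m, "P") == ls.snp_count(first, "P") + ls.snp_count(second, "P")


class TestThinSites:
    def test_greedy_example(self):
        m = make_matrix(
            np.zeros((5, 2), dtype=np.int8), positions=[1, 10_000, 60_000, 70_000, 120_000]
        )
        thinned = thin_sites(m, 50_000)
        assert thinned.positions.tolist() == [1, 60_000, 120_000]

    def test_zero_distance_is_identity(self):
        m = make_matrix(np.zeros((10, 2), dtype=np.int8))
        assert thin_sites(m, 0).n_sites == 10

    def test_retained_spacing_property(self):
        rng = np.random.default_rng(19)
        positions = np.sort(rng.choice(10_000_000, size=2_000, replace=False))
        m = make_matrix(np.zeros((2_000, 2), dtype=np.int8), positions=positions.tolist())
        kept = thin_sites(m, 50_000).positions
        assert (np.diff(kept) >= 50_000).all()


class TestDistanceMatrix:
    def test_identical_and_opposite_genotypes(self):
        G = np.array([[0, 0, 2], [2, 2, 0], [1, 1, 1]], dtype=np.int8)
        dm = distance_matrix(make_matrix(G))
        assert dm.values[0, 1] == pytest.approx(0.0)
        assert dm.values[0, 2] == pytest.approx(2 / 3)  # two opposite + one shared het

    def test_full_discordance_is_one(self):
        G = np.array([[0, 2]] * 5, dtype=np.int8)
        dm = distance_matrix(make_matrix(G))
        assert dm.values[0, 1] == pytest.approx(1.0)

    def test_het_vs_hom_single_site(self):
        dm = distance_matrix(make_matrix(np.array([[1, 0]], dtype=np.int8)))
        assert dm.values[0, 1] == pytest.approx(0.5)

    def test_matches_bruteforce_tally_and_permutation_invariance(self):
        rng = np.random.default_rng(3)
        G = rng.choice([0, 1, 2, MISSING], size=(300, 4), p=[0.3, 0.2, 0.3, 0.2])
        m = make_matrix(G)
        dm = distance_matrix(m)
        for i in range(4):
            for j in range(i + 1, 4):
                shared = sites = 0
                for row in G:
                    if row[i] != MISSING and row[j] != MISSING:
                        sites += 1
                        shared += 2 - abs(int(row[i]) - int(row[j]))
                assert dm.values[i, j] == pytest.approx(1 - shared / (2 * sites))
        perm = rng.permutation(300)
        dm2 = distance_matrix(m.take_sites(perm))
        np.testing.assert_allclose(dm.values, dm2.values)

    def test_no_shared_sites_is_error(self):
        G = np.array([[0, MISSING], [MISSING, 0]], dtype=np.int8)
        with pytest.raises(ValueError, match="share no genotyped sites"):
            distance_matrix(make_matrix(G))


def _parse_newick(newick):
    import io

    from skbio import TreeNode

    return TreeNode.read(io.StringIO(newick))


def _tip_distances(newick):
    tree = _parse_newick(newick)
    tips = sorted(t.name for t in tree.tips())
    out = {}
    for i, a in enumerate(tips):
        for b in tips[i + 1 :]:
            out[(a, b)] = tree.find(a).distance(tree.find(b))
    return out


class TestNeighborJoining:
    def test_four_taxon_additive_matrix_recovered_exactly(self):
        # tree: ((A:1,B:2):1,(C:3,D:4)) with the internal edge of length 1
        labels = ["A", "B", "C", "D"]
        D = np.array(
            [
                [0, 3, 5, 6],
                [3, 0, 6, 7],
                [5, 6, 0, 7],
                [6, 7, 7, 0],
            ],
            dtype=float,
        )
        dm = DistanceMatrix(labels, D, np.ones((4, 4), dtype=np.int64))
        newick = nj_tree(dm)
        dists = _tip_distances(newick)
        for (a, b), d in dists.items():
            i, j = labels.index(a), labels.index(b)
            assert d == pytest.approx(D[i, j], abs=1e-9)
        # topology: AB|CD split
        tree = _parse_newick(newick)
        lca = tree.lca(["A", "B"])
        assert {t.name for t in lca.tips()} in ({"A", "B"}, {"C", "D"})

    def test_three_taxon_closed_form(self):
        D = np.array([[0, 4, 6], [4, 0, 8], [6, 8, 0]], dtype=float)
        dm = DistanceMatrix(["X", "Y", "Z"], D, np.ones((3, 3), dtype=np.int64))
        dists = _tip_distances(nj_tree(dm))
        assert dists[("X", "Y")] == pytest.approx(4.0)
        assert dists[("X", "Z")] == pytest.approx(6.0)
        assert dists[("Y", "Z")] == pytest.approx(8.0)

    def test_eight_taxon_additive_matrix_recovered_exactly(self):
        rng = np.random.default_rng(42)
        # build a random additive matrix from a fixed tree by path sums
        newick_in = (
            "((A:0.5,(B:1.2,C:0.7):0.4):0.3,((D:0.9,E:0.2):0.6,(F:1.1,(G:0.3,H:0.8):0.5):0.2):0.4);"
        )
        tree = _parse_newick(newick_in)
        labels = sorted(t.name for t in tree.tips())
        n = len(labels)
        D = np.zeros((n, n))
        for i, a in enumerate(labels):
            for j in range(i + 1, n):
                D[i, j] = D[j, i] = tree.find(a).distance(tree.find(labels[j]))
        dm = DistanceMatrix(labels, D, np.ones((n, n), dtype=np.int64))
        dists = _tip_distances(nj_tree(dm))
        for (a, b), d in dists.items():
            assert d == pytest.approx(D[labels.index(a), labels.index(b)], abs=1e-9)

    def test_ultrametric_tie_break_is_deterministic(self):
        D = np.ones((4, 4)) - np.eye(4)
        dm = DistanceMatrix(list("ABCD"), D, np.ones((4, 4), dtype=np.int64))
        assert nj_tree(dm) == nj_tree(dm)
        assert nj_tree(dm).startswith("(")  # serializes; ties resolved by lowest pair

    def test_agrees_with_reference_implementation_topology(self):
        """On an additive matrix the in-package NJ and scikit-bio's NJ give
        the same unrooted topology."""
        from skbio import DistanceMatrix as SkbioDM
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(10)
        newick_in = "((A:0.5,B:1.2):0.3,(C:0.9,(D:0.2,E:1.4):0.7):0.6,F:0.8);"
        tree = _parse_newick(newick_in)
        labels = sorted(t.name for t in tree.tips())
        n = len(labels)
        D = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                D[i, j] = D[j, i] = tree.find(labels[i]).distance(tree.find(labels[j]))
        ours = _parse_newick(nj_tree(DistanceMatrix(labels, D, np.ones((n, n), np.int64))))
        theirs = skbio_nj(SkbioDM(D, ids=labels))
        assert ours.compare_rfd(theirs) == 0.0

    def test_nonsymmetric_input_rejected(self):
        D = np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0]], dtype=float)
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(list("ABC"), D, np.ones((3, 3), dtype=np.int64))
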