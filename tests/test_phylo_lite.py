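"""Anchored alignment, p-distances and neighbor joining."""

import itertools

import dendropy
import numpy as np
import pytest

from conftest import random_additive_tree, tree_leaf_distances
from nsltp import anchor_align, nj, p_distance, parse_ecm_string, scan_ecm
from nsltp.phylo_lite import AnchoredAlignment


def domain(spacing, filler="A", pre=0, post=0):
    seq = (filler * pre + "C" + filler * spacing[0] + "C" + filler * spacing[1]
           + "CC" + filler * spacing[2] + "C" + filler + "C"
           + filler * spacing[3] + "C" + filler * spacing[4] + "C"
           + filler * post)
    (m,) = scan_ecm(seq)
    return seq, m


class TestAnchorAlign:
    def test_identical_domains_align_gap_free(self):
        seq, m = domain((9, 14, 19, 22, 7))
        a = anchor_align([("x", seq, m), ("y", seq, m)])
        assert a.rows[0] == a.rows[1]
        assert "-" not in a.rows[0]

    def test_shorter_segment_padded(self):
        s1, m1 = domain((9, 14, 19, 22, 7))
        s2, m2 = domain((7, 14, 19, 22, 7))
        a = anchor_align([("long", s1, m1), ("short", s2, m2)])
        assert a.rows[1].count("-") == 2
        # gaps sit at the end of the first inter-cysteine segment
        assert a.rows[1][1:10] == "AAAAAAA--"

    def test_fixture_alignment_width(self, fixture_rows):
        domains = []
        spacings = []
        for r in fixture_rows:
            v = parse_ecm_string(r.ecm_string)
            spacings.append(v)
            seq, m = domain(tuple(v))
            domains.append((r.gene_name, seq, m))
        a = anchor_align(domains)
        expected = 8 + 1 + sum(
            max(v[k] for v in spacings) for k in range(5))
        assert a.width == expected
        for col in a.anchor_columns:
            assert all(row[col] == "C" for row in a.rows)

    def test_missing_match_is_error(self):
        seq, m = domain((9, 14, 19, 22, 7))
        with pytest.raises(ValueError, match="missing"):
            anchor_align([("x", seq, None)])


class TestPDistance:
    def test_identical_rows_zero(self):
        seq, m = domain((9, 14, 19, 22, 7))
        d = p_distance(anchor_align([("x", seq, m), ("y", seq, m)]))
        assert d[0, 1] == 0.0

    def test_all_mismatch_rows_one(self):
        a = AnchoredAlignment(ids=("x", "y"), rows=("CAC", "CGC"),
                              anchor_columns=(0, 2))
        # only the middle column differs; distance = 1/3
        assert p_distance(a)[0, 1] == pytest.approx(1 / 3)

    def test_hand_counted_three_taxa(self):
        a = AnchoredAlignment(
            ids=("x", "y", "z"),
            rows=("CAAGC", "CATG-", "CTTGC"),
            anchor_columns=(0,))
        d = p_distance(a)
        assert d[0, 1] == pytest.approx(1 / 4)   # 4 comparable, 1 mismatch
        assert d[0, 2] == pytest.approx(2 / 5)
        assert d[1, 2] == pytest.approx(1 / 4)
        assert np.allclose(d, d.T) and np.allclose(np.diag(d), 0)

    def test_no_comparable_columns_is_error(self):
        a = AnchoredAlignment(ids=("x", "y"), rows=("CA-", "C-A"),
                              anchor_columns=(0,))
        with pytest.raises(ValueError, match="no comparable"):
            # anchor column is shared; drop it to force the degenerate case
            p_distance(AnchoredAlignment(
                ids=("x", "y"), rows=("A-", "-A"), anchor_columns=()))


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        d = np.array([[0.0, 0.3, 0.5],
                      [0.3, 0.0, 0.6],
                      [0.5, 0.6, 0.0]])
        tree = nj(d, ["a", "b", "c"])
        lengths = {child.name: l for child, l in tree.children}
        assert lengths["a"] == pytest.approx(0.5 * (0.3 + 0.5 - 0.6))
        assert lengths["b"] == pytest.approx(0.5 * (0.3 + 0.6 - 0.5))
        assert lengths["c"] == pytest.approx(0.5 * (0.5 + 0.6 - 0.3))

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            nj(np.zeros((2, 2)), ["a", "b"])

    def test_four_taxon_topology_vs_least_squares_oracle(self):
        # additive matrix from the quartet ((a,b),(c,d)) with known lengths
        d = np.zeros((4, 4))
        ids = ["a", "b", "c", "d"]
        # pendant: a=.1 b=.2 c=.3 d=.4, internal .5
        pend = {"a": 0.1, "b": 0.2, "c": 0.3, "d": 0.4}
        for i, j in itertools.combinations(range(4), 2):
            x, y = ids[i], ids[j]
            internal = 0.0 if {x, y} in ({"a", "b"}, {"c", "d"}) else 0.5
            d[i, j] = d[j, i] = pend[x] + pend[y] + internal

        # oracle: least-squares fit of each of the 3 unrooted quartets;
        # the generating split must fit best (zero residual)
        def quartet_rss(split):
            sides = [set(split[0]), set(split[1])]
            pairs = list(itertools.combinations(range(4), 2))
            A = np.zeros((6, 5))
            y = np.zeros(6)
            for row, (i, j) in enumerate(pairs):
                A[row, i] = A[row, j] = 1
                if {ids[i], ids[j]} not in sides:
                    A[row, 4] = 1.0  # crosses the internal edge
                y[row] = d[i, j]
            _, rss, *_ = np.linalg.lstsq(A, y, rcond=None)
            return float(rss[0]) if len(rss) else float(
                np.sum((A @ np.linalg.pinv(A) @ y - y) ** 2))

        splits = [(("a", "b"), ("c", "d")),
                  (("a", "c"), ("b", "d")),
                  (("a", "d"), ("b", "c"))]
        best = min(splits, key=quartet_rss)
        assert best == splits[0]
        assert quartet_rss(splits[0]) == pytest.approx(0.0, abs=1e-12)

        tree = nj(d, ids)
        dist = tree_leaf_distances(tree)
        for i, j in itertools.combinations(range(4), 2):
            assert dist[frozenset((ids[i], ids[j]))] == pytest.approx(d[i, j], abs=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_additive_matrix_recovered_exactly(self, seed):
        rng = np.random.default_rng(seed)
        D, ids = random_additive_tree(8, rng)
        tree = nj(D, ids)
        dist = tree_leaf_distances(tree)
        for i, j in itertools.combinations(range(8), 2):
            assert dist[frozenset((ids[i], ids[j]))] == pytest.approx(
                D[i, j], abs=1e-9)

    def test_leaf_permutation_gives_isomorphic_tree(self):
        rng = np.random.default_rng(123)
        D, ids = random_additive_tree(8, rng)
        perm = list(rng.permutation(8))
        Dp = D[np.ix_(perm, perm)]
        ids_p = [ids[i] for i in perm]
        tns = dendropy.TaxonNamespace()
        t1 = dendropy.Tree.get(data=nj(D, ids).to_newick(), schema="newick",
                               taxon_namespace=tns)
        t2 = dendropy.Tree.get(data=nj(Dp, ids_p).to_newick(), schema="newick",
                               taxon_namespace=tns)
        t1.encode_bipartitions()
        t2.encode_bipartitions()
        assert dendropy.calculate.treecompare.symmetric_difference(t1, t2) == 0

    def test_newick_round_trip_preserves_lengths(self):
        rng = np.random.default_rng(9)
        D, ids = random_additive_tree(6, rng)
        tree = nj(D, ids)
        parsed = dendropy.Tree.get(data=tree.to_newick(), schema="newick")
        pdm = parsed.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in parsed.taxon_namespace}
        own = tree_leaf_distances(tree)
        for i, j in itertools.combinations(range(6), 2):
            got = pdm.patristic_distance(taxa[ids[i]], taxa[ids[j]])
            assert got == pytest.approx(own[frozenset((ids[i], ids[j]))], rel=1e-4)
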