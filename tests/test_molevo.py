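import itertools

import numpy as np
import pytest

from hsp70census.molevo import (
    CodonAlignment,
    DistanceMatrix,
    PhyloTree,
    back_translate,
    bootstrap_support,
    jukes_cantor,
    neighbor_joining,
    ng86_kaks,
    p_distance_matrix,
    synonymous_site_fraction,
)
from .util import SENSE_CODONS, bf_pathway_differences, bf_synonymous_sites


class TestBackTranslate:
    def test_gap_expansion(self):
        caln = back_translate("MK-V", "MKAV", "ATGAAAGTT", "ATGAAAGCTGTA")
        assert caln.codons_a == ("ATG", "AAA", "---", "GTT")
        assert caln.codons_b == ("ATG", "AAA", "GCT", "GTA")

    def test_translation_mismatch_names_position(self):
        with pytest.raises(ValueError, match="residue 1"):
            back_translate("MK", "MK", "ATGGGG", "ATGAAA")

    def test_trailing_stop_tolerated(self):
        caln = back_translate("MK", "MK", "ATGAAATAA", "ATGAAA")
        assert caln.codons_a == ("ATG", "AAA")

    def test_round_trip_recovers_cds(self):
        cds_a, cds_b = "ATGAAAGTT", "ATGAAAGCTGTA"
        caln = back_translate("MK-V", "MKAV", cds_a, cds_b)
        assert "".join(c for c in caln.codons_a if c != "---") == cds_a
        assert "".join(c for c in caln.codons_b if c != "---") == cds_b


class TestNG86:
    def test_identical_sequences(self):
        caln = CodonAlignment(("ATG", "AAA"), ("ATG", "AAA"))
        r = ng86_kaks(caln)
        assert r.Sd == r.Nd == 0
        assert r.ka == r.ks == 0.0
        assert r.ratio is None and "ks_zero" in r.flags

    def test_phenylalanine_site_count(self):
        assert synonymous_site_fraction("TTT") == pytest.approx(1 / 3)

    def test_single_synonymous_column(self):
        r = ng86_kaks(CodonAlignment(("TTT",), ("TTC",)))
        assert r.Sd == 1 and r.Nd == 0
        assert r.ps == pytest.approx(1 / r.S)

    def test_sites_match_brute_force_for_all_sense_codons(self):
        for codon in SENSE_CODONS:
            assert synonymous_site_fraction(codon) == pytest.approx(
                bf_synonymous_sites(codon), abs=1e-12
            )

    def test_matches_brute_force_on_random_codon_pairs(self, rng):
        codons = np.array(SENSE_CODONS)
        for _ in range(300):
            ca, cb = rng.choice(codons, 2)
            r = ng86_kaks(CodonAlignment((ca,), (cb,)))
            sd, nd = bf_pathway_differences(ca, cb)
            assert r.Sd == pytest.approx(sd, abs=1e-9)
            assert r.Nd == pytest.approx(nd, abs=1e-9)
            s = (bf_synonymous_sites(ca) + bf_synonymous_sites(cb)) / 2
            assert r.S == pytest.approx(s, abs=1e-9)

    def test_site_conservation(self, rng):
        codons = np.array(SENSE_CODONS)
        for _ in range(50):
            n = int(rng.integers(1, 30))
            a = tuple(rng.choice(codons, n))
            b = tuple(rng.choice(codons, n))
            r = ng86_kaks(CodonAlignment(a, b))
            assert r.N + r.S == pytest.approx(3 * r.n_codons)

    def test_gap_columns_skipped(self):
        caln = CodonAlignment(("ATG", "---"), ("ATG", "AAA"))
        r = ng86_kaks(caln)
        assert r.n_codons == 1 and r.n_skipped == 1

    def test_saturation_flagged(self):
        assert jukes_cantor(0.8) is None
        assert jukes_cantor(0.0) == 0.0


class TestPDistance:
    def test_identical_rows_zero(self):
        dm = p_distance_matrix({"a": "MKVL", "b": "MKVL"})
        assert dm[("a", "b")] == 0.0

    def test_direct_count_ignoring_gaps(self):
        dm = p_distance_matrix({"a": "MKVLAAAAAA", "b": "MHVLCC-AAA"})
        # comparable columns: 9 (one gap), diffs: K/H, A/C, A/C = 3
        assert dm[("a", "b")] == pytest.approx(3 / 9)

    def test_symmetric_zero_diagonal(self, rng):
        rows = {
            f"t{i}": "".join(rng.choice(list("ACDEFG"), 30)) for i in range(5)
        }
        dm = p_distance_matrix(rows)
        assert np.allclose(dm.matrix, dm.matrix.T)
        assert np.allclose(np.diag(dm.matrix), 0)


def random_additive_tree(rng, n_taxa):
    """Random topology + branch lengths; returns (PhyloTree-free) distance
    matrix built by an independent path-length computation."""
    # build an adjacency of a random unrooted binary tree
    import itertools as it

    nodes = [f"t{i}" for i in range(3)]
    edges = {}
    internal = 0
    center = "int0"
    internal += 1
    for leaf in nodes:
        edges[(center, leaf)] = rng.uniform(0.05, 1.0)
    for i in range(3, n_taxa):
        leaf = f"t{i}"
        split_edge = list(edges)[rng.integers(0, len(edges))]
        w = edges.pop(split_edge)
        mid = f"int{internal}"
        internal += 1
        u, v = split_edge
        f = rng.uniform(0.2, 0.8)
        edges[(u, mid)] = w * f
        edges[(mid, v)] = w * (1 - f)
        edges[(mid, leaf)] = rng.uniform(0.05, 1.0)
    # path lengths by BFS
    import collections

    adj = collections.defaultdict(list)
    for (u, v), w in edges.items():
        adj[u].append((v, w))
        adj[v].append((u, w))
    taxa = sorted(f"t{i}" for i in range(n_taxa))
    m = np.zeros((n_taxa, n_taxa))
    for i, src in enumerate(taxa):
        dist = {src: 0.0}
        queue = collections.deque([src])
        while queue:
            cur = queue.popleft()
            for nxt, w in adj[cur]:
                if nxt not in dist:
                    dist[nxt] = dist[cur] + w
                    queue.append(nxt)
        for j, dst in enumerate(taxa):
            m[i, j] = dist[dst]
    m = (m + m.T) / 2  # per-row BFS leaves float-level asymmetry
    np.fill_diagonal(m, 0.0)
    return DistanceMatrix(tuple(taxa), m)


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        dm = DistanceMatrix(
            ("a", "b", "c"), np.array([[0, 0.4, 0.6], [0.4, 0, 0.8], [0.6, 0.8, 0]])
        )
        tree = neighbor_joining(dm)
        bl = tree.branch_length
        assert bl["a"] == pytest.approx(0.1)
        assert bl["b"] == pytest.approx(0.3)
        assert bl["c"] == pytest.approx(0.5)

    def test_additive_matrices_recovered_exactly(self, rng):
        for _ in range(10):
            dm = random_additive_tree(rng, 8)
            tree = neighbor_joining(dm)
            recovered = tree.distance_matrix()
            assert recovered.labels == dm.labels
            assert np.allclose(recovered.matrix, dm.matrix, atol=1e-9)

    def test_star_distances_zero_internal_branches(self):
        n = 4
        m = np.full((n, n), 1.0)
        np.fill_diagonal(m, 0.0)
        tree = neighbor_joining(DistanceMatrix(("a", "b", "c", "d"), m))
        for node in tree.internal_edges():
            assert tree.branch_length[node] == pytest.approx(0.0, abs=1e-12)

    def test_deterministic_on_ties(self):
        n = 5
        m = np.full((n, n), 2.0)
        np.fill_diagonal(m, 0.0)
        labels = tuple("abcde")
        t1 = neighbor_joining(DistanceMatrix(labels, m)).to_newick()
        t2 = neighbor_joining(DistanceMatrix(labels, m)).to_newick()
        assert t1 == t2

    def test_topology_agrees_with_skbio(self, rng):
        skbio = pytest.importorskip("skbio")
        from skbio import DistanceMatrix as SkbioDM
        from skbio.tree import nj as skbio_nj

        dm = random_additive_tree(rng, 7)
        ours = neighbor_joining(dm)
        theirs = skbio_nj(SkbioDM(dm.matrix, ids=list(dm.labels)))
        all_taxa = frozenset(dm.labels)

        def skbio_bipartitions(t):
            out = set()
            for node in t.non_tips():
                side = frozenset(tip.name for tip in node.tips())
                if 1 < len(side) < len(all_taxa) - 1:
                    other = all_taxa - side
                    out.add(min(side, other, key=lambda s: (len(s), tuple(sorted(s)))))
            return out

        assert ours.bipartitions() == skbio_bipartitions(theirs)

    def test_non_symmetric_input_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(("a", "b"), np.array([[0, 1.0], [2.0, 0]]))


class TestBootstrap:
    ROWS = [
        ("a", "AAAAAAAAAACCCC"),
        ("b", "AAAAAAAAAACCCC"),
        ("c", "TTTTTTTTTTGGGG"),
        ("d", "TTTTTTTTTTGGGG"),
        ("e", "TTTTTTTTTTCCGG"),
    ]

    def test_fully_supported_bipartition(self):
        tree = bootstrap_support(self.ROWS, n_reps=50, seed=3)
        assert any(s == pytest.approx(1.0) for s in tree.support.values())

    def test_supports_in_unit_interval(self):
        tree = bootstrap_support(self.ROWS, n_reps=30, seed=4)
        assert tree.support
        assert all(0.0 <= s <= 1.0 for s in tree.support.values())

    def test_same_seed_same_supports(self):
        t1 = bootstrap_support(self.ROWS, n_reps=40, seed=7)
        t2 = bootstrap_support(self.ROWS, n_reps=40, seed=7)
        assert t1.to_newick() == t2.to_newick()

    def test_fewer_than_four_taxa_no_supports(self):
        tree = bootstrap_support(self.ROWS[:3], n_reps=10, seed=1)
        assert tree.support == {}
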