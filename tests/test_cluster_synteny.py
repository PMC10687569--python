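import numpy as np
import pytest

from hsp70census.cluster_synteny import (
    GeneCluster,
    Region,
    detect_clusters,
    flag_t1_rich,
    homologous,
    neighborhood,
    synteny_link,
    synteny_matrix,
)
from hsp70census.io_core import AMINO_ACIDS, GeneModel, ProteinRecord, assign_ordinals


def make_chromosome(pattern, chrom="chr1"):
    """Genes from a pattern string: 'F' = family member, '.' = background."""
    genes, family = [], set()
    for i, ch in enumerate(pattern):
        gid = f"{chrom}_g{i:03d}"
        genes.append(
            GeneModel(
                gene_id=gid, chrom=chrom, start=1000 * (i + 1),
                end=1000 * (i + 1) + 500, strand="+", protein_id=f"p_{gid}",
            )
        )
        if ch == "F":
            family.add(gid)
    return assign_ordinals(genes), family


class TestDetectClusters:
    def test_consecutive_run_is_one_cluster(self):
        genes, fam = make_chromosome("." * 5 + "F" * 12 + "." * 5)
        clusters = detect_clusters(genes, fam)
        assert len(clusters) == 1 and clusters[0].size == 12

    def test_pair_below_min_size_ignored(self):
        genes, fam = make_chromosome("...FF...")
        assert detect_clusters(genes, fam) == []

    def test_gap_over_max_intervening_splits_runs(self):
        genes, fam = make_chromosome("FFF" + "." * 6 + "FFFF")
        clusters = detect_clusters(genes, fam, max_intervening=5)
        assert sorted(c.size for c in clusters) == [3, 4]
        merged = detect_clusters(genes, fam, max_intervening=6)
        assert [c.size for c in merged] == [7]

    def test_intervening_genes_tolerated_within_run(self):
        genes, fam = make_chromosome("F..F.F")
        clusters = detect_clusters(genes, fam, max_intervening=2)
        assert len(clusters) == 1 and clusters[0].size == 3

    def test_partition_no_gene_in_two_clusters(self, small_dataset):
        ds = small_dataset
        t1 = {t.gene_id for t in ds.truth if t.lineage == "T1"}
        clusters = detect_clusters(ds.genes, t1)
        seen = [m for c in clusters for m in c.members]
        assert len(seen) == len(set(seen))

    def test_raising_max_intervening_is_monotone(self):
        genes, fam = make_chromosome("FF.F..F...F....F" * 3)
        sizes = []
        for mi in (1, 2, 3, 4, 5):
            clusters = detect_clusters(genes, fam, min_size=2, max_intervening=mi)
            sizes.append(sum(c.size for c in clusters))
        assert sizes == sorted(sizes)


class TestT1Rich:
    @pytest.mark.parametrize("count,expected", [(15, True), (14, False), (58, True), (0, False)])
    def test_threshold(self, count, expected):
        assert flag_t1_rich(count) is expected

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            flag_t1_rich(-1)


class TestNeighborhood:
    def test_interior_anchor(self):
        genes, _ = make_chromosome("." * 200)
        anchor = next(g for g in genes if g.ordinal == 50)
        neigh = neighborhood(genes, anchor, n=10)
        assert [g.ordinal for g in neigh] == list(range(40, 50)) + list(range(51, 61))

    def test_edge_truncation(self):
        genes, _ = make_chromosome("." * 30)
        anchor = next(g for g in genes if g.ordinal == 2)
        neigh = neighborhood(genes, anchor, n=10)
        assert [g.ordinal for g in neigh] == [0, 1] + list(range(3, 13))

    def test_cluster_span_excluded(self):
        genes, fam = make_chromosome("." * 10 + "F" * 11 + "." * 20)
        cluster = detect_clusters(genes, fam)[0]
        neigh = neighborhood(genes, cluster, n=10)
        assert [g.ordinal for g in neigh] == list(range(0, 10)) + list(range(21, 31))


class TestHomologous:
    def _rand(self, rng, n=120):
        return ProteinRecord(
            id=f"r{rng.integers(1e9)}", sequence="".join(rng.choice(list(AMINO_ACIDS), n))
        )

    def test_self_homology(self, rng):
        p = self._rand(rng)
        assert homologous(p, p)

    def test_shuffled_not_homologous(self, rng):
        misses = 0
        for _ in range(20):
            p = self._rand(rng)
            q = ProteinRecord(id="q", sequence="".join(rng.permutation(list(p.sequence))))
            misses += not homologous(p, q)
        assert misses == 20

    def test_symmetry(self, rng):
        for _ in range(10):
            a, b = self._rand(rng), self._rand(rng)
            assert homologous(a, b) == homologous(b, a)


def _regions_with_shared_flankers(rng, n_shared, n=8, length=150):
    """Two neighbourhoods sharing exactly n_shared homologous genes."""
    def prot(seq, pid):
        return ProteinRecord(id=pid, sequence=seq)

    proteins = {}
    genes_a, genes_b = [], []
    shared = ["".join(rng.choice(list(AMINO_ACIDS), length)) for _ in range(n_shared)]
    for i in range(n):
        pa = f"a{i}"
        pb = f"b{i}"
        seq_a = shared[i] if i < n_shared else "".join(rng.choice(list(AMINO_ACIDS), length))
        seq_b = shared[i] if i < n_shared else "".join(rng.choice(list(AMINO_ACIDS), length))
        proteins[pa] = prot(seq_a, pa)
        proteins[pb] = prot(seq_b, pb)
        genes_a.append(GeneModel(gene_id=f"ga{i}", chrom="c1", start=100 * i + 1,
                                 end=100 * i + 50, strand="+", protein_id=pa, ordinal=i))
        genes_b.append(GeneModel(gene_id=f"gb{i}", chrom="c2", start=100 * i + 1,
                                 end=100 * i + 50, strand="+", protein_id=pb, ordinal=i))
    ra = Region(genome="g", chrom="c1", anchor_id="A", neighbor_gene_ids=tuple(g.gene_id for g in genes_a))
    rb = Region(genome="g", chrom="c2", anchor_id="B", neighbor_gene_ids=tuple(g.gene_id for g in genes_b))
    return ra, rb, genes_a, genes_b, proteins


class TestSyntenyLink:
    def test_three_homologs_is_syntenic_two_is_not(self, rng):
        for n_shared, expected in [(3, True), (2, False)]:
            ra, rb, ga, gb, prots = _regions_with_shared_flankers(rng, n_shared)
            link = synteny_link(ra, rb, ga, gb, prots)
            assert link.n_homologs == n_shared
            assert link.syntenic is expected

    def test_invariant_under_gene_order_reversal(self, rng):
        ra, rb, ga, gb, prots = _regions_with_shared_flankers(rng, 4)
        link = synteny_link(ra, rb, ga, gb, prots)
        flipped = synteny_link(ra, rb, ga, list(reversed(gb)), prots)
        assert link.syntenic == flipped.syntenic
        assert link.n_homologs == flipped.n_homologs

    def test_tandem_array_cannot_multi_map(self, rng):
        """Three copies of one gene on side A matching a single gene on side B
        yield one homolog pair, not three."""
        ra, rb, ga, gb, prots = _regions_with_shared_flankers(rng, 1, n=3)
        seq = prots["b0"].sequence
        for pid in ("a0", "a1", "a2"):
            prots[pid] = ProteinRecord(id=pid, sequence=seq)
        link = synteny_link(ra, rb, ga, gb, prots)
        assert link.n_homologs == 1
        assert not link.syntenic


class TestSyntenyMatrix:
    def test_single_cluster_empty_table(self, rng):
        genes, fam = make_chromosome("." * 12 + "F" * 5 + "." * 12)
        cluster = detect_clusters(genes, fam)[0]
        proteins = {
            g.protein_id: ProteinRecord(
                id=g.protein_id, sequence="".join(rng.choice(list(AMINO_ACIDS), 80))
            )
            for g in genes
        }
        assert synteny_matrix([("g", cluster)], {"g": genes}, proteins) == []

    def test_planted_duplication_detected_control_rejected(self, small_dataset):
        ds = small_dataset
        t1 = {t.gene_id for t in ds.truth if t.lineage == "T1"}
        clusters = detect_clusters(ds.genes, t1)
        proteins = {p.id: p for p in ds.proteins}
        links = synteny_matrix(
            [("syn", c) for c in clusters], {"syn": ds.genes}, proteins
        )
        by_pair = {
            frozenset((l.region_a.anchor_id, l.region_b.anchor_id)): l for l in links
        }
        dup = next(c for c in clusters if c.chrom == "chr2")
        orig = next(c for c in clusters if c.chrom == "chr1" and c.size == dup.size)
        control = next(c for c in clusters if c.chrom == "chr3")
        assert by_pair[frozenset((orig.cluster_id, dup.cluster_id))].syntenic
        for l in links:
            if control.cluster_id in (l.region_a.anchor_id, l.region_b.anchor_id):
                assert not l.syntenic
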