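"""Tandem gene clusters, T1-rich genomes, and the 3-of-10 microsynteny rule.

A tandem cluster is a maximal run of family genes on one chromosome in which
consecutive family members are separated by at most ``max_intervening``
non-family genes; runs smaller than ``min_size`` are discarded.  Two genomic
neighbourhoods (the 10 genes on each side of an anchor gene or cluster) are
*syntenic* when a one-to-one matching under the protein-level homology
criterion pairs at least three of their genes — one tandem array cannot
satisfy the rule by multi-mapping.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import maximum_bipartite_matching

from .io_core import GeneModel, ProteinRecord
from .sequence_metrics import global_align

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneCluster:
    """A tandem array of family genes on one chromosome."""

    cluster_id: str
    chrom: str
    members: tuple[str, ...]        # gene ids ordered by ordinal
    span: tuple[int, int]           # (min start, max end), 1-based inclusive
    ordinal_span: tuple[int, int]   # (min ordinal, max ordinal)

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class Region:
    """A neighbourhood around an anchor: the flanking genes of a cluster."""

    genome: str
    chrom: str
    anchor_id: str
    neighbor_gene_ids: tuple[str, ...]


@dataclass(frozen=True)
class SyntenyLink:
    region_a: Region
    region_b: Region
    homolog_pairs: tuple[tuple[str, str], ...]
    syntenic: bool

    @property
    def n_homologs(self) -> int:
        return len(self.homolog_pairs)


def detect_clusters(
    genes: Sequence[GeneModel],
    family_gene_ids: Iterable[str],
    min_size: int = 3,
    max_intervening: int = 5,
) -> list[GeneCluster]:
    """Find maximal tandem runs of family genes.

    Consecutive family members of a run are separated by at most
    ``max_intervening`` non-family genes (by ordinal); runs shorter than
    ``min_size`` are dropped.  Every family gene belongs to at most one
    cluster (the runs partition the family genes on each chromosome).
    """
    family = set(family_gene_ids)
    clusters: list[GeneCluster] = []
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    n_cluster = 0
    for chrom in sorted(by_chrom):
        chrom_genes = sorted(by_chrom[chrom], key=lambda g: g.ordinal)
        fam = [g for g in chrom_genes if g.gene_id in family]
        run: list[GeneModel] = []
        runs: list[list[GeneModel]] = []
        for g in fam:
            if run and g.ordinal - run[-1].ordinal - 1 > max_intervening:
                runs.append(run)
                run = []
            run.append(g)
        if run:
            runs.append(run)
        for r in runs:
            if len(r) < min_size:
                continue
            n_cluster += 1
            clusters.append(
                GeneCluster(
                    cluster_id=f"cluster{n_cluster:03d}_{chrom}",
                    chrom=chrom,
                    members=tuple(g.gene_id for g in r),
                    span=(min(g.start for g in r), max(g.end for g in r)),
                    ordinal_span=(r[0].ordinal, r[-1].ordinal),
                )
            )
    return clusters


def flag_t1_rich(t1_gene_count: int, threshold: int = 15) -> bool:
    """A genome is T1-rich when it carries at least ``threshold`` T1 genes."""
    if t1_gene_count < 0:
        raise ValueError("count must be >= 0")
    return t1_gene_count >= threshold


def neighborhood(
    genes: Sequence[GeneModel],
    anchor: GeneModel | GeneCluster,
    n: int = 10,
) -> list[GeneModel]:
    """The ``n`` genes on each side of the anchor's ordinal span.

    Anchor (or cluster member) genes are excluded; fewer genes are returned
    near chromosome ends.  Order is by ordinal.
    """
    if isinstance(anchor, GeneCluster):
        chrom = anchor.chrom
        lo, hi = anchor.ordinal_span
        excluded = set(anchor.members)
    else:
        chrom = anchor.chrom
        lo = hi = anchor.ordinal
        excluded = {anchor.gene_id}
    chrom_genes = sorted(
        (g for g in genes if g.chrom == chrom), key=lambda g: g.ordinal
    )
    out = [
        g
        for g in chrom_genes
        if (lo - n <= g.ordinal < lo or hi < g.ordinal <= hi + n)
        and g.gene_id not in excluded
    ]
    return out


def homologous(
    a: ProteinRecord,
    b: ProteinRecord,
    sim_threshold: float = 50.0,
    cov_threshold: float = 0.5,
) -> bool:
    """Protein-level homology: global similarity and coverage thresholds.

    True iff percent similarity (terminal gaps excluded) ≥ ``sim_threshold``
    and the aligned residue-to-residue columns cover at least
    ``cov_threshold`` of the shorter sequence.
    """
    aln = global_align(a, b)
    aligned_cols = sum(
        1 for x, y in zip(aln.aligned_a, aln.aligned_b) if x != "-" and y != "-"
    )
    coverage = aligned_cols / min(a.length, b.length)
    return aln.similarity >= sim_threshold and coverage >= cov_threshold


def _count_homolog_pairs(
    genes_a: Sequence[GeneModel],
    genes_b: Sequence[GeneModel],
    proteins: Mapping[str, ProteinRecord],
    sim_threshold: float,
    cov_threshold: float,
) -> list[tuple[str, str]]:
    """One-to-one homolog pairing via maximum bipartite matching."""
    na, nb = len(genes_a), len(genes_b)
    if na == 0 or nb == 0:
        return []
    adj = np.zeros((na, nb), dtype=bool)
    for i, ga in enumerate(genes_a):
        pa = proteins.get(ga.protein_id)
        if pa is None:
            continue
        for j, gb in enumerate(genes_b):
            pb = proteins.get(gb.protein_id)
            if pb is None:
                continue
            adj[i, j] = homologous(pa, pb, sim_threshold, cov_threshold)
    if not adj.any():
        return []
    match = maximum_bipartite_matching(csr_matrix(adj), perm_type="column")
    pairs = [
        (genes_a[i].gene_id, genes_b[match[i]].gene_id)
        for i in range(na)
        if match[i] != -1
    ]
    return pairs


def synteny_link(
    region_a: Region,
    region_b: Region,
    genes_a: Sequence[GeneModel],
    genes_b: Sequence[GeneModel],
    proteins: Mapping[str, ProteinRecord],
    min_homologs: int = 3,
    sim_threshold: float = 50.0,
    cov_threshold: float = 0.5,
) -> SyntenyLink:
    """Evaluate the microsynteny rule between two neighbourhoods.

    The two neighbour sets are matched one-to-one under the homology
    criterion; the regions are syntenic iff at least ``min_homologs`` pairs
    exist.  Symmetric in its two regions.
    """
    pairs = _count_homolog_pairs(
        genes_a, genes_b, proteins, sim_threshold, cov_threshold
    )
    return SyntenyLink(
        region_a=region_a,
        region_b=region_b,
        homolog_pairs=tuple(sorted(pairs)),
        syntenic=len(pairs) >= min_homologs,
    )


def synteny_matrix(
    clusters: Sequence[tuple[str, GeneCluster]],
    genes_by_genome: Mapping[str, Sequence[GeneModel]],
    proteins: Mapping[str, ProteinRecord],
    neighborhood_size: int = 10,
    min_homologs: int = 3,
    sim_threshold: float = 50.0,
    cov_threshold: float = 0.5,
) -> list[SyntenyLink]:
    """All-vs-all synteny links between cluster neighbourhoods.

    ``clusters`` is a list of (genome, cluster); intra- and inter-genome
    pairs are both evaluated.  The result contains each unordered pair once.
    """
    regions = []
    for genome, cluster in clusters:
        genes = genes_by_genome[genome]
        neigh = neighborhood(genes, cluster, neighborhood_size)
        regions.append(
            (
                Region(
                    genome=genome,
                    chrom=cluster.chrom,
                    anchor_id=cluster.cluster_id,
                    neighbor_gene_ids=tuple(g.gene_id for g in neigh),
                ),
                neigh,
            )
        )
    links = []
    for (ra, na), (rb, nb) in itertools.combinations(regions, 2):
        links.append(
            synteny_link(
                ra, rb, na, nb, proteins, min_homologs, sim_threshold, cov_threshold
            )
        )
    return links


def links_to_rows(links: Iterable[SyntenyLink]) -> list[dict]:
    return [
        {
            "region_a": f"{l.region_a.genome}:{l.region_a.anchor_id}",
            "region_b": f"{l.region_b.genome}:{l.region_b.anchor_id}",
            "n_homologs": l.n_homologs,
            "syntenic": int(l.syntenic),
        }
        for l in links
    ]


def clusters_to_rows(clusters: Iterable[GeneCluster]) -> list[dict]:
    return [
        {
            "cluster_id": c.cluster_id,
            "chrom": c.chrom,
            "size": c.size,
            "start": c.span[0],
            "end": c.span[1],
            "members": ",".join(c.members),
        }
        for c in clusters
    ]
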