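"""Molecular evolution: protein-guided codon alignment, Nei–Gojobori (1986)
Ka/Ks, p-distances, neighbour-joining trees and Felsenstein bootstrap.

The NG86 estimator counts synonymous (S) and nonsynonymous (N) *sites* per
codon as the fraction of the nine single-nucleotide mutants that preserve the
encoded amino acid (mutations to stop codons count as nonsynonymous, so
N + S = 3 per codon exactly), and synonymous/nonsynonymous *differences*
between a codon pair by averaging over every minimal mutational pathway;
pathways passing through a stop codon are excluded and the average
renormalised (if every pathway is blocked, all are used).  Proportions are
corrected with the Jukes–Cantor formula d = −3/4·ln(1 − 4p/3).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from Bio.Data import CodonTable

logger = logging.getLogger(__name__)

_STANDARD = CodonTable.unambiguous_dna_by_id[1]
CODON_TO_AA = dict(_STANDARD.forward_table)
STOP_CODONS = set(_STANDARD.stop_codons)
BASES = "ACGT"


def translate_codon(codon: str) -> str | None:
    """Amino acid for a codon, '*' for stop, None for ambiguous codons."""
    if codon in STOP_CODONS:
        return "*"
    return CODON_TO_AA.get(codon)


# ---------------------------------------------------------------------------
# Codon alignment (pal2nal behaviour)


@dataclass(frozen=True)
class CodonAlignment:
    """Two gapped coding sequences in aligned codon columns.

    Each column is a 3-character codon or ``---`` (a protein gap expanded to
    a 3-nt gap).
    """

    codons_a: tuple[str, ...]
    codons_b: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.codons_a) != len(self.codons_b):
            raise ValueError("codon rows differ in length")

    def ungapped_pairs(self) -> list[tuple[str, str]]:
        return [
            (a, b)
            for a, b in zip(self.codons_a, self.codons_b)
            if a != "---" and b != "---"
        ]


def _prepare_cds(cds: str, protein_ungapped: str, which: str) -> str:
    cds = cds.upper().replace("U", "T")
    if len(cds) == 3 * len(protein_ungapped) + 3 and cds[-3:] in STOP_CODONS:
        cds = cds[:-3]  # trailing stop codon tolerated and trimmed
    if len(cds) != 3 * len(protein_ungapped):
        raise ValueError(
            f"CDS {which}: length {len(cds)} != 3 x protein length "
            f"{len(protein_ungapped)}"
        )
    for i, aa in enumerate(protein_ungapped):
        codon = cds[3 * i : 3 * i + 3]
        trans = translate_codon(codon)
        if aa == "X":
            continue
        if trans != aa:
            raise ValueError(
                f"CDS {which}: translation mismatch at residue {i} "
                f"({codon} -> {trans}, expected {aa})"
            )
    return cds


def back_translate(
    aligned_protein_a: str,
    aligned_protein_b: str,
    cds_a: str,
    cds_b: str,
) -> CodonAlignment:
    """Expand an aligned protein pair to a codon alignment of its CDSs.

    Every protein gap column becomes a 3-nt gap; every residue column becomes
    its source codon.  The CDSs must translate to the ungapped proteins
    (a trailing stop codon is trimmed); a mismatch raises an error naming the
    residue position.
    """
    if len(aligned_protein_a) != len(aligned_protein_b):
        raise ValueError("aligned proteins differ in length")
    ung_a = aligned_protein_a.replace("-", "")
    ung_b = aligned_protein_b.replace("-", "")
    cds_a = _prepare_cds(cds_a, ung_a, "A")
    cds_b = _prepare_cds(cds_b, ung_b, "B")
    out_a, out_b = [], []
    ia = ib = 0
    for ra, rb in zip(aligned_protein_a, aligned_protein_b):
        if ra == "-":
            out_a.append("---")
        else:
            out_a.append(cds_a[3 * ia : 3 * ia + 3])
            ia += 1
        if rb == "-":
            out_b.append("---")
        else:
            out_b.append(cds_b[3 * ib : 3 * ib + 3])
            ib += 1
    return CodonAlignment(tuple(out_a), tuple(out_b))


# ---------------------------------------------------------------------------
# NG86


def synonymous_site_fraction(codon: str) -> float:
    """Synonymous sites of one codon: Σ_pos (#synonymous of 3 mutants)/3.

    Mutations producing stop codons count as nonsynonymous, keeping
    N + S = 3 per codon.
    """
    aa = translate_codon(codon)
    if aa is None or aa == "*":
        raise ValueError(f"cannot count sites of codon {codon!r}")
    s = 0.0
    for pos in range(3):
        for base in BASES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            if translate_codon(mutant) == aa:
                s += 1 / 3
    return s


def _pathway_counts(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Synonymous/nonsynonymous differences averaged over minimal pathways."""
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_pos:
        return 0.0, 0.0
    all_paths: list[tuple[float, float]] = []
    open_paths: list[tuple[float, float]] = []
    for order in itertools.permutations(diff_pos):
        current = codon_a
        sd = nd = 0.0
        blocked = False
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            aa_from, aa_to = translate_codon(current), translate_codon(nxt)
            if aa_to == "*" or aa_from == "*":
                blocked = True
            if aa_from == aa_to:
                sd += 1
            else:
                nd += 1
            current = nxt
        all_paths.append((sd, nd))
        if not blocked:
            open_paths.append((sd, nd))
    paths = open_paths if open_paths else all_paths
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    return sd, nd


def jukes_cantor(p: float) -> float | None:
    """JC69 distance d = −3/4 ln(1 − 4p/3); None when p ≥ 3/4."""
    if p < 0:
        raise ValueError("proportion must be non-negative")
    if p >= 0.75:
        return None
    return -0.75 * math.log(1 - 4 * p / 3)


@dataclass(frozen=True)
class KaKsResult:
    """NG86 estimates for one aligned coding-sequence pair."""

    S: float
    N: float
    Sd: float
    Nd: float
    ps: float
    pn: float
    ks: float | None
    ka: float | None
    ratio: float | None
    n_codons: int
    n_skipped: int
    flags: tuple[str, ...] = ()
    model: str = "NG86"


def ng86_kaks(alignment: CodonAlignment) -> KaKsResult:
    """Nei–Gojobori Ka/Ks from a pairwise codon alignment.

    Codon columns containing gaps, ambiguity characters or stop codons are
    skipped (and counted in ``n_skipped``).  The ratio is None when Ks is
    zero or undefined.
    """
    S = N = Sd = Nd = 0.0
    n_codons = n_skipped = 0
    for ca, cb in zip(alignment.codons_a, alignment.codons_b):
        if ca == "---" or cb == "---":
            n_skipped += 1
            continue
        aa_a, aa_b = translate_codon(ca), translate_codon(cb)
        if aa_a in (None, "*") or aa_b in (None, "*"):
            n_skipped += 1
            continue
        n_codons += 1
        S += (synonymous_site_fraction(ca) + synonymous_site_fraction(cb)) / 2
        sd, nd = _pathway_counts(ca, cb)
        Sd += sd
        Nd += nd
    N = 3 * n_codons - S
    if n_codons == 0:
        raise ValueError("no comparable codon pairs")
    ps = Sd / S if S > 0 else 0.0
    pn = Nd / N if N > 0 else 0.0
    flags = []
    ks = jukes_cantor(ps)
    ka = jukes_cantor(pn)
    if ks is None:
        flags.append("ks_saturated")
    if ka is None:
        flags.append("ka_saturated")
    ratio = None
    if ks is not None and ka is not None:
        if ks == 0.0:
            flags.append("ks_zero")
        else:
            ratio = ka / ks
    return KaKsResult(
        S=S, N=N, Sd=Sd, Nd=Nd, ps=ps, pn=pn, ks=ks, ka=ka, ratio=ratio,
        n_codons=n_codons, n_skipped=n_skipped, flags=tuple(flags),
    )


# ---------------------------------------------------------------------------
# Distances


@dataclass(frozen=True)
class DistanceMatrix:
    labels: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("matrix is not symmetric")
        if not np.allclose(np.diag(m), 0.0, atol=1e-12):
            raise ValueError("diagonal must be zero")
        if not np.isfinite(m).all() or (m < -1e-12).any():
            raise ValueError("entries must be finite and non-negative")
        object.__setattr__(self, "matrix", m)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.matrix[i, j])


def p_distance_matrix(
    rows: Mapping[str, str] | Sequence[tuple[str, str]]
) -> DistanceMatrix:
    """Pairwise proportion of differing sites over gap-free columns."""
    items = list(rows.items()) if isinstance(rows, Mapping) else list(rows)
    labels = tuple(lab for lab, _ in items)
    seqs = [s for _, s in items]
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError("aligned rows must have equal length")
    n = len(seqs)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            comp = diff = 0
            for a, b in zip(seqs[i], seqs[j]):
                if a == "-" or b == "-":
                    continue
                comp += 1
                if a != b:
                    diff += 1
            if comp == 0:
                raise ValueError(
                    f"no comparable columns between {labels[i]!r} and {labels[j]!r}"
                )
            m[i, j] = m[j, i] = diff / comp
    return DistanceMatrix(labels, m)


# ---------------------------------------------------------------------------
# Trees


class PhyloTree:
    """An unrooted tree stored with an arbitrary internal root.

    Internal nodes are integers, leaves are taxon labels (strings).  Branch
    lengths are attached to the child end of each edge; bootstrap supports
    (in [0, 1]) may be attached to internal nodes.
    """

    def __init__(self) -> None:
        self.children: dict[int, list[str | int]] = {}
        self.branch_length: dict[str | int, float] = {}
        self.support: dict[int, float] = {}
        self.root: int | None = None
        self._counter = 0

    # -- construction -------------------------------------------------------

    def add_internal(self, children: Sequence[str | int], lengths: Sequence[float]) -> int:
        node = self._counter
        self._counter += 1
        self.children[node] = list(children)
        for ch, ln in zip(children, lengths):
            if ln < 0:
                if ln < -1e-9:  # true negative NJ estimate, not float noise
                    logger.warning("negative branch length %.4g clamped to 0", ln)
                ln = 0.0
            self.branch_length[ch] = float(ln)
        self.root = node
        return node

    # -- queries ------------------------------------------------------------

    @property
    def leaves(self) -> list[str]:
        out: list[str] = []

        def walk(node: str | int) -> None:
            if isinstance(node, str):
                out.append(node)
            else:
                for ch in self.children[node]:
                    walk(ch)

        walk(self.root)
        return sorted(out)

    def merge_order(self) -> list[tuple[int, list[str | int]]]:
        """Internal nodes with their children, in creation (post-)order."""
        return [(n, self.children[n]) for n in sorted(self.children)]

    def _leafset(self, node: str | int) -> frozenset[str]:
        if isinstance(node, str):
            return frozenset([node])
        out: set[str] = set()
        for ch in self.children[node]:
            out |= self._leafset(ch)
        return frozenset(out)

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial bipartitions, each as the smaller-or-canonical side."""
        all_leaves = frozenset(self.leaves)
        out: set[frozenset[str]] = set()
        for node in self.children:
            if node == self.root:
                continue
            side = self._leafset(node)
            if 1 < len(side) < len(all_leaves) - 1:
                other = all_leaves - side
                out.add(min(side, other, key=lambda s: (len(s), tuple(sorted(s)))))
        return out

    def internal_edges(self) -> list[int]:
        return [n for n in self.children if n != self.root]

    def distance_matrix(self) -> DistanceMatrix:
        """Leaf-to-leaf path-length distances (additivity check)."""
        leaves = self.leaves
        index = {l: i for i, l in enumerate(leaves)}
        n = len(leaves)
        m = np.zeros((n, n))

        def below(node: str | int) -> dict[str, float]:
            if isinstance(node, str):
                return {node: 0.0}
            acc: dict[str, float] = {}
            groups = []
            for ch in self.children[node]:
                d = below(ch)
                ln = self.branch_length.get(ch, 0.0)
                d = {k: v + ln for k, v in d.items()}
                groups.append(d)
                acc.update(d)
            for gi, gj in itertools.combinations(groups, 2):
                for a, da in gi.items():
                    for b, db in gj.items():
                        m[index[a], index[b]] = m[index[b], index[a]] = da + db
            return acc

        below(self.root)
        return DistanceMatrix(tuple(leaves), m)

    # -- newick -------------------------------------------------------------

    def to_newick(self, with_support: bool = True) -> str:
        def fmt(node: str | int) -> str:
            if isinstance(node, str):
                ln = self.branch_length.get(node)
                return node if ln is None else f"{node}:{ln:.6g}"
            inner = ",".join(fmt(ch) for ch in self.children[node])
            label = ""
            if with_support and node in self.support:
                label = f"{self.support[node]:.3f}"
            if node == self.root:
                return f"({inner}){label}"
            ln = self.branch_length.get(node, 0.0)
            return f"({inner}){label}:{ln:.6g}"

        return fmt(self.root) + ";"


def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Saitou–Nei neighbour joining with deterministic tie-breaking.

    Ties in the Q criterion are broken by the lexicographically smallest
    (node, node) name pair.  Negative branch-length estimates are clamped to
    zero (with a warning).  For 3 taxa the closed-form three-point branch
    lengths are returned directly.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("need at least 3 taxa")
    tree = PhyloTree()
    # active nodes: name -> (sort_key, tree_node)
    nodes: list[str | int] = list(dm.labels)
    names: dict[str | int, str] = {l: l for l in dm.labels}
    d: dict[tuple[str | int, str | int], float] = {}
    for i, a in enumerate(dm.labels):
        for j, b in enumerate(dm.labels):
            d[(a, b)] = float(dm.matrix[i, j])

    def dist(a: str | int, b: str | int) -> float:
        return d[(a, b)] if (a, b) in d else d[(b, a)]

    while len(nodes) > 3:
        m = len(nodes)
        r = {a: sum(dist(a, k) for k in nodes if k != a) for a in nodes}
        best_pair = None
        best_q = math.inf
        for a, b in itertools.combinations(nodes, 2):
            q = (m - 2) * dist(a, b) - r[a] - r[b]
            key = tuple(sorted((names[a], names[b])))
            if q < best_q - 1e-12 or (
                abs(q - best_q) <= 1e-12
                and (best_pair is None or key < best_pair[2])
            ):
                best_q = q
                best_pair = (a, b, key)
        a, b, _ = best_pair
        va = 0.5 * dist(a, b) + (r[a] - r[b]) / (2 * (m - 2))
        vb = dist(a, b) - va
        u = tree.add_internal([a, b], [va, vb])
        names[u] = min(names[a], names[b])
        for k in nodes:
            if k == a or k == b:
                continue
            d[(u, k)] = 0.5 * (dist(a, k) + dist(b, k) - dist(a, b))
        nodes = [k for k in nodes if k != a and k != b] + [u]

    x, y, z = sorted(nodes, key=lambda k: names[k])
    dxy, dxz, dyz = dist(x, y), dist(x, z), dist(y, z)
    vx = (dxy + dxz - dyz) / 2
    vy = (dxy + dyz - dxz) / 2
    vz = (dxz + dyz - dxy) / 2
    tree.add_internal([x, y, z], [vx, vy, vz])
    return tree


def bootstrap_support(
    rows: Mapping[str, str] | Sequence[tuple[str, str]],
    n_reps: int = 100,
    seed: int = 0,
) -> PhyloTree:
    """NJ tree with Felsenstein bootstrap supports on internal branches.

    Columns of the protein alignment are resampled with replacement
    ``n_reps`` times; each replicate is rebuilt with NJ and the support of an
    original internal bipartition is the fraction of replicates containing
    it.  With fewer than 4 taxa there are no internal branches and the point
    tree is returned without supports.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    items = list(rows.items()) if isinstance(rows, Mapping) else list(rows)
    labels = [lab for lab, _ in items]
    seqs = [s for _, s in items]
    tree = neighbor_joining(p_distance_matrix(items))
    if len(labels) < 4:
        return tree
    ncol = len(seqs[0])
    rng = np.random.default_rng(seed)
    counts: dict[frozenset[str], int] = {bp: 0 for bp in tree.bipartitions()}
    for _ in range(n_reps):
        cols = rng.integers(0, ncol, size=ncol)
        resampled = [
            (lab, "".join(s[c] for c in cols)) for lab, s in zip(labels, seqs)
        ]
        try:
            rep_tree = neighbor_joining(p_distance_matrix(resampled))
        except ValueError:
            continue  # replicate with an all-gap pair: uninformative
        rep_bp = rep_tree.bipartitions()
        for bp in counts:
            if bp in rep_bp:
                counts[bp] += 1
    for node in tree.internal_edges():
        side = tree._leafset(node)
        all_leaves = frozenset(tree.leaves)
        if not (1 < len(side) < len(all_leaves) - 1):
            continue
        key = min(side, all_leaves - side, key=lambda s: (len(s), tuple(sorted(s))))
        if key in counts:
            tree.support[node] = counts[key] / n_reps
    return tree
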