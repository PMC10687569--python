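"""Log-odds profiles for the 14 conserved Hsp70 domain blocks.

Full-length cytosolic Hsp70 carries 14 conserved sequence blocks in collinear
order: six in the nucleotide-binding domain (NBD), one in the interdomain
linker, one in SBDβ, four in the α-helical lid (SBDα) and two in the
C-terminal domain (CTD).  Each block is represented as a position-specific
log-odds profile (base-2, pseudocounted) built from an aligned, ungapped seed
alignment.  A protein "hits" a block when some window scores at least a fixed
fraction of the block's maximum attainable score — a deterministic,
dataset-independent stand-in for a search E-value cutoff.

Scanning a protein against the block library yields a
:class:`BlockHitPattern`, the evidence vector that drives truncation
subtyping downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io_core import AMINO_ACIDS, ProteinRecord, read_fasta, write_fasta

RESIDUE_INDEX = {r: i for i, r in enumerate(AMINO_ACIDS)}

# canonical block order along the protein
BLOCK_DOMAINS = (
    ("NBD1", "NBD"), ("NBD2", "NBD"), ("NBD3", "NBD"),
    ("NBD4", "NBD"), ("NBD5", "NBD"), ("NBD6", "NBD"),
    ("LNK1", "linker"),
    ("SBDb1", "SBDb"),
    ("SBDa1", "SBDa"), ("SBDa2", "SBDa"), ("SBDa3", "SBDa"), ("SBDa4", "SBDa"),
    ("CTD1", "CTD"), ("CTD2", "CTD"),
)
BLOCK_ORDER = tuple(b for b, _ in BLOCK_DOMAINS)
DOMAIN_OF_BLOCK = dict(BLOCK_DOMAINS)


def encode(sequence: str) -> np.ndarray:
    """Residues → indices 0..19; X (or any non-canonical) → -1."""
    return np.array([RESIDUE_INDEX.get(r, -1) for r in sequence], dtype=np.int64)


@dataclass(frozen=True)
class MotifBlock:
    """One conserved block as a width × 20 log-odds profile (base 2)."""

    block_id: str
    domain: str
    weights: np.ndarray          # (width, 20) log-odds
    background: np.ndarray       # (20,) frequencies
    threshold_fraction: float

    def __post_init__(self) -> None:
        if self.weights.ndim != 2 or self.weights.shape[1] != 20:
            raise ValueError("weights must be (width, 20)")
        if not np.isfinite(self.weights).all():
            raise ValueError("weights must be finite (pseudocounted)")
        if abs(float(self.background.sum()) - 1.0) > 1e-9:
            raise ValueError("background must sum to 1")

    @property
    def width(self) -> int:
        return self.weights.shape[0]

    @property
    def max_score(self) -> float:
        return float(self.weights.max(axis=1).sum())

    @property
    def threshold_score(self) -> float:
        return self.threshold_fraction * self.max_score

    @property
    def consensus(self) -> str:
        return "".join(AMINO_ACIDS[i] for i in self.weights.argmax(axis=1))

    def score_at(self, encoded: np.ndarray, start: int) -> float:
        """Windowed log-odds sum; positions aligned to X score 0."""
        window = encoded[start : start + self.width]
        if len(window) < self.width:
            raise ValueError("window extends past sequence end")
        idx = np.arange(self.width)
        valid = window >= 0
        return float(self.weights[idx[valid], window[valid]].sum())

    def score_all(self, encoded: np.ndarray) -> np.ndarray | None:
        """Window scores at every start offset; None if sequence too short.

        Vectorised: ``scores[s] = sum_i W[i, seq[s+i]]`` with X positions
        contributing 0.
        """
        n = len(encoded) - self.width + 1
        if n <= 0:
            return None
        windows = np.lib.stride_tricks.sliding_window_view(encoded, self.width)
        valid = windows >= 0
        picked = self.weights[np.arange(self.width)[None, :], np.clip(windows, 0, 19)]
        return np.where(valid, picked, 0.0).sum(axis=1)

    def scan(self, encoded: np.ndarray) -> tuple[float, int] | None:
        """Best (score, start) over all offsets; None if sequence too short."""
        scores = self.score_all(encoded)
        if scores is None:
            return None
        best = int(np.argmax(scores))
        return float(scores[best]), best


def build_block(
    seed_sequences: Sequence[str],
    block_id: str,
    domain: str,
    background: np.ndarray | None = None,
    pseudocount: float = 1.0,
    threshold_fraction: float = 0.70,
) -> MotifBlock:
    """Build a log-odds profile from an ungapped, aligned seed block.

    ``weights[i][r] = log2((count_ir + pc·bg_r) / (n + pc) / bg_r)``.
    X in a seed contributes nothing to the counts of its column.
    """
    if len(seed_sequences) < 2:
        raise ValueError("need at least 2 seed sequences")
    widths = {len(s) for s in seed_sequences}
    if len(widths) != 1:
        raise ValueError(f"seed sequences have unequal lengths: {sorted(widths)}")
    (width,) = widths
    if background is None:
        background = np.full(20, 1 / 20)
    counts = np.zeros((width, 20))
    for seq in seed_sequences:
        enc = encode(seq.upper())
        for i, r in enumerate(enc):
            if r >= 0:
                counts[i, r] += 1
    if (counts.sum(axis=1) == 0).any():
        raise ValueError("column consists entirely of X")
    n = len(seed_sequences)
    with np.errstate(divide="ignore"):
        weights = np.log2(
            (counts + pseudocount * background[None, :])
            / (n + pseudocount)
            / background[None, :]
        )
    return MotifBlock(block_id, domain, weights, background, threshold_fraction)


def information_content(frequencies: Sequence[float], alphabet_size: int = 20) -> float:
    """Column information content in bits: log2(A) − entropy."""
    freqs = np.asarray(frequencies, dtype=float)
    if (freqs < 0).any():
        raise ValueError("negative frequency")
    total = freqs.sum()
    if abs(total - 1.0) > 1e-6:
        raise ValueError("frequencies must sum to 1")
    nz = freqs[freqs > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    return float(np.log2(alphabet_size)) - entropy


# ---------------------------------------------------------------------------
# Scanning


@dataclass(frozen=True)
class BlockHit:
    hit: bool
    best_score: float
    best_start: int  # 0-based; -1 when the block could not be scored


@dataclass(frozen=True)
class BlockHitPattern:
    """Per-protein block-hit vector in canonical block order."""

    hits: Mapping[str, BlockHit]
    blocks: Mapping[str, MotifBlock]

    @property
    def n_hits_total(self) -> int:
        return sum(h.hit for h in self.hits.values())

    def domain_hits(self, domain: str) -> int:
        return sum(
            h.hit for b, h in self.hits.items() if DOMAIN_OF_BLOCK[b] == domain
        )

    @property
    def sbda_hits(self) -> int:
        return self.domain_hits("SBDa")

    @property
    def ctd_hits(self) -> int:
        return self.domain_hits("CTD")

    @property
    def nbd_hits(self) -> int:
        return self.domain_hits("NBD")

    @property
    def last_hit_end(self) -> int | None:
        """0-based exclusive end of the last hit block, or None without hits."""
        ends = [
            h.best_start + self.blocks[b].width
            for b, h in self.hits.items()
            if h.hit
        ]
        return max(ends) if ends else None

    @property
    def last_sbda_hit_end(self) -> int | None:
        ends = [
            h.best_start + self.blocks[b].width
            for b, h in self.hits.items()
            if h.hit and DOMAIN_OF_BLOCK[b] == "SBDa"
        ]
        return max(ends) if ends else None

    def bitstring(self) -> str:
        return "".join(
            "1" if self.hits[b].hit else "0" for b in BLOCK_ORDER if b in self.hits
        )


def _order_consistent_hits(
    candidates: dict[str, list[tuple[int, float]]],
    block_ids: Sequence[str],
) -> dict[str, tuple[int, float]]:
    """Pick ≤1 hit per block with non-decreasing starts along canonical order,
    maximising hit count then total score (dynamic programming)."""
    # state: list of (last_start, count, total, assignment)
    best: list[tuple[int, int, float, dict]] = [(-1, 0, 0.0, {})]
    for bid in block_ids:
        nxt = list(best)
        for last, count, total, assign in best:
            for start, score in candidates.get(bid, []):
                if start >= last:
                    nxt.append(
                        (start, count + 1, total + score, {**assign, bid: (start, score)})
                    )
        # prune: keep the Pareto frontier over (last_start, count, total)
        nxt.sort(key=lambda s: (s[0], -s[1], -s[2]))
        pruned: list[tuple[int, int, float, dict]] = []
        for state in nxt:
            if not any(
                p[0] <= state[0] and p[1] >= state[1] and p[2] >= state[2]
                and (p[1], p[2]) != (state[1], state[2])
                for p in pruned
            ):
                pruned.append(state)
        best = pruned
    top = max(best, key=lambda s: (s[1], s[2]))
    return top[3]


def scan_blocks(
    protein: ProteinRecord | str,
    blocks: Sequence[MotifBlock],
    order_constraint: bool = True,
) -> BlockHitPattern:
    """Scan a protein for every block; optionally enforce canonical order.

    Per block, ``best_score`` is the maximum windowed log-odds sum over all
    start offsets (unconstrained).  With the order constraint on, threshold-
    passing windows that cannot be arranged in canonical block order are
    demoted: the final hit set is the order-consistent assignment maximising
    the number of hits, ties broken by total score.
    """
    seq = protein.sequence if isinstance(protein, ProteinRecord) else protein
    if not seq:
        raise ValueError("empty protein")
    enc = encode(seq)
    order = {b: i for i, b in enumerate(BLOCK_ORDER)}
    blocks = sorted(blocks, key=lambda b: order.get(b.block_id, len(order)))
    raw: dict[str, tuple[float, int] | None] = {}
    passing: dict[str, list[tuple[int, float]]] = {}
    for block in blocks:
        scores = block.score_all(enc)
        if scores is None:
            raw[block.block_id] = None
            continue
        best = int(np.argmax(scores))
        raw[block.block_id] = (float(scores[best]), best)
        # threshold-passing offsets, needed for order reconciliation
        (idx,) = np.nonzero(scores >= block.threshold_score)
        passing[block.block_id] = [(int(s), float(scores[s])) for s in idx]
    if order_constraint:
        chosen = _order_consistent_hits(passing, [b.block_id for b in blocks])
    else:
        chosen = {
            bid: max(offs, key=lambda t: t[1])
            for bid, offs in passing.items()
            if offs
        }
    hits: dict[str, BlockHit] = {}
    for block in blocks:
        result = raw[block.block_id]
        if result is None:
            hits[block.block_id] = BlockHit(False, float("-inf"), -1)
            continue
        best_score, best_start = result
        if block.block_id in chosen:
            start, _ = chosen[block.block_id]
            hits[block.block_id] = BlockHit(True, best_score, start)
        else:
            hits[block.block_id] = BlockHit(False, best_score, best_start)
    return BlockHitPattern(hits, {b.block_id: b for b in blocks})


# ---------------------------------------------------------------------------
# C-terminal consensus


@dataclass(frozen=True)
class ConsensusLogo:
    """Consensus string with per-column information content (bits)."""

    consensus: str
    information: tuple[float, ...]
    frequencies: np.ndarray  # (columns, 20)

    def motif_string(self, min_bits: float = 1.0) -> str:
        """Consensus over the maximal trailing run of columns with IC ≥ min_bits."""
        cols = [i for i, ic in enumerate(self.information) if ic >= min_bits]
        if not cols:
            return ""
        # trailing contiguous run (the conserved terminus)
        end = len(self.information)
        run_start = end
        for i in range(end - 1, -1, -1):
            if self.information[i] >= min_bits:
                run_start = i
            else:
                break
        return self.consensus[run_start:end]


def _pairwise_linear_nw(a: str, b: str, match: float = 1.0, mismatch: float = -1.0,
                        gap: float = -2.0) -> tuple[str, str]:
    """Linear-gap global alignment for short segments (guide distances/MSA)."""
    n, m = len(a), len(b)
    score = np.zeros((n + 1, m + 1))
    score[:, 0] = gap * np.arange(n + 1)
    score[0, :] = gap * np.arange(m + 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            d = score[i - 1, j - 1] + (match if a[i - 1] == b[j - 1] else mismatch)
            score[i, j] = max(d, score[i - 1, j] + gap, score[i, j - 1] + gap)
    out_a, out_b = [], []
    i, j = n, m
    while i > 0 or j > 0:
        if i > 0 and j > 0 and score[i, j] == score[i - 1, j - 1] + (
            match if a[i - 1] == b[j - 1] else mismatch
        ):
            out_a.append(a[i - 1]); out_b.append(b[j - 1]); i -= 1; j -= 1
        elif i > 0 and score[i, j] == score[i - 1, j] + gap:
            out_a.append(a[i - 1]); out_b.append("-"); i -= 1
        else:
            out_a.append("-"); out_b.append(b[j - 1]); j -= 1
    return "".join(reversed(out_a)), "".join(reversed(out_b))


def _profile_align(group_a: list[str], group_b: list[str]) -> list[str]:
    """Profile-profile alignment with linear gaps (progressive MSA step)."""
    na, nb = len(group_a[0]), len(group_b[0])

    def col_freq(group: list[str], j: int) -> np.ndarray:
        f = np.zeros(21)  # 20 residues + gap
        for s in group:
            r = s[j]
            f[20 if r == "-" else RESIDUE_INDEX.get(r, 0)] += 1
        return f / len(group)

    fa = [col_freq(group_a, j) for j in range(na)]
    fb = [col_freq(group_b, j) for j in range(nb)]

    def col_score(x: np.ndarray, y: np.ndarray) -> float:
        match = float((x[:20] * y[:20]).sum())
        gap_pen = float(x[20] + y[20])
        return 2.0 * match - 1.0 * (1 - match) - gap_pen

    gap = -2.0
    score = np.zeros((na + 1, nb + 1))
    score[:, 0] = gap * np.arange(na + 1)
    score[0, :] = gap * np.arange(nb + 1)
    for i in range(1, na + 1):
        for j in range(1, nb + 1):
            score[i, j] = max(
                score[i - 1, j - 1] + col_score(fa[i - 1], fb[j - 1]),
                score[i - 1, j] + gap,
                score[i, j - 1] + gap,
            )
    cols: list[tuple[int | None, int | None]] = []
    i, j = na, nb
    while i > 0 or j > 0:
        if i > 0 and j > 0 and abs(
            score[i, j] - (score[i - 1, j - 1] + col_score(fa[i - 1], fb[j - 1]))
        ) < 1e-12:
            cols.append((i - 1, j - 1)); i -= 1; j -= 1
        elif i > 0 and abs(score[i, j] - (score[i - 1, j] + gap)) < 1e-12:
            cols.append((i - 1, None)); i -= 1
        else:
            cols.append((None, j - 1)); j -= 1
    cols.reverse()
    merged: list[str] = []
    for s in group_a:
        merged.append("".join(s[ci] if ci is not None else "-" for ci, _ in cols))
    for s in group_b:
        merged.append("".join(s[cj] if cj is not None else "-" for _, cj in cols))
    return merged


def progressive_msa(segments: Sequence[str]) -> list[str]:
    """Small progressive MSA: p-distance NJ guide tree + linear-gap profiles.

    Intended for short, mostly-colinear segments such as 20-residue C-termini;
    not a general-purpose aligner.
    """
    from .molevo import neighbor_joining, DistanceMatrix

    n = len(segments)
    if n == 1:
        return [segments[0]]
    if n == 2:
        a, b = _pairwise_linear_nw(segments[0], segments[1])
        return [a, b]
    # guide distances from pairwise alignments
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ai, aj = _pairwise_linear_nw(segments[i], segments[j])
            comp = [(x, y) for x, y in zip(ai, aj) if x != "-" and y != "-"]
            p = (
                sum(x != y for x, y in comp) / len(comp) if comp else 1.0
            )
            dist[i, j] = dist[j, i] = p
    labels = [str(i) for i in range(n)]
    tree = neighbor_joining(DistanceMatrix(tuple(labels), dist))
    # progressive merge following the tree's post-order internal nodes
    groups: dict[str, list[str]] = {str(i): [segments[i]] for i in range(n)}
    order = tree.merge_order()
    aligned_of: dict[int, list[str]] = {}
    member_ids: dict[int, list[str]] = {}
    for node_id, children in order:
        child_groups = []
        for ch in children:
            if isinstance(ch, str):
                child_groups.append(groups[ch])
            else:
                child_groups.append(aligned_of[ch])
        acc = child_groups[0]
        for g in child_groups[1:]:
            acc = _profile_align(acc, g)
        aligned_of[node_id] = acc
        ids = []
        for ch in children:
            if isinstance(ch, str):
                ids.append(ch)
            else:
                ids.extend(member_ids[ch])
        member_ids[node_id] = ids
    final_id, = [nid for nid, _ in order[-1:]]
    rows = aligned_of[final_id]
    ids = member_ids[final_id]
    # restore input order
    by_id = dict(zip(ids, rows))
    return [by_id[str(i)] for i in range(n)]


def cterm_consensus(
    proteins: Sequence[ProteinRecord | str], window: int = 20
) -> ConsensusLogo:
    """Consensus logo of the last ``window`` residues of same-form proteins.

    The terminal windows are progressively aligned and summarised as a
    consensus string with per-column information content; high-IC columns
    constitute the reported C-terminal motif.
    """
    if len(proteins) < 2:
        raise ValueError("need at least 2 proteins")
    segs = []
    for p in proteins:
        seq = p.sequence if isinstance(p, ProteinRecord) else p
        segs.append(seq[-window:])
    rows = progressive_msa(segs)
    ncol = len(rows[0])
    freqs = np.zeros((ncol, 20))
    info = []
    consensus = []
    for j in range(ncol):
        col = [r[j] for r in rows if r[j] != "-" and r[j] in RESIDUE_INDEX]
        f = np.zeros(20)
        for r in col:
            f[RESIDUE_INDEX[r]] += 1
        if col:
            f = f / len(col)
        freqs[j] = f
        if col:
            ic = information_content(f) * len(col) / len(rows)  # gap-weighted
            info.append(ic)
            consensus.append(AMINO_ACIDS[int(f.argmax())])
        else:
            info.append(0.0)
            consensus.append("-")
    return ConsensusLogo("".join(consensus), tuple(info), freqs)


# ---------------------------------------------------------------------------
# Block library serialisation


def save_block_library(
    seed_alignments: Mapping[str, Sequence[str]],
    directory: str | Path,
    threshold_fraction: float = 0.70,
) -> None:
    """Write seed alignments (one FASTA per block) plus a manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = []
    for block_id in BLOCK_ORDER:
        if block_id not in seed_alignments:
            continue
        seqs = seed_alignments[block_id]
        recs = [
            ProteinRecord(id=f"{block_id}_seed{i}", sequence=s)
            for i, s in enumerate(seqs)
        ]
        write_fasta(recs, directory / f"{block_id}.faa")
        manifest.append(
            {
                "block_id": block_id,
                "domain": DOMAIN_OF_BLOCK[block_id],
                "threshold_fraction": threshold_fraction,
            }
        )
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))


def load_block_library(
    directory: str | Path,
    pseudocount: float = 1.0,
    background: np.ndarray | None = None,
) -> list[MotifBlock]:
    """Load a block library directory written by :func:`save_block_library`."""
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    blocks = []
    for entry in manifest:
        bid = entry["block_id"]
        seqs = [r.sequence for r in read_fasta(directory / f"{bid}.faa")]
        blocks.append(
            build_block(
                seqs,
                bid,
                entry["domain"],
                background=background,
                pseudocount=pseudocount,
                threshold_fraction=entry["threshold_fraction"],
            )
        )
    order = {b: i for i, b in enumerate(BLOCK_ORDER)}
    blocks.sort(key=lambda b: order[b.block_id])
    return blocks
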