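"""Molecular mass, the 50–90 kDa candidate filter, pairwise alignment and
per-domain percent similarity against a reference panel.

Percent *similarity* counts alignment columns whose residue pair scores
positively under the substitution matrix (BLASTP's "positives" convention);
percent *identity* counts exact matches.  Terminal gap columns are excluded
from both denominators so a truncated query is not penalised twice when its
within-domain similarity is measured.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .io_core import AMINO_ACIDS, ProteinRecord

logger = logging.getLogger(__name__)

# ExPASy average residue masses (Da); total protein mass adds one water.
WATER_MASS = 18.0153
RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886, "C": 103.1388,
    "E": 129.1155, "Q": 128.1307, "G": 57.0519, "H": 137.1411, "I": 113.1594,
    "L": 113.1594, "K": 128.1741, "M": 131.1926, "F": 147.1766, "P": 97.1167,
    "S": 87.0782, "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}

DOMAIN_ORDER = ("NBD", "linker", "SBDb", "SBDa", "CTD")


def protein_mass(record: ProteinRecord | str) -> float:
    """Average molecular mass in Da (sum of residue masses + one water)."""
    seq = record.sequence if isinstance(record, ProteinRecord) else record
    if not seq:
        raise ValueError("empty sequence")
    try:
        return sum(RESIDUE_MASS[r] for r in seq) + WATER_MASS
    except KeyError as exc:
        raise ValueError(f"cannot compute mass: unknown residue {exc}") from None


def mass_filter(
    records: Iterable[ProteinRecord],
    lo: float = 50_000.0,
    hi: float = 90_000.0,
) -> list[ProteinRecord]:
    """Keep records with ``lo <= mass <= hi`` (inclusive bounds)."""
    if not (0 < lo < hi):
        raise ValueError("bounds must satisfy 0 < lo < hi")
    kept, dropped = [], 0
    for rec in records:
        if lo <= protein_mass(rec) <= hi:
            kept.append(rec)
        else:
            dropped += 1
    logger.info("mass_filter: kept %d, dropped %d", len(kept), dropped)
    return kept


# ---------------------------------------------------------------------------
# Pairwise global alignment


@dataclass(frozen=True)
class AlignmentResult:
    """A global alignment with percent identity/similarity.

    ``aligned_a``/``aligned_b`` are equal-length gapped strings.  Identity and
    similarity are percentages over columns between the first and last column
    at which both sequences have begun/not yet ended (terminal gaps excluded);
    internal gap columns stay in the denominator.
    """

    aligned_a: str
    aligned_b: str
    score: float
    identity: float
    similarity: float

    @property
    def columns(self) -> int:
        return len(self.aligned_a)


def _default_aligner(
    matrix_name: str = "BLOSUM62", gap_open: float = 10.0, gap_extend: float = 0.5
) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix_name)
    # Biopython scores the first gap position with open_gap_score and each
    # further position with extend_gap_score: a length-L gap costs
    # open + (L-1)*extend, the EMBOSS convention.
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    return aligner


def _percentages(
    aligned_a: str, aligned_b: str, matrix
) -> tuple[float, float]:
    n = len(aligned_a)
    # exclude terminal gaps: keep columns between the first and last column
    # where both rows carry residues (internal gaps stay in the denominator)
    first = next(
        (i for i in range(n) if aligned_a[i] != "-" and aligned_b[i] != "-"), None
    )
    last = next(
        (i for i in range(n - 1, -1, -1) if aligned_a[i] != "-" and aligned_b[i] != "-"),
        None,
    )
    if first is None:
        return 0.0, 0.0
    ident = simil = denom = 0
    for i in range(first, last + 1):
        ra, rb = aligned_a[i], aligned_b[i]
        denom += 1
        if ra == "-" or rb == "-":
            continue
        if ra == rb:
            ident += 1
            simil += 1
        else:
            try:
                if matrix[ra, rb] > 0:
                    simil += 1
            except (KeyError, IndexError):
                pass
    if denom == 0:
        return 0.0, 0.0
    return 100.0 * ident / denom, 100.0 * simil / denom


def global_align(
    a: str | ProteinRecord,
    b: str | ProteinRecord,
    matrix_name: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> AlignmentResult:
    """Optimal global alignment under affine-gap scoring.

    Deterministic: the first traceback reported by the aligner is used
    (diagonal preferred over vertical over horizontal at score ties).
    """
    seq_a = a.sequence if isinstance(a, ProteinRecord) else a
    seq_b = b.sequence if isinstance(b, ProteinRecord) else b
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    aligner = _default_aligner(matrix_name, gap_open, gap_extend)
    aln = next(iter(aligner.align(seq_a, seq_b)))
    sa, sb = str(aln[0]), str(aln[1])
    identity, similarity = _percentages(sa, sb, aligner.substitution_matrix)
    return AlignmentResult(sa, sb, float(aln.score), identity, similarity)


def align_score(
    a: str, b: str,
    matrix_name: str = "BLOSUM62", gap_open: float = 10.0, gap_extend: float = 0.5,
) -> float:
    """Alignment score only (no traceback); faster for large screens."""
    aligner = _default_aligner(matrix_name, gap_open, gap_extend)
    return float(aligner.score(a, b))


# ---------------------------------------------------------------------------
# Reference panel and per-domain similarity


@dataclass(frozen=True)
class DomainSegmentation:
    """0-based half-open intervals of the five Hsp70 domains on a protein.

    A domain may be absent (``None``).  Present intervals are disjoint and in
    N→C order NBD < linker < SBDβ < SBDα < CTD.
    """

    intervals: Mapping[str, tuple[int, int] | None]

    def __post_init__(self) -> None:
        prev_end = 0
        for name in DOMAIN_ORDER:
            iv = self.intervals.get(name)
            if iv is None:
                continue
            lo, hi = iv
            if not (0 <= lo < hi):
                raise ValueError(f"{name}: bad interval {iv}")
            if lo < prev_end:
                raise ValueError(f"{name}: overlaps/precedes previous domain")
            prev_end = hi

    def __getitem__(self, name: str) -> tuple[int, int] | None:
        return self.intervals.get(name)


@dataclass(frozen=True)
class PanelReference:
    record: ProteinRecord
    form: str
    segmentation: DomainSegmentation


@dataclass(frozen=True)
class ReferencePanel:
    """Full-length Hsp70 references for the four forms with known domains."""

    references: tuple[PanelReference, ...]

    def __post_init__(self) -> None:
        forms = {r.form for r in self.references}
        missing = {"cytosolic", "ER", "mitochondrial", "chloroplast"} - forms
        if missing:
            raise ValueError(f"panel missing forms: {sorted(missing)}")

    def by_form(self, form: str) -> list[PanelReference]:
        return [r for r in self.references if r.form == form]


def _column_map(aligned_ref: str, aligned_query: str) -> list[tuple[int, int | None]]:
    """Map each reference residue position to its aligned query position."""
    out: list[tuple[int, int | None]] = []
    ri = qi = 0
    for cr, cq in zip(aligned_ref, aligned_query):
        if cr != "-":
            out.append((ri, qi if cq != "-" else None))
            ri += 1
        if cq != "-":
            qi += 1
    return out


def domain_similarity(
    query: ProteinRecord,
    reference: PanelReference,
    matrix_name: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
    min_occupancy: float = 0.2,
) -> dict[str, float | None]:
    """Per-domain percent similarity of ``query`` against one reference.

    The reference's domain intervals are projected through a global alignment
    to slice the query.  A domain whose projected query slice covers fewer
    than ``min_occupancy`` of its columns is reported absent (``None``), not
    0 %.  The ``full_length`` entry is the overall percent similarity with
    terminal gaps excluded.
    """
    aln = global_align(query, reference.record, matrix_name, gap_open, gap_extend)
    # alignment order: (query, reference)
    matrix = substitution_matrices.load(matrix_name)
    ref_to_q = _column_map(aln.aligned_b, aln.aligned_a)
    q_seq, r_seq = query.sequence, reference.record.sequence
    out: dict[str, float | None] = {"full_length": aln.similarity}
    for name in DOMAIN_ORDER:
        iv = reference.segmentation[name]
        if iv is None:
            out[name] = None
            continue
        lo, hi = iv
        pairs = [(ri, qi) for ri, qi in ref_to_q if lo <= ri < hi]
        occupied = [(ri, qi) for ri, qi in pairs if qi is not None]
        if not pairs or len(occupied) < min_occupancy * len(pairs):
            out[name] = None
            continue
        simil = 0
        for ri, qi in occupied:
            ra, qa = r_seq[ri], q_seq[qi]
            if ra == qa or (
                ra in AMINO_ACIDS and qa in AMINO_ACIDS and matrix[ra, qa] > 0
            ):
                simil += 1
        out[name] = 100.0 * simil / len(pairs)
    return out


def panel_similarity(
    query: ProteinRecord, panel: ReferencePanel, **kwargs
) -> dict[str, dict[str, float | None]]:
    """Average per-domain similarity against every panel form."""
    result: dict[str, dict[str, float | None]] = {}
    for form in ("cytosolic", "ER", "mitochondrial", "chloroplast"):
        refs = panel.by_form(form)
        per_ref = [domain_similarity(query, r, **kwargs) for r in refs]
        merged: dict[str, float | None] = {}
        for key in ["full_length", *DOMAIN_ORDER]:
            vals = [d[key] for d in per_ref if d.get(key) is not None]
            merged[key] = float(np.mean(vals)) if vals else None
        result[form] = merged
    return result
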