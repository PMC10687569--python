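"""Input/output and run configuration.

The pipeline's atoms are :class:`ProteinRecord` (an amino-acid sequence) and
:class:`GeneModel` (its positioned gene on a chromosome).  External coordinates
follow GFF3 (1-based, inclusive); everything downstream works with gene
*ordinals* — the 0-based rank of a gene along its chromosome by start
coordinate — so interval arithmetic never touches base pairs.

No science lives here.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
VALID_RESIDUES = frozenset(AMINO_ACIDS + "X")


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence.

    ``sequence`` is uppercase over the 20 canonical residues plus ``X``
    (unknown).  ``length`` always equals ``len(sequence)``.
    """

    id: str
    sequence: str
    species: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein {self.id!r}: empty sequence")
        seq = self.sequence.upper()
        bad = set(seq) - VALID_RESIDUES
        if bad:
            raise ValueError(
                f"protein {self.id!r}: invalid residues {sorted(bad)}"
            )
        object.__setattr__(self, "sequence", seq)

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneModel:
    """A gene positioned on a chromosome, linked to its protein.

    ``start``/``end`` are 1-based inclusive (GFF3 convention); ``ordinal`` is
    the 0-based rank of the gene along its chromosome by ascending start.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    protein_id: str
    ordinal: int = -1

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"gene {self.gene_id!r}: start {self.start} > end {self.end}"
            )
        if self.strand not in {"+", "-"}:
            raise ValueError(f"gene {self.gene_id!r}: bad strand {self.strand!r}")


@dataclass
class RunConfig:
    """All tunable thresholds of the pipeline, serialisable to YAML.

    Defaults encode the study conditions: a 50–90 kDa mass window, a 60 %
    nearest-reference similarity floor for form assignment, exact terminal
    motif matching within the last 20 residues, block hits at 70 % of a
    profile's maximum score, tandem clusters of ≥3 family genes with ≤5
    intervening genes, 10-gene flanking neighbourhoods and the 3-homolog
    microsynteny rule.
    """

    mass_lo: float = 50_000.0
    mass_hi: float = 90_000.0
    min_form_similarity: float = 60.0
    cterm_window: int = 20
    cterm_mismatch_budget: int = 0
    block_threshold_fraction: float = 0.70
    min_t1_blocks: int = 6
    min_t1_nbd_blocks: int = 4
    extension_min: int = 40
    st_rich_window: int = 30
    st_rich_fraction: float = 0.4
    min_cluster_size: int = 3
    max_intervening: int = 5
    neighborhood_size: int = 10
    min_synteny_homologs: int = 3
    homolog_min_similarity: float = 50.0
    homolog_min_coverage: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.mass_lo < self.mass_hi):
            raise ValueError("mass window must satisfy 0 < lo < hi")
        if not (0.0 <= self.min_form_similarity <= 100.0):
            raise ValueError("min_form_similarity must be a percentage")
        if not (0.0 < self.block_threshold_fraction <= 1.0):
            raise ValueError("block_threshold_fraction must be in (0, 1]")
        for name in ("cterm_window", "min_cluster_size", "neighborhood_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.max_intervening < 0 or self.cterm_mismatch_budget < 0:
            raise ValueError("counts must be non-negative")
        if not (0.0 < self.st_rich_fraction <= 1.0):
            raise ValueError("st_rich_fraction must be in (0, 1]")
        if not (0.0 < self.homolog_min_coverage <= 1.0):
            raise ValueError("homolog_min_coverage must be in (0, 1]")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path, species: str = "") -> list[ProteinRecord]:
    """Read a protein FASTA file.

    The header token before the first whitespace is the record id.  Sequences
    are uppercased.  Duplicate ids and empty sequences are errors.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(ProteinRecord(id=rec.id, sequence=str(rec.seq), species=species))
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    seqs = [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    SeqIO.write(seqs, str(path), "fasta")


def read_nucleotide_fasta(path: str | Path) -> dict[str, str]:
    """Read a nucleotide FASTA into an id → uppercase sequence mapping."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"empty sequence for {rec.id!r} in {path}")
        out[rec.id] = seq
    return out


# ---------------------------------------------------------------------------
# GFF3


def assign_ordinals(genes: Sequence[GeneModel]) -> list[GeneModel]:
    """Rank genes 0..n-1 per chromosome by ascending start (ties by gene_id)."""
    out: list[GeneModel] = []
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for chrom_genes in by_chrom.values():
        chrom_genes.sort(key=lambda g: (g.start, g.gene_id))
        for i, g in enumerate(chrom_genes):
            out.append(dataclasses.replace(g, ordinal=i))
    out.sort(key=lambda g: (g.chrom, g.ordinal))
    return out


def read_gff3(path: str | Path, protein_attr: str = "protein_id") -> list[GeneModel]:
    """Read gene features from a GFF3 file.

    Each ``gene`` feature must carry an ``ID`` attribute and a protein
    cross-reference attribute (default ``protein_id``).  Genes without the
    cross-reference are skipped with a warning; ordinals are assigned per
    chromosome by ascending start.
    """
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneModel] = []
    skipped = 0
    for feat in db.features_of_type("gene"):
        if protein_attr not in feat.attributes:
            skipped += 1
            continue
        genes.append(
            GeneModel(
                gene_id=feat.id,
                chrom=feat.seqid,
                start=feat.start,
                end=feat.end,
                strand=feat.strand if feat.strand in {"+", "-"} else "+",
                protein_id=feat.attributes[protein_attr][0],
            )
        )
    if skipped:
        logger.warning("read_gff3: skipped %d gene(s) lacking %r", skipped, protein_attr)
    return assign_ordinals(genes)


def write_gff3(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.chrom, g.start, g.gene_id)):
            attrs = f"ID={g.gene_id};protein_id={g.protein_id}"
            fh.write(
                f"{g.chrom}\t.\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )


# ---------------------------------------------------------------------------
# Tables


def write_table(
    rows: Sequence[dict],
    path: str | Path,
    sort_by: str | None = None,
    columns: Sequence[str] | None = None,
) -> None:
    """Write dict rows as a TSV with a header and a deterministic row order.

    Rows are sorted by ``sort_by`` (default: the first key of the schema) so
    that the same row set always produces a byte-identical file.  ``columns``
    supplies the schema when ``rows`` is empty (header-only output).
    """
    if rows:
        cols = list(columns) if columns else list(rows[0].keys())
        df = pd.DataFrame(rows, columns=cols)
        key = sort_by or cols[0]
        df = df.sort_values(key, kind="mergesort").reset_index(drop=True)
    else:
        df = pd.DataFrame(columns=list(columns) if columns else [])
    df.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
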