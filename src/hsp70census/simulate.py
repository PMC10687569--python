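"""Synthetic Hsp70 genome generator with planted truth.

Builds proteomes + gene maps that emulate the statistical structure of the
study inputs: full-length Hsp70s of the four cellular forms with their
conserved C-termini, truncated cytosolic variants realising the T1 Type I–IV
and T2 architectures, tandem T1 gene clusters (a 12/7/5 supercluster on one
chromosome, echoing the largest observed supercluster), a T1-rich genome,
and duplicated gene neighbourhoods that satisfy or violate the 3-of-10
microsynteny rule.  Every generated gene carries a planted label
(:class:`TruthRow`), and everything is keyed to one seed.

Class difficulty is controlled solely by the per-site substitution rate;
indels are not simulated — the truncations themselves are the indels of
interest.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .io_core import (
    AMINO_ACIDS,
    GeneModel,
    ProteinRecord,
    assign_ordinals,
    write_fasta,
    write_gff3,
)
from .motif_profiles import (
    BLOCK_DOMAINS,
    MotifBlock,
    build_block,
    save_block_library,
    scan_blocks,
)
from .sequence_metrics import DomainSegmentation, PanelReference, ReferencePanel

AA = np.array(list(AMINO_ACIDS))

# codons per amino acid, for seeded reverse translation
_CODONS_BY_AA: dict[str, list[str]] = {}
from .molevo import CODON_TO_AA  # noqa: E402

for codon, aa in sorted(CODON_TO_AA.items()):
    _CODONS_BY_AA.setdefault(aa, []).append(codon)

# Architecture layout (all lengths in residues).  Block widths are sized so
# that, at the study's 5 % per-site substitution rate and the default 0.70
# score-fraction threshold, the subtype-critical SBDα blocks are missed with
# probability < 0.5 % each; narrower blocks (linker) are not subtype-critical.
BLOCK_WIDTHS = {
    "NBD": 24, "linker": 12, "SBDb": 24, "SBDa": 32, "CTD": 20,
}
LEAD_LEN = 10
NBD_SPACER = 40
LINKER_FLANKS = (10, 6)
SBDB_FLANKS = (10, 30)
SBDA_SPACER = 5
CTD_LAYOUT = (6, 4, 4)  # spacer, inter-block spacer, pre-terminus spacer
T2_BLOCK_SCRAMBLE = 0.45
T2_ST_HEAD = 20
T2_EXTENSION = 45
TYPE4_EXTENSION = 60
FORM_TERMINI = {
    "cytosolic": "GPKIEEVD",
    "ER": "HDEL",
    "mitochondrial": "EAEYEEVKK",
    "chloroplast": "DVIDADFTDSK",
}
MINIMAL_MOTIFS = {
    "cytosolic": "EEVD",
    "ER": "HDEL",
    "mitochondrial": "EEVKK",
    "chloroplast": "TDSK",
}

CLASSES = (
    "FL_cytosolic", "FL_ER", "FL_mitochondrial", "FL_chloroplast",
    "T1_I", "T1_II", "T1_III", "T1_IV", "T2",
)


@dataclass
class GeneratorConfig:
    """Study conditions of the synthetic genome.

    Defaults: 100 instances per class at 5 % per-site substitution, a 12/7/5
    tandem T1 supercluster, one duplicated neighbourhood (synteny positive)
    and one shuffled-flank control (synteny negative), on 5 chromosomes.
    """

    counts: dict = field(default_factory=lambda: {c: 100 for c in CLASSES})
    substitution_rate: float = 0.05
    cluster_sizes: tuple = (12, 7, 5)
    plant_synteny: bool = True
    flank_mutation_rate: float = 0.02
    n_chromosomes: int = 5
    background_length: tuple = (150, 400)
    species: str = "synthetica"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.substitution_rate < 0.5):
            raise ValueError("substitution rate must be in [0, 0.5)")
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("counts must be >= 0")
        unknown = set(self.counts) - set(CLASSES)
        if unknown:
            raise ValueError(f"unknown classes: {sorted(unknown)}")
        if self.cluster_sizes and self.counts.get("T1_II", 0) < sum(
            self.cluster_sizes
        ):
            raise ValueError(
                "cluster sizes exceed the number of Type II instances"
            )


@dataclass(frozen=True)
class TruthRow:
    gene_id: str
    protein_id: str
    species: str
    form: str
    length_class: str
    lineage: str
    subtype: str
    cluster_id: str = ""
    synteny_partner: str = ""
    n_mutations: int = 0


@dataclass
class Archetypes:
    """Fixed ancestral sequences plus the block library and reference panel."""

    full_length: dict            # form -> sequence
    t1: dict                     # subtype -> sequence
    t2: str
    segmentation: DomainSegmentation
    blocks: list
    seed_alignments: dict        # block_id -> list of seed sequences
    panel: ReferencePanel


@dataclass
class Dataset:
    proteins: list
    cds: dict                    # protein_id -> coding sequence
    genes: list
    truth: list                  # list[TruthRow]
    archetypes: Archetypes
    config: GeneratorConfig

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(t) for t in self.truth])


# ---------------------------------------------------------------------------
# Primitive generators


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(AA[rng.integers(0, 20, size=length)])


def mutate(
    sequence: str,
    rate: float,
    rng: np.random.Generator | int,
    protected: Sequence[int] = (),
) -> tuple[str, int]:
    """I.i.d. per-site substitution to a uniform different residue.

    ``protected`` positions (e.g. the minimal C-terminal motif of a
    full-length class) are never touched.  Returns (sequence, #substitutions).
    """
    if not (0 <= rate < 0.5):
        raise ValueError("rate must be in [0, 0.5)")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    seq = np.array(list(sequence))
    hit = rng.random(len(seq)) < rate
    for p in protected:
        hit[p] = False
    n = int(hit.sum())
    for i in np.nonzero(hit)[0]:
        choices = [a for a in AMINO_ACIDS if a != seq[i]]
        seq[i] = choices[rng.integers(0, len(choices))]
    return "".join(seq), n


def reverse_translate(protein: str, rng: np.random.Generator) -> str:
    """Uniform synonymous-codon back-translation, with a TAA stop appended."""
    codons = []
    for aa in protein:
        options = _CODONS_BY_AA.get(aa)
        if options is None:  # X: arbitrary codon (won't be translated back)
            options = ["NNN"]
        codons.append(options[rng.integers(0, len(options))])
    return "".join(codons) + "TAA"


def descend_cds(
    base_seq: str,
    base_cds: str,
    instance_seq: str,
    rng: np.random.Generator,
    synonymous_rate: float = 0.06,
) -> str:
    """CDS of an instance descended from its archetype's CDS.

    Codons of unmutated residues are inherited from the archetype, each
    redrawn among synonymous options with probability ``synonymous_rate``
    (silent divergence); a mutated residue gets a random codon of its new
    amino acid.  Keeps synonymous divergence between same-class instances
    well below saturation, so tandem-paralog Ka/Ks is measurable.
    """
    assert len(base_seq) == len(instance_seq)
    codons = []
    for i, (a, b) in enumerate(zip(base_seq, instance_seq)):
        if a == b and rng.random() >= synonymous_rate:
            codons.append(base_cds[3 * i : 3 * i + 3])
        else:
            options = _CODONS_BY_AA.get(b, ["NNN"])
            codons.append(options[rng.integers(0, len(options))])
    return "".join(codons) + "TAA"


# ---------------------------------------------------------------------------
# Archetype construction


def _build_body(rng: np.random.Generator) -> tuple[str, dict, DomainSegmentation]:
    """Full-length cytosolic archetype and the positions of its 14 blocks."""
    consensi = {
        bid: random_protein(rng, BLOCK_WIDTHS[dom]) for bid, dom in BLOCK_DOMAINS
    }
    parts: list[str] = [random_protein(rng, LEAD_LEN)]
    pos = LEAD_LEN
    starts: dict[str, int] = {}

    def add(text: str) -> None:
        nonlocal pos
        parts.append(text)
        pos += len(text)

    nbd_start = pos
    for i in range(1, 7):
        add(random_protein(rng, NBD_SPACER))
        starts[f"NBD{i}"] = pos
        add(consensi[f"NBD{i}"])
    nbd_end = pos
    add(random_protein(rng, LINKER_FLANKS[0]))
    linker_start = pos - LINKER_FLANKS[0]
    starts["LNK1"] = pos
    add(consensi["LNK1"])
    add(random_protein(rng, LINKER_FLANKS[1]))
    linker_end = pos
    add(random_protein(rng, SBDB_FLANKS[0]))
    starts["SBDb1"] = pos
    add(consensi["SBDb1"])
    add(random_protein(rng, SBDB_FLANKS[1]))
    sbdb_end = pos
    sbda_start = pos
    for i in range(1, 5):
        add(random_protein(rng, SBDA_SPACER))
        starts[f"SBDa{i}"] = pos
        add(consensi[f"SBDa{i}"])
    sbda_end = pos
    add(random_protein(rng, CTD_LAYOUT[0]))
    starts["CTD1"] = pos
    add(consensi["CTD1"])
    add(random_protein(rng, CTD_LAYOUT[1]))
    starts["CTD2"] = pos
    add(consensi["CTD2"])
    add(random_protein(rng, CTD_LAYOUT[2]))
    add(FORM_TERMINI["cytosolic"])
    pos += 0
    body = "".join(parts)
    seg = DomainSegmentation(
        {
            "NBD": (nbd_start, nbd_end),
            "linker": (linker_start, linker_end),
            "SBDb": (linker_end, sbdb_end),
            "SBDa": (sbda_start, sbda_end),
            "CTD": (sbda_end, len(body)),
        }
    )
    info = {"consensi": consensi, "starts": starts,
            "sbda_end": sbda_end, "sbdb_end": sbdb_end}
    return body, info, seg


def _scramble_region(
    seq: str, lo: int, hi: int, rate: float, rng: np.random.Generator
) -> str:
    """Redraw each position with probability ``rate`` (no upper cap: this is
    divergence construction, not a substitution process)."""
    region = list(seq[lo:hi])
    for i in range(len(region)):
        if rng.random() < rate:
            choices = [a for a in AMINO_ACIDS if a != region[i]]
            region[i] = choices[rng.integers(0, len(choices))]
    return seq[:lo] + "".join(region) + seq[hi:]


def build_archetypes(
    seed: int,
    threshold_fraction: float = 0.70,
    seed_copies: int = 10,
    seed_mutation: float = 0.02,
) -> Archetypes:
    """Build the ancestral sequences, the block library and the panel.

    Construction guarantees: the full-length cytosolic archetype hits all 14
    blocks in canonical order; the Type III archetype has no SBDα/CTD hits;
    the T2 archetype hits none of the 14 blocks (verified at build time by
    scanning, with re-scrambling until the guarantee holds).
    """
    rng = np.random.default_rng(seed)
    body, info, seg = _build_body(rng)
    consensi = info["starts"]

    # seed alignments: consensus + lightly mutated copies
    seeds: dict[str, list[str]] = {}
    for bid, dom in BLOCK_DOMAINS:
        start = info["starts"][bid]
        width = BLOCK_WIDTHS[dom]
        block_seq = body[start : start + width]
        variants = [block_seq]
        for _ in range(seed_copies - 1):
            v, _n = mutate(block_seq, seed_mutation, rng)
            variants.append(v)
        seeds[bid] = variants
    blocks = [
        build_block(
            seeds[bid], bid, dom, threshold_fraction=threshold_fraction
        )
        for bid, dom in BLOCK_DOMAINS
    ]

    # other full-length forms: diverged bodies with their own termini
    full_length = {"cytosolic": body}
    for form in ("ER", "mitochondrial", "chloroplast"):
        terminus = FORM_TERMINI[form]
        trunk = body[: len(body) - len(terminus)]
        trunk, _ = mutate(trunk, 0.18, rng)
        full_length[form] = trunk + terminus

    # T1 archetypes (truncated cytosolic)
    sbda_end = info["sbda_end"]
    sbdb_end = info["sbdb_end"]
    type1 = body[:sbda_end]                      # CTD (and EEVD) deleted
    sa2 = info["starts"]["SBDa2"]
    sa3 = info["starts"]["SBDa3"]
    w = BLOCK_WIDTHS["SBDa"]
    for _attempt in range(20):
        type2 = _scramble_region(type1, sa2, sa2 + w, 0.6, rng)
        type2 = _scramble_region(type2, sa3, sa3 + w, 0.6, rng)
        pat = scan_blocks(type2, blocks, order_constraint=True)
        if pat.sbda_hits == 2:  # SBDα1/SBDα4 hit, scrambled middle blocks dead
            break
    else:
        raise RuntimeError("could not scramble an atypical-SBDα archetype")
    type3 = body[:sbdb_end]                      # SBDα and CTD both deleted
    # leucine-rich conserved extension for Type IV
    ext = "".join(
        "L" if rng.random() < 0.45 else AMINO_ACIDS[rng.integers(0, 20)]
        for _ in range(TYPE4_EXTENSION)
    )
    type4 = type2 + ext
    t1 = {"I": type1, "II": type2, "III": type3, "IV": type4}

    # T2: divergent block-free body, S/T-rich head, C-terminal extension
    st_head = "".join(
        "ST"[rng.integers(0, 2)] if rng.random() < 0.7
        else AMINO_ACIDS[rng.integers(0, 20)]
        for _ in range(T2_ST_HEAD)
    )
    t2_ext = random_protein(rng, T2_EXTENSION)
    trunk = body[LEAD_LEN:sbda_end]
    for _attempt in range(20):
        t2_body = trunk
        for bid, dom in BLOCK_DOMAINS:
            start = info["starts"][bid]
            if start + BLOCK_WIDTHS[dom] > sbda_end:
                continue
            lo = start - LEAD_LEN
            t2_body = _scramble_region(
                t2_body, lo, lo + BLOCK_WIDTHS[dom], T2_BLOCK_SCRAMBLE, rng
            )
        candidate = st_head + t2_body + t2_ext
        if scan_blocks(candidate, blocks, order_constraint=False).n_hits_total == 0:
            break
    else:
        raise RuntimeError("could not scramble a block-free T2 archetype")
    t2 = candidate

    panel = ReferencePanel(
        tuple(
            PanelReference(
                record=ProteinRecord(id=f"ref_{form}", sequence=seq, species="panel"),
                form=form,
                segmentation=seg,
            )
            for form, seq in full_length.items()
        )
    )
    return Archetypes(
        full_length=full_length, t1=t1, t2=t2, segmentation=seg,
        blocks=blocks, seed_alignments=seeds, panel=panel,
    )


def _protected_positions(form: str, sequence: str) -> list[int]:
    """Positions of the minimal C-terminal motif, shielded from mutation."""
    minimal = MINIMAL_MOTIFS[form]
    full = FORM_TERMINI[form]
    idx = sequence.rfind(full)
    if idx < 0:
        idx = sequence.rfind(minimal)
        motif = minimal
    else:
        # protect the minimal core within the full terminus
        off = full.rfind(minimal)
        idx = idx + off
        motif = minimal
    return list(range(idx, idx + len(motif)))


# ---------------------------------------------------------------------------
# Genome assembly


def _class_truth(cls: str) -> tuple[str, str, str, str]:
    """(form, length_class, lineage, subtype) for a generator class."""
    if cls.startswith("FL_"):
        return cls[3:], "full_length", "NA", "NA"
    if cls == "T2":
        return "cytosolic", "truncated", "T2", "NA"
    return "cytosolic", "truncated", "T1", cls.split("_")[1]


def _instance(
    cls: str,
    archetypes: Archetypes,
    rate: float,
    rng: np.random.Generator,
) -> tuple[str, int]:
    if cls.startswith("FL_"):
        form = cls[3:]
        base = archetypes.full_length[form]
        protected = _protected_positions(form, base)
    elif cls == "T2":
        base = archetypes.t2
        protected = []
    else:
        base = archetypes.t1[cls.split("_")[1]]
        protected = []
    return mutate(base, rate, rng, protected=protected)


def generate(config: GeneratorConfig) -> Dataset:
    """Generate one synthetic genome with planted Hsp70 biology.

    Gene layout: chromosome 1 carries the tandem T1 supercluster
    (subclusters of the configured sizes, separated by more than
    ``max_intervening`` background genes); chromosome 2 a duplicated copy of
    the first subcluster *with* its flanking genes (microsynteny positive);
    chromosome 3 a copy of the second subcluster with fresh random flanks
    (control, microsynteny negative); remaining instances are scattered with
    enough background genes between T1 genes that no accidental tandem run
    forms.
    """
    rng = np.random.default_rng(config.seed)
    archetypes = build_archetypes(int(rng.integers(0, 2**31 - 1)))
    species = config.species

    proteins: list[ProteinRecord] = []
    cds: dict[str, str] = {}
    truth: list[TruthRow] = []
    chrom_items: dict[str, list[tuple[str, TruthRow | None]]] = {
        f"chr{i + 1}": [] for i in range(config.n_chromosomes)
    }
    n_bg = 0

    def new_background() -> ProteinRecord:
        nonlocal n_bg
        n_bg += 1
        lo, hi = config.background_length
        rec = ProteinRecord(
            id=f"bg{n_bg:05d}",
            sequence=random_protein(rng, int(rng.integers(lo, hi))),
            species=species,
        )
        proteins.append(rec)
        cds[rec.id] = reverse_translate(rec.sequence, rng)
        return rec

    def add_bg(chrom: str, count: int) -> list[str]:
        ids = []
        for _ in range(count):
            rec = new_background()
            chrom_items[chrom].append((rec.id, None))
            ids.append(rec.id)
        return ids

    counters = {c: 0 for c in CLASSES}
    base_seq_of = {
        **{f"FL_{f}": s for f, s in archetypes.full_length.items()},
        **{f"T1_{st}": s for st, s in archetypes.t1.items()},
        "T2": archetypes.t2,
    }
    base_cds_of = {
        cls: reverse_translate(seq, rng)[:-3] for cls, seq in base_seq_of.items()
    }

    def new_instance(cls: str, cluster_id: str = "") -> tuple[ProteinRecord, TruthRow]:
        counters[cls] += 1
        pid = f"{cls}_{counters[cls]:04d}"
        seq, n_mut = _instance(cls, archetypes, config.substitution_rate, rng)
        rec = ProteinRecord(id=pid, sequence=seq, species=species)
        proteins.append(rec)
        cds[pid] = descend_cds(base_seq_of[cls], base_cds_of[cls], seq, rng)
        form, lc, lineage, subtype = _class_truth(cls)
        row = TruthRow(
            gene_id=f"g_{pid}", protein_id=pid, species=species, form=form,
            length_class=lc, lineage=lineage, subtype=subtype,
            cluster_id=cluster_id, n_mutations=n_mut,
        )
        truth.append(row)
        return rec, row

    def add_instance(chrom: str, cls: str, cluster_id: str = "") -> TruthRow:
        rec, row = new_instance(cls, cluster_id)
        chrom_items[chrom].append((rec.id, row))
        return row

    # --- chromosome 1: the tandem supercluster ---------------------------
    cluster_rows: dict[str, list[TruthRow]] = {}
    add_bg("chr1", 12)
    for ci, size in enumerate(config.cluster_sizes):
        cid = f"planted_cluster_{ci + 1}"
        rows = [add_instance("chr1", "T1_II", cluster_id=cid) for _ in range(size)]
        cluster_rows[cid] = rows
        # > max_intervening separates subclusters, and ≥ the neighbourhood
        # size so cluster flanks never reach into the next subcluster
        add_bg("chr1", 12)

    # --- chromosomes 2/3: synteny duplication and shuffled-flank control --
    if config.plant_synteny and config.cluster_sizes:
        cid = "planted_cluster_1"
        flank_rate = config.flank_mutation_rate
        # find the original cluster-1 flanks on chr1 (10 genes each side)
        items = chrom_items["chr1"]
        idx = [i for i, (_pid, row) in enumerate(items)
               if row is not None and row.cluster_id == cid]
        left = [items[i][0] for i in range(max(0, idx[0] - 10), idx[0])]
        right = [items[i][0] for i in range(idx[-1] + 1, idx[-1] + 11)]
        prot_by_id = {p.id: p for p in proteins}

        def copy_flank(src_ids: list[str], chrom: str) -> None:
            for sid in src_ids:
                seq, _ = mutate(prot_by_id[sid].sequence, flank_rate, rng)
                nonlocal_rec = ProteinRecord(
                    id=f"{sid}_dup", sequence=seq, species=species
                )
                proteins.append(nonlocal_rec)
                cds[nonlocal_rec.id] = reverse_translate(seq, rng)
                chrom_items[chrom].append((nonlocal_rec.id, None))

        copy_flank(left, "chr2")
        dup_rows = []
        for src in cluster_rows[cid]:
            row = add_instance("chr2", "T1_II", cluster_id="dup_cluster_1")
            dup_rows.append(row)
        copy_flank(right, "chr2")
        # record the partnership
        for src, dup in zip(cluster_rows[cid], dup_rows):
            i = truth.index(src)
            truth[i] = dataclasses.replace(src, synteny_partner=dup.gene_id)
            j = truth.index(dup)
            truth[j] = dataclasses.replace(dup, synteny_partner=src.gene_id)

        # control: cluster-2 copy with fresh random flanks
        add_bg("chr3", 10)
        for _ in range(config.cluster_sizes[1] if len(config.cluster_sizes) > 1 else 3):
            add_instance("chr3", "T1_II", cluster_id="control_cluster")
        add_bg("chr3", 10)

    # --- scattered instances ---------------------------------------------
    scatter_chroms = [
        f"chr{i + 1}" for i in range(3, config.n_chromosomes)
    ] or ["chr1"]
    t1_classes = ("T1_I", "T1_II", "T1_III", "T1_IV")
    ci = 0
    for cls in CLASSES:
        remaining = config.counts.get(cls, 0) - (
            counters[cls] if cls == "T1_II" else 0
        )
        for _ in range(max(0, remaining)):
            chrom = scatter_chroms[ci % len(scatter_chroms)]
            ci += 1
            # T1 genes need > max_intervening background genes around them so
            # that scattered genes never form accidental tandem runs
            add_bg(chrom, 6 if cls in t1_classes else 1)
            add_instance(chrom, cls)
    for chrom in scatter_chroms:
        add_bg(chrom, 3)

    # --- coordinates ------------------------------------------------------
    genes: list[GeneModel] = []
    seq_of = {p.id: p.sequence for p in proteins}
    for chrom in sorted(chrom_items):
        pos = 1
        for pid, _row in chrom_items[chrom]:
            length = 3 * len(seq_of[pid])
            start = pos + int(rng.integers(500, 2000))
            end = start + length + 3
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(
                GeneModel(
                    gene_id=f"g_{pid}", chrom=chrom, start=start, end=end,
                    strand=strand, protein_id=pid,
                )
            )
            pos = end
    genes = assign_ordinals(genes)
    return Dataset(
        proteins=proteins, cds=cds, genes=genes, truth=truth,
        archetypes=archetypes, config=config,
    )


def write_dataset(dataset: Dataset, directory: str | Path) -> None:
    """Write a self-contained dataset directory (all plain text)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_fasta(dataset.proteins, directory / "proteins.faa")
    with open(directory / "cds.fna", "w") as fh:
        for pid in sorted(dataset.cds):
            fh.write(f">{pid}\n{dataset.cds[pid]}\n")
    write_gff3(dataset.genes, directory / "genes.gff3")
    dataset.truth_frame().to_csv(directory / "truth.tsv", sep="\t", index=False)
    save_block_library(dataset.archetypes.seed_alignments, directory / "blocks")
    panel_records = [r.record for r in dataset.archetypes.panel.references]
    write_fasta(panel_records, directory / "panel.faa")
    seg_rows = []
    for ref in dataset.archetypes.panel.references:
        for dom, iv in ref.segmentation.intervals.items():
            if iv is not None:
                seg_rows.append(
                    {"protein_id": ref.record.id, "form": ref.form,
                     "domain": dom, "start": iv[0], "end": iv[1]}
                )
    pd.DataFrame(seg_rows).to_csv(directory / "panel_domains.tsv", sep="\t", index=False)
    (directory / "config.yaml").write_text(
        yaml.safe_dump(
            {**dataclasses.asdict(dataset.config),
             "cluster_sizes": list(dataset.config.cluster_sizes),
             "background_length": list(dataset.config.background_length)},
            sort_keys=True,
        )
    )


def generate_ortholog_set(
    config: GeneratorConfig, n_genomes: int = 3, divergence: float = 0.03
) -> list[Dataset]:
    """Several genomes sharing an orthologous copy of the planted cluster.

    Genome 0 is ``generate(config)``; each further genome is regenerated with
    a derived seed and its cluster-1 members and flanks replaced by diverged
    copies of genome 0's, so all pairwise neighbourhoods satisfy the
    microsynteny rule.
    """
    base = generate(config)
    rng = np.random.default_rng(config.seed + 7)
    datasets = [base]
    prot_by_id = {p.id: p.sequence for p in base.proteins}
    cluster_ids = [
        t.protein_id for t in base.truth if t.cluster_id == "planted_cluster_1"
    ]
    gene_by_pid = {g.protein_id: g for g in base.genes}
    chrom = gene_by_pid[cluster_ids[0]].chrom
    chrom_genes = sorted(
        (g for g in base.genes if g.chrom == chrom), key=lambda g: g.ordinal
    )
    ords = [gene_by_pid[pid].ordinal for pid in cluster_ids]
    lo, hi = min(ords), max(ords)
    flank = [
        g.protein_id
        for g in chrom_genes
        if lo - 10 <= g.ordinal < lo or hi < g.ordinal <= hi + 10
    ]
    for gi in range(1, n_genomes):
        sp = f"{config.species}_{gi}"
        cfg = dataclasses.replace(
            config, seed=config.seed + 1000 * gi, species=sp
        )
        ds = generate(cfg)
        # overwrite genome gi's cluster-1 members and flanks with orthologs
        own_cluster = [
            t.protein_id for t in ds.truth if t.cluster_id == "planted_cluster_1"
        ]
        own_gene = {g.protein_id: g for g in ds.genes}
        own_chrom = own_gene[own_cluster[0]].chrom
        own_sorted = sorted(
            (g for g in ds.genes if g.chrom == own_chrom), key=lambda g: g.ordinal
        )
        o_ords = [own_gene[pid].ordinal for pid in own_cluster]
        o_lo, o_hi = min(o_ords), max(o_ords)
        own_flank = [
            g.protein_id
            for g in own_sorted
            if o_lo - 10 <= g.ordinal < o_lo or o_hi < g.ordinal <= o_hi + 10
        ]
        replacement = dict(zip(own_cluster, cluster_ids)) | dict(
            zip(own_flank, flank)
        )
        new_proteins = []
        for p in ds.proteins:
            src = replacement.get(p.id)
            if src is None:
                new_proteins.append(p)
            else:
                seq, _ = mutate(prot_by_id[src], divergence, rng)
                new_proteins.append(
                    ProteinRecord(id=p.id, sequence=seq, species=sp)
                )
                ds.cds[p.id] = reverse_translate(seq, rng)
        # namespace ids so genomes can be pooled without collisions
        prefix = f"{sp}."
        ds.proteins = [
            ProteinRecord(id=prefix + p.id, sequence=p.sequence, species=sp)
            for p in new_proteins
        ]
        ds.cds = {prefix + k: v for k, v in ds.cds.items()}
        ds.genes = [
            dataclasses.replace(
                g, gene_id=prefix + g.gene_id, protein_id=prefix + g.protein_id
            )
            for g in ds.genes
        ]
        ds.truth = [
            dataclasses.replace(
                t,
                gene_id=prefix + t.gene_id,
                protein_id=prefix + t.protein_id,
                species=sp,
                synteny_partner=(
                    prefix + t.synteny_partner if t.synteny_partner else ""
                ),
            )
            for t in ds.truth
        ]
        datasets.append(ds)
    return datasets
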