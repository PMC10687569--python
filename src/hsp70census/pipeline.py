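"""One-command orchestration: classify → clusters/synteny → molecular
evolution summaries, with a machine-readable run manifest.

The manifest mirrors the per-species tallies of the study's summary tables:
candidates, mass-filter survivors, per-form counts, truncated counts, T1
subtype histogram, T2 count, clusters and synteny links — all internally
consistent (Σ subtypes + unclassified = T1 total, etc.).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classifier import Hsp70Call, calls_to_rows, classify_all
from .cluster_synteny import (
    clusters_to_rows,
    detect_clusters,
    flag_t1_rich,
    links_to_rows,
    synteny_matrix,
)
from .io_core import (
    ProteinRecord,
    RunConfig,
    read_fasta,
    read_gff3,
    read_nucleotide_fasta,
    read_table,
    write_table,
)
from .molevo import DistanceMatrix, back_translate, neighbor_joining, ng86_kaks
from .motif_profiles import load_block_library
from .sequence_metrics import (
    DomainSegmentation,
    PanelReference,
    ReferencePanel,
    global_align,
)

logger = logging.getLogger(__name__)

CALL_COLUMNS = [
    "protein_id", "species", "form", "length_class", "lineage", "subtype",
    "mass_Da", "form_similarity", "blocks_hit", "sbda_hits", "ctd_hits",
    "extension_len", "st_rich",
]


@dataclass
class RunManifest:
    seed: int
    config: dict
    input_checksums: dict
    stage_counts: dict
    version: str = __version__

    def validate(self) -> None:
        c = self.stage_counts
        forms = sum(v for k, v in c.items() if k.startswith("form_"))
        if forms > c.get("after_dedup", forms):
            raise ValueError("manifest inconsistency: forms exceed dedup survivors")
        t1 = c.get("lineage_T1", 0)
        subtypes = sum(v for k, v in c.items() if k.startswith("subtype_"))
        if subtypes != t1:
            raise ValueError("manifest inconsistency: subtype histogram != T1 total")
        if any(v < 0 for v in c.values()):
            raise ValueError("manifest inconsistency: negative count")

    def write(self, path: str | Path) -> None:
        self.validate()
        Path(path).write_text(
            json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True) + "\n"
        )


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def load_panel(dataset_dir: Path) -> ReferencePanel:
    records = {r.id: r for r in read_fasta(dataset_dir / "panel.faa")}
    seg_table = read_table(dataset_dir / "panel_domains.tsv")
    refs = []
    for (pid, form), group in seg_table.groupby(["protein_id", "form"], sort=True):
        intervals = {
            row["domain"]: (int(row["start"]), int(row["end"]))
            for _, row in group.iterrows()
        }
        refs.append(
            PanelReference(
                record=records[pid], form=form,
                segmentation=DomainSegmentation(intervals),
            )
        )
    return ReferencePanel(tuple(refs))


def run_all(
    dataset_dir: str | Path,
    out_dir: str | Path,
    config: RunConfig | None = None,
) -> RunManifest:
    """Run the full pipeline on a dataset directory.

    Expects ``proteins.faa``, ``genes.gff3``, ``blocks/`` and ``panel.faa`` +
    ``panel_domains.tsv`` (and optionally ``cds.fna`` for Ka/Ks).  Writes
    calls.tsv, clusters.tsv, links.tsv, kaks.tsv, tree.nwk and
    manifest.json (last, so its presence marks a completed run).
    """
    dataset_dir = Path(dataset_dir)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config = config or RunConfig()

    required = ["proteins.faa", "genes.gff3", "panel.faa", "panel_domains.tsv"]
    for name in required:
        if not (dataset_dir / name).exists():
            raise FileNotFoundError(f"missing input file: {dataset_dir / name}")
    checksums = {
        name: _checksum(dataset_dir / name)
        for name in required + (["cds.fna"] if (dataset_dir / "cds.fna").exists() else [])
    }

    proteins = read_fasta(dataset_dir / "proteins.faa")
    genes = read_gff3(dataset_dir / "genes.gff3")
    blocks = load_block_library(
        dataset_dir / "blocks", pseudocount=1.0
    )
    panel = load_panel(dataset_dir)
    locus_of = {g.protein_id: g.gene_id for g in genes}

    calls, counts = classify_all(
        proteins, panel, blocks, config=config, locus_of=locus_of
    )
    write_table(calls_to_rows(calls), out_dir / "calls.tsv",
                sort_by="protein_id", columns=CALL_COLUMNS)

    # clusters of T1 genes
    t1_proteins = {c.protein_id for c in calls if c.lineage == "T1"}
    t1_genes = {g.gene_id for g in genes if g.protein_id in t1_proteins}
    clusters = detect_clusters(
        genes, t1_genes, config.min_cluster_size, config.max_intervening
    )
    write_table(clusters_to_rows(clusters), out_dir / "clusters.tsv",
                sort_by="cluster_id",
                columns=["cluster_id", "chrom", "size", "start", "end", "members"])
    counts["clusters"] = len(clusters)
    counts["t1_rich"] = int(flag_t1_rich(len(t1_proteins)))

    # synteny among cluster neighbourhoods
    species = proteins[0].species if proteins else ""
    prot_map = {p.id: p for p in proteins}
    links = synteny_matrix(
        [(species or "genome", c) for c in clusters],
        {species or "genome": genes},
        prot_map,
        neighborhood_size=config.neighborhood_size,
        min_homologs=config.min_synteny_homologs,
        sim_threshold=config.homolog_min_similarity,
        cov_threshold=config.homolog_min_coverage,
    )
    write_table(links_to_rows(links), out_dir / "links.tsv", sort_by="region_a",
                columns=["region_a", "region_b", "n_homologs", "syntenic"])
    counts["synteny_links"] = sum(l.syntenic for l in links)

    # Ka/Ks between consecutive cluster members (tandem paralog pairs)
    kaks_rows = []
    cds = {}
    if (dataset_dir / "cds.fna").exists():
        cds = read_nucleotide_fasta(dataset_dir / "cds.fna")
    gene_by_id = {g.gene_id: g for g in genes}
    if cds:
        for cluster in clusters:
            for ga, gb in zip(cluster.members, cluster.members[1:]):
                pa = gene_by_id[ga].protein_id
                pb = gene_by_id[gb].protein_id
                if pa not in cds or pb not in cds:
                    continue
                aln = global_align(prot_map[pa], prot_map[pb])
                codon_aln = back_translate(
                    aln.aligned_a, aln.aligned_b, cds[pa], cds[pb]
                )
                r = ng86_kaks(codon_aln)
                kaks_rows.append(
                    {
                        "pair": f"{pa}|{pb}",
                        "S": round(r.S, 3), "N": round(r.N, 3),
                        "Sd": round(r.Sd, 3), "Nd": round(r.Nd, 3),
                        "Ka": "NA" if r.ka is None else round(r.ka, 5),
                        "Ks": "NA" if r.ks is None else round(r.ks, 5),
                        "ratio": "NA" if r.ratio is None else round(r.ratio, 5),
                        "flags": ";".join(r.flags),
                    }
                )
    write_table(kaks_rows, out_dir / "kaks.tsv", sort_by="pair",
                columns=["pair", "S", "N", "Sd", "Nd", "Ka", "Ks", "ratio", "flags"])

    # NJ tree over the panel plus one representative call per class, using
    # alignment-based distances (100 - percent similarity)/100
    reps: dict[str, Hsp70Call] = {}
    for c in calls:
        key = f"{c.form}|{c.length_class}|{c.lineage}|{c.subtype}"
        if c.form != "unclassified" and key not in reps:
            reps[key] = c
    tips: list[ProteinRecord] = [r.record for r in panel.references]
    tips += [prot_map[c.protein_id] for c in reps.values()]
    if len(tips) >= 3:
        n = len(tips)
        m = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                sim = global_align(tips[i], tips[j]).similarity
                m[i, j] = m[j, i] = max(0.0, (100.0 - sim) / 100.0)
        tree = neighbor_joining(
            DistanceMatrix(tuple(t.id for t in tips), m)
        )
        (out_dir / "tree.nwk").write_text(tree.to_newick(with_support=False) + "\n")
    else:
        (out_dir / "tree.nwk").write_text(";\n")

    manifest = RunManifest(
        seed=config.seed,
        config=dataclasses.asdict(config),
        input_checksums=checksums,
        stage_counts={k: int(v) for k, v in sorted(counts.items())},
    )
    manifest.write(out_dir / "manifest.json")
    return manifest


def summarize(calls: pd.DataFrame) -> pd.DataFrame:
    """Per-form / length-class summary across species.

    For each (form, length_class): the min/max/mean gene count over species
    possessing at least one such gene, and the occurrence rate — the
    fraction of all species in the table with at least one.
    """
    if calls.empty:
        return pd.DataFrame(
            columns=["form", "length_class", "min", "max", "mean", "occurrence"]
        )
    species = calls["species"].unique()
    n_species = len(species)
    rows = []
    grouped = calls[calls["form"] != "unclassified"].groupby(
        ["form", "length_class"], sort=True
    )
    for (form, lc), group in grouped:
        per_species = group.groupby("species")["protein_id"].count()
        rows.append(
            {
                "form": form,
                "length_class": lc,
                "min": int(per_species.min()),
                "max": int(per_species.max()),
                "mean": round(float(per_species.mean()), 2),
                "occurrence": round(len(per_species) / n_species, 4),
            }
        )
    return pd.DataFrame(rows)
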