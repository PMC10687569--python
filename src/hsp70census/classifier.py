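"""The core decision procedure: Hsp70 form assignment, full-length vs
truncated calling by conserved C-terminal motifs, T1/T2 lineage assignment
for truncated cytosolic proteins, and T1 subtype (I–IV) typing.

Each eukaryotic Hsp70 form carries a diagnostic C-terminal signature:
``EEVD`` (cytosolic, strictly terminal), ``HDEL`` (ER/Bip, strictly
terminal), ``EEVKK`` (mitochondrial) and ``TDSK`` (chloroplast).  A protein
assigned to a form but lacking its signature in the terminal window is a
*truncated* Hsp70.  Truncated cytosolic proteins split into the T1 lineage
(recognisable conserved blocks, subtyped I–IV by SBDα/CTD loss patterns) and
the divergent T2 lineage (no conserved blocks, an S/T-rich N-terminal region
and a C-terminal extension).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from .io_core import ProteinRecord, RunConfig
from .motif_profiles import BlockHitPattern, MotifBlock, scan_blocks
from .sequence_metrics import (
    ReferencePanel,
    domain_similarity,
    mass_filter,
    protein_mass,
)

logger = logging.getLogger(__name__)

FORMS = ("cytosolic", "ER", "mitochondrial", "chloroplast")
FORM_PRIORITY = {f: i for i, f in enumerate(FORMS)}


@dataclass(frozen=True)
class CtermMotifSpec:
    """Per-form C-terminal motifs: the full consensus and the minimal core.

    ``terminal_forms`` lists forms whose minimal motif must end exactly at
    the final residue; the others may end within ``terminal_slack`` residues
    of the end.
    """

    full: Mapping[str, str] = field(
        default_factory=lambda: {
            "cytosolic": "GPKIEEVD",
            "ER": "HDEL",
            "mitochondrial": "EAEYEEVKK",
            "chloroplast": "DVIDADFTDSK",
        }
    )
    minimal: Mapping[str, str] = field(
        default_factory=lambda: {
            "cytosolic": "EEVD",
            "ER": "HDEL",
            "mitochondrial": "EEVKK",
            "chloroplast": "TDSK",
        }
    )
    window: int = 20
    mismatch_budget: int = 0
    terminal_forms: frozenset = frozenset({"cytosolic", "ER"})
    terminal_slack: int = 3

    def __post_init__(self) -> None:
        for form, mini in self.minimal.items():
            if mini not in self.full.get(form, mini) and form in self.full:
                raise ValueError(f"{form}: minimal motif not within full motif")
            if self.window < len(mini):
                raise ValueError(f"{form}: window shorter than minimal motif")


@dataclass(frozen=True)
class Hsp70Call:
    """Full classification verdict for one protein, with its evidence."""

    protein_id: str
    species: str
    form: str                       # cytosolic/ER/mitochondrial/chloroplast/unclassified
    length_class: str               # full_length / truncated / NA
    lineage: str                    # T1 / T2 / unclassified / NA
    subtype: str                    # I / II / III / IV / unclassified / NA
    mass_da: float
    form_similarity: float
    blocks_bitstring: str = ""
    sbda_hits: int = 0
    ctd_hits: int = 0
    nbd_hits: int = 0
    extension_len: int = -1         # -1: not measurable (no SBDα anchor)
    st_rich: bool = False
    cterm_detail: str = ""

    def __post_init__(self) -> None:
        if self.lineage not in ("NA",) and not (
            self.form == "cytosolic" and self.length_class == "truncated"
        ):
            raise ValueError(
                f"{self.protein_id}: lineage {self.lineage!r} requires a "
                "truncated cytosolic protein"
            )
        if self.subtype != "NA" and self.lineage != "T1":
            raise ValueError(f"{self.protein_id}: subtype requires lineage T1")


# ---------------------------------------------------------------------------
# Stage operations


def classify_form(
    protein: ProteinRecord,
    panel: ReferencePanel,
    min_similarity: float = 60.0,
) -> tuple[str, float]:
    """Nearest-reference form assignment by full-length percent similarity.

    Returns the form of the best-matching panel reference provided its
    similarity reaches ``min_similarity``; otherwise ``("unclassified", best)``.
    Ties are broken by form priority cytosolic > ER > mitochondrial >
    chloroplast.
    """
    best_form, best_sim = "unclassified", 0.0
    for ref in sorted(
        panel.references, key=lambda r: FORM_PRIORITY.get(r.form, 99)
    ):
        sims = domain_similarity(protein, ref)
        sim = sims["full_length"] or 0.0
        if sim > best_sim + 1e-9:
            best_form, best_sim = ref.form, sim
    if best_sim < min_similarity:
        return "unclassified", best_sim
    return best_form, best_sim


def _matches_with_budget(window: str, motif: str, budget: int, anchored_end: bool,
                         slack: int) -> tuple[bool, str]:
    """Substring match of ``motif`` in ``window`` with ≤budget substitutions.

    ``anchored_end``: match must end at the final residue of the window
    (strictly terminal motifs); otherwise it may end within ``slack``
    residues of the end.
    """
    m = len(motif)
    n = len(window)
    if m > n:
        return False, "window shorter than motif"
    if anchored_end:
        starts = [n - m]
    else:
        starts = list(range(max(0, n - m - slack), n - m + 1))
    for s in starts:
        mismatches = sum(1 for a, b in zip(window[s : s + m], motif) if a != b)
        if mismatches <= budget:
            return True, f"match at -{n - s} ({mismatches} mismatch)"
    return False, "no terminal match"


def call_length_class(
    protein: ProteinRecord,
    form: str,
    spec: CtermMotifSpec | None = None,
) -> tuple[str, str]:
    """Full-length iff the form's minimal C-terminal motif is present.

    The minimal motif is searched in the last ``spec.window`` residues with
    at most ``spec.mismatch_budget`` substitutions (no indels).  For strictly
    terminal motifs (EEVD, HDEL) the match must end at the final residue.
    Returns (length_class, detail).
    """
    spec = spec or CtermMotifSpec()
    if form not in spec.minimal:
        raise ValueError(f"no C-terminal motif spec for form {form!r}")
    window = protein.sequence[-spec.window :]
    ok, detail = _matches_with_budget(
        window,
        spec.minimal[form],
        spec.mismatch_budget,
        anchored_end=form in spec.terminal_forms,
        slack=spec.terminal_slack,
    )
    return ("full_length" if ok else "truncated"), detail


def st_rich_flag(
    protein: ProteinRecord | str, window: int = 30, fraction: float = 0.4
) -> bool:
    """True iff some 20-residue window within the first ``window`` residues
    is at least ``fraction`` serine+threonine."""
    seq = protein.sequence if isinstance(protein, ProteinRecord) else protein
    head = seq[:window]
    k = 20
    if len(head) < k:
        st = sum(1 for r in head if r in "ST")
        return len(head) > 0 and st / k >= fraction
    for s in range(len(head) - k + 1):
        st = sum(1 for r in head[s : s + k] if r in "ST")
        if st / k >= fraction:
            return True
    return False


def assign_lineage(
    pattern: BlockHitPattern,
    st_rich: bool,
    extension_present: bool,
    min_t1_blocks: int = 6,
    min_t1_nbd_blocks: int = 4,
) -> str:
    """T1/T2/unclassified call for a truncated cytosolic protein.

    T2: no conserved block hits at all, plus a T2 hallmark (S/T-rich
    N-terminus or a C-terminal extension).  T1: at least ``min_t1_blocks``
    hits including ``min_t1_nbd_blocks`` NBD hits.  Anything else is
    unclassified.
    """
    if pattern.n_hits_total == 0:
        if st_rich or extension_present:
            return "T2"
        return "unclassified"
    if (
        pattern.n_hits_total >= min_t1_blocks
        and pattern.nbd_hits >= min_t1_nbd_blocks
    ):
        return "T1"
    return "unclassified"


def assign_t1_subtype(
    sbda_hits: int, ctd_hits: int, extension_length: int, extension_min: int = 40
) -> str:
    """Subtype a T1 protein from its SBDα/CTD block pattern.

    I: intact SBDα (4 hits), no CTD, no extension — CTD deletion only.
    II: atypical SBDα (1–3 hits), no CTD, no extension.
    III: SBDα and CTD both absent (0 hits each).
    IV: atypical SBDα (1–3 hits) with a C-terminal extension.
    Everything else is unclassified.
    """
    ext = extension_length >= extension_min if extension_length >= 0 else False
    if sbda_hits == 0 and ctd_hits == 0:
        return "III"
    if sbda_hits == 4 and ctd_hits == 0 and not ext:
        return "I"
    if 1 <= sbda_hits <= 3 and ext:
        return "IV"
    if 1 <= sbda_hits <= 3 and ctd_hits == 0 and not ext:
        return "II"
    return "unclassified"


def dedup(
    proteins: Sequence[ProteinRecord],
    locus_of: Mapping[str, str] | None = None,
) -> list[ProteinRecord]:
    """Collapse identical sequences sharing a gene locus (isoform screen).

    Key: (sequence, locus); the lexicographically smallest protein id of a
    duplicate group is kept.  Without locus information, identical sequences
    are assumed to be alternative isoforms of one locus.
    """
    groups: dict[tuple[str, str], list[ProteinRecord]] = {}
    for p in proteins:
        locus = locus_of.get(p.id, p.id) if locus_of is not None else ""
        groups.setdefault((p.sequence, locus), []).append(p)
    kept = [min(g, key=lambda p: p.id) for g in groups.values()]
    kept.sort(key=lambda p: p.id)
    return kept


# ---------------------------------------------------------------------------
# Pipeline composition


def classify_all(
    proteins: Sequence[ProteinRecord],
    panel: ReferencePanel,
    blocks: Sequence[MotifBlock],
    spec: CtermMotifSpec | None = None,
    config: RunConfig | None = None,
    locus_of: Mapping[str, str] | None = None,
) -> tuple[list[Hsp70Call], dict[str, int]]:
    """Run the full classification cascade and return calls plus stage counts.

    Stages: mass filter → dedup → form assignment → length class →
    (truncated cytosolic only) lineage → T1 subtype.  Proteins dropped at a
    stage carry an explicit verdict; nothing is silently discarded.
    """
    spec = spec or CtermMotifSpec()
    config = config or RunConfig()
    calls: list[Hsp70Call] = []
    counts: Counter[str] = Counter()
    counts["candidates"] = len(proteins)

    measurable = []
    for p in proteins:
        try:
            protein_mass(p)
            measurable.append(p)
        except ValueError:
            counts["mass_unmeasurable"] += 1
    passed = mass_filter(measurable, config.mass_lo, config.mass_hi)
    counts["mass_pass"] = len(passed)
    passed = dedup(passed, locus_of)
    counts["after_dedup"] = len(passed)

    for p in passed:
        mass = protein_mass(p)
        form, sim = classify_form(p, panel, config.min_form_similarity)
        if form == "unclassified":
            counts["form_unclassified"] += 1
            calls.append(
                Hsp70Call(
                    protein_id=p.id, species=p.species, form="unclassified",
                    length_class="NA", lineage="NA", subtype="NA",
                    mass_da=mass, form_similarity=sim,
                )
            )
            continue
        counts[f"form_{form}"] += 1
        length_class, detail = call_length_class(p, form, spec)
        counts[length_class] += 1
        if not (form == "cytosolic" and length_class == "truncated"):
            calls.append(
                Hsp70Call(
                    protein_id=p.id, species=p.species, form=form,
                    length_class=length_class, lineage="NA", subtype="NA",
                    mass_da=mass, form_similarity=sim, cterm_detail=detail,
                )
            )
            continue
        pattern = scan_blocks(p, blocks, order_constraint=True)
        st = st_rich_flag(p, config.st_rich_window, config.st_rich_fraction)
        anchor = pattern.last_sbda_hit_end
        ext_len = p.length - anchor if anchor is not None else -1
        last_end = pattern.last_hit_end
        ext_present = (
            last_end is not None and p.length - last_end >= config.extension_min
        )
        lineage = assign_lineage(
            pattern, st, ext_present, config.min_t1_blocks, config.min_t1_nbd_blocks
        )
        counts[f"lineage_{lineage}"] += 1
        subtype = "NA"
        if lineage == "T1":
            subtype = assign_t1_subtype(
                pattern.sbda_hits, pattern.ctd_hits, ext_len, config.extension_min
            )
            counts[f"subtype_{subtype}"] += 1
        calls.append(
            Hsp70Call(
                protein_id=p.id, species=p.species, form=form,
                length_class=length_class, lineage=lineage, subtype=subtype,
                mass_da=mass, form_similarity=sim,
                blocks_bitstring=pattern.bitstring(),
                sbda_hits=pattern.sbda_hits, ctd_hits=pattern.ctd_hits,
                nbd_hits=pattern.nbd_hits, extension_len=ext_len,
                st_rich=st, cterm_detail=detail,
            )
        )
    calls.sort(key=lambda c: c.protein_id)
    logger.info("classify_all: %s", dict(counts))
    return calls, dict(counts)


def calls_to_rows(calls: Iterable[Hsp70Call]) -> list[dict]:
    return [
        {
            "protein_id": c.protein_id,
            "species": c.species,
            "form": c.form,
            "length_class": c.length_class,
            "lineage": c.lineage,
            "subtype": c.subtype,
            "mass_Da": round(c.mass_da, 2),
            "form_similarity": round(c.form_similarity, 2),
            "blocks_hit": c.blocks_bitstring,
            "sbda_hits": c.sbda_hits,
            "ctd_hits": c.ctd_hits,
            "extension_len": c.extension_len,
            "st_rich": int(c.st_rich),
        }
        for c in calls
    ]
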