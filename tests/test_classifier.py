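import itertools

import numpy as np
import pytest

from hsp70census.classifier import (
    CtermMotifSpec,
    assign_lineage,
    assign_t1_subtype,
    call_length_class,
    classify_all,
    classify_form,
    dedup,
    st_rich_flag,
)
from hsp70census.io_core import AMINO_ACIDS, ProteinRecord
from hsp70census.motif_profiles import scan_blocks
from hsp70census.simulate import MINIMAL_MOTIFS, mutate


class TestClassifyForm:
    def test_panel_references_classify_as_themselves(self, archetypes):
        for ref in archetypes.panel.references:
            form, sim = classify_form(ref.record, archetypes.panel)
            assert form == ref.form
            assert sim == pytest.approx(100.0)

    def test_er_archetype_is_er(self, archetypes, rng):
        seq, _ = mutate(archetypes.full_length["ER"], 0.05, rng)
        form, _ = classify_form(
            ProteinRecord(id="q", sequence=seq), archetypes.panel
        )
        assert form == "ER"

    def test_shuffled_sequence_unclassified(self, archetypes, rng):
        shuffled = "".join(
            rng.permutation(list(archetypes.full_length["cytosolic"]))
        )
        form, sim = classify_form(
            ProteinRecord(id="s", sequence=shuffled), archetypes.panel
        )
        assert form == "unclassified"
        assert sim < 60


class TestLengthClass:
    def _rec(self, seq):
        return ProteinRecord(id="q", sequence=seq)

    def test_terminal_motifs_called_full_length(self):
        body = "M" + "A" * 600
        cases = {
            "cytosolic": body + "GPKIEEVD",
            "ER": body + "HDEL",
            "mitochondrial": body + "EAEYEEVKK",
            "chloroplast": body + "DVIDADFTDSK",
        }
        for form, seq in cases.items():
            lc, _ = call_length_class(self._rec(seq), form)
            assert lc == "full_length", form

    def test_deleting_minimal_motif_truncates(self):
        body = "M" + "A" * 600
        seq = body + "GPKIEEVD"
        lc, _ = call_length_class(self._rec(seq[:-4]), "cytosolic")
        assert lc == "truncated"

    def test_eevd_must_be_strictly_terminal(self):
        seq = "M" + "A" * 600 + "GPKIEEVD" + "KK"
        lc, _ = call_length_class(self._rec(seq), "cytosolic")
        assert lc == "truncated"

    def test_mito_motif_may_end_near_terminus(self):
        seq = "M" + "A" * 600 + "EAEYEEVKK" + "AA"
        lc, _ = call_length_class(self._rec(seq), "mitochondrial")
        assert lc == "full_length"

    def test_short_protein_searches_whole_sequence(self):
        lc, _ = call_length_class(self._rec("MEEVD"), "cytosolic")
        assert lc == "full_length"

    def test_mismatch_budget_is_monotone(self):
        seq = "M" + "A" * 600 + "GPKIEEVA"  # one substitution in EEVD
        statuses = []
        for budget in (0, 1, 2):
            spec = CtermMotifSpec(mismatch_budget=budget)
            statuses.append(
                call_length_class(self._rec(seq), "cytosolic", spec)[0]
            )
        assert statuses == ["truncated", "full_length", "full_length"]


class TestStRich:
    def test_st_run_detected(self):
        assert st_rich_flag("SSTTSSTTSSTTSSTTSSTT" + "A" * 100)

    def test_poly_alanine_not_st_rich(self):
        assert not st_rich_flag("A" * 100)

    def test_t2_archetype_is_st_rich(self, archetypes):
        assert st_rich_flag(archetypes.t2)


class TestLineage:
    def test_t1_from_many_hits(self, archetypes):
        pattern = scan_blocks(archetypes.t1["I"], archetypes.blocks)
        assert assign_lineage(pattern, st_rich=False, extension_present=False) == "T1"

    def test_t2_needs_zero_hits_plus_feature(self, archetypes):
        pattern = scan_blocks(archetypes.t2, archetypes.blocks)
        assert pattern.n_hits_total == 0
        assert assign_lineage(pattern, st_rich=True, extension_present=False) == "T2"
        assert (
            assign_lineage(pattern, st_rich=False, extension_present=False)
            == "unclassified"
        )

    def test_few_hits_is_unclassified(self, archetypes):
        # only the two CTD blocks present: below the T1 evidence floor
        tail = archetypes.full_length["cytosolic"][-70:]
        pattern = scan_blocks(tail, archetypes.blocks)
        assert 0 < pattern.n_hits_total < 6
        assert (
            assign_lineage(pattern, st_rich=False, extension_present=False)
            == "unclassified"
        )


class TestSubtype:
    @pytest.mark.parametrize(
        "sbda,ctd,ext,expected",
        [
            (4, 0, 5, "I"),
            (2, 0, 60, "IV"),
            (0, 0, 0, "III"),
            (0, 0, 300, "III"),
            (2, 0, 10, "II"),
            (1, 0, 39, "II"),
            (3, 1, 60, "IV"),
            (4, 0, 60, "unclassified"),
            (4, 1, 5, "unclassified"),
            (0, 2, 10, "unclassified"),
        ],
    )
    def test_rule_table(self, sbda, ctd, ext, expected):
        assert assign_t1_subtype(sbda, ctd, ext) == expected

    def test_partition_is_exhaustive_and_single_valued(self):
        """Every (sbda, ctd, extension) combination maps to exactly one label,
        and each label's defining predicate matches the rule output."""
        for sbda, ctd, ext in itertools.product(
            range(5), range(3), range(0, 101, 10)
        ):
            label = assign_t1_subtype(sbda, ctd, ext)
            extended = ext >= 40
            predicates = {
                "I": sbda == 4 and ctd == 0 and not extended,
                "II": 1 <= sbda <= 3 and ctd == 0 and not extended,
                "III": sbda == 0 and ctd == 0,
                "IV": 1 <= sbda <= 3 and extended,
            }
            matches = [k for k, v in predicates.items() if v]
            assert len(matches) <= 1
            assert label == (matches[0] if matches else "unclassified")


class TestDedup:
    def test_identical_sequence_same_locus_collapsed(self):
        a = ProteinRecord(id="p2", sequence="MKVL")
        b = ProteinRecord(id="p1", sequence="MKVL")
        c = ProteinRecord(id="p3", sequence="MKVL")
        locus = {"p1": "g1", "p2": "g1", "p3": "g2"}
        kept = dedup([a, b, c], locus)
        assert [p.id for p in kept] == ["p1", "p3"]

    def test_different_sequences_kept(self):
        a = ProteinRecord(id="p1", sequence="MKVL")
        b = ProteinRecord(id="p2", sequence="MKVA")
        assert len(dedup([a, b], {"p1": "g1", "p2": "g1"})) == 2


class TestClassifyAll:
    def test_empty_input(self, archetypes):
        calls, counts = classify_all([], archetypes.panel, archetypes.blocks)
        assert calls == []
        assert counts["candidates"] == 0

    def test_determinism(self, small_dataset):
        ds = small_dataset
        args = (ds.proteins[:60], ds.archetypes.panel, ds.archetypes.blocks)
        calls1, counts1 = classify_all(*args)
        calls2, counts2 = classify_all(*args)
        assert calls1 == calls2 and counts1 == counts2

    def test_lineage_only_for_truncated_cytosolic(self, study_calls):
        for c in study_calls[0]:
            if c.lineage in ("T1", "T2"):
                assert c.form == "cytosolic" and c.length_class == "truncated"

    def test_stage_counts_consistent(self, study_calls):
        _, counts = study_calls
        forms = sum(v for k, v in counts.items() if k.startswith("form_"))
        assert forms <= counts["after_dedup"]
        subtypes = sum(v for k, v in counts.items() if k.startswith("subtype_"))
        assert subtypes == counts.get("lineage_T1", 0)
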