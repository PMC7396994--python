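"""Call extraction, dual normalization, consequences, annotation, VCF."""

import numpy as np
import pytest

from orf15asm.align import global_align
from orf15asm.calls import (
    FrequencyRecord,
    annotate_frequency,
    attach_consequences,
    calls_from_alignment,
    classify_consequence,
    finalize_calls,
    left_aligned_vcf_fields,
    prioritize,
    read_frequency_table,
    write_vcf,
)
from orf15asm.reference import (
    AmpliconReference,
    CoordinateMap,
    Segment,
    Variant,
    VariantSet,
    apply_variant_set,
    revcomp,
)


@pytest.fixture(scope="module")
def toy():
    """A small same-orientation amplicon: 30 bp UTR-free coding core."""
    rng = np.random.default_rng(42)
    # coding on the plus strand, one segment, anchored at c.1 (codon-aligned)
    core = "ATGGAAGAGGGAGAAGGGATTGGAGAGTTT"
    ref = AmpliconReference(
        name="toy", plus_seq=core, locus=("chrT", 1001, 1000 + len(core)),
        primer_fwd=(1, 3), primer_rev=(len(core) - 2, len(core)),
        coding_strand="plus",
    )
    cmap = CoordinateMap("NM_TOY", "same", (Segment(1, len(core), "coding", 1),))
    return ref, cmap


class TestCallsFromAlignment:
    def test_no_differences_no_calls(self):
        seq = "ACGTTGCA" * 10
        assert calls_from_alignment(global_align(seq, seq)) == []

    def test_single_mismatch_is_one_snv(self):
        ref = "ACGTTGCA" * 10
        q = ref[:40] + ("A" if ref[40] != "A" else "C") + ref[41:]
        calls = calls_from_alignment(global_align(q, ref))
        assert len(calls) == 1 and calls[0].variant.kind == "SNV"
        assert calls[0].variant.start == 41

    def test_mismatch_adjacent_to_gap_merges_into_delins(self):
        """A substituted base hugging a deletion is one delins event."""
        ref = "ACGTTGCAAGGCTTACGGATCCATGCAAGT" * 3
        # replace the GGC at positions 40-42 by a lone A: no pure-deletion
        # representation exists, so the run must merge into one delins
        assert ref[39:42] == "GGC"
        q = ref[:39] + "A" + ref[42:]
        calls = calls_from_alignment(global_align(q, ref))
        assert len(calls) == 1
        v = calls[0].variant
        assert v.kind == "delins"
        assert apply_variant_set(ref, VariantSet([v])) == q

    def test_separated_events_stay_separate(self):
        ref = "ACGTTGCAAGGCTTACGGATCCATGCAAGT" * 3
        q = ref[:10] + ref[12:]  # clean 2-bp deletion
        q = q[:50] + ("A" if q[50] != "A" else "T") + q[51:]
        calls = calls_from_alignment(global_align(q, ref))
        assert sorted(c.variant.kind for c in calls) == ["SNV", "del"]


class TestFinalize:
    def test_dual_normalization_left_vcf_right_hgvs(self):
        """Intra-repeat deletion: VCF left-aligns, HGVS 3'-shifts."""
        seq = "CCATTTGCC" + "ACGTTGCAAGGCTTACGGATCCATGCAAGT" * 3
        ref = AmpliconReference(
            name="r", plus_seq=seq, locus=("chrT", 501, 500 + len(seq)),
            primer_fwd=(1, 3), primer_rev=(len(seq) - 2, len(seq)),
            coding_strand="plus",
        )
        cmap = CoordinateMap("NM_X", "same", (Segment(1, len(seq), "coding", 1),))
        from orf15asm.calls import VariantCall

        raw = [VariantCall(Variant(4, 4, "T", ""), caller="assembly")]
        fin = finalize_calls(raw, ref, cmap)
        v = fin[0].variant
        assert v.start == 6  # 3' end of the TTT tract
        assert fin[0].hgvs_c == "c.6delT"
        pos, ra, aa = fin[0].vcf_fields
        assert pos == 503  # anchor base before the leftmost representation
        assert (ra, aa) == ("AT", "A")

    def test_insertion_with_preceding_copy_emitted_as_dup(self, toy):
        ref, cmap = toy
        from orf15asm.calls import VariantCall

        # insert an exact copy of GAA after the existing GAA at 13-15
        raw = [VariantCall(Variant(16, 15, "", "GAA"), caller="assembly")]
        fin = finalize_calls(raw, ref, cmap)
        assert fin[0].variant.kind == "dup"
        assert "dup" in fin[0].hgvs_c

    def test_finalized_set_reproduces_contig(self, ref, cmap, catalogue):
        seq = ref.plus_seq
        contig = apply_variant_set(seq, catalogue["dup27"])
        aln = global_align(contig, seq)
        fin = finalize_calls(calls_from_alignment(aln), ref, cmap)
        called = VariantSet([c.variant for c in fin])
        assert apply_variant_set(seq, called) == contig


class TestConsequence:
    def test_two_bp_coding_del_is_frameshift(self, toy):
        ref, cmap = toy
        v = Variant(7, 8, ref.plus_seq[6:8], "")
        cons = classify_consequence(v, cmap, ref.plus_seq)
        assert cons.cls == "frameshift"

    def test_inframe_del_is_inframe(self, toy):
        ref, cmap = toy
        v = Variant(7, 9, ref.plus_seq[6:9], "")
        assert classify_consequence(v, cmap, ref.plus_seq).cls == "inframe_indel"

    def test_gag_to_tag_is_nonsense(self, toy):
        ref, cmap = toy
        # codon 9 (c.25-27) is GAG in the toy core; G>T at c.25 makes TAG
        assert ref.plus_seq[24:27] == "GAG"
        v = Variant(25, 25, "G", "T")
        cons = classify_consequence(v, cmap, ref.plus_seq)
        assert cons.cls == "nonsense"
        assert cons.p_notation == "p.Glu9Ter"

    def test_silent_and_missense(self, toy):
        ref, cmap = toy
        # GAA -> GAG at codon 2 stays Glu
        assert ref.plus_seq[3:6] == "GAA"
        silent = classify_consequence(Variant(6, 6, "A", "G"), cmap, ref.plus_seq)
        assert silent.cls == "silent" and silent.p_notation == "p.="
        missense = classify_consequence(Variant(4, 4, "G", "C"), cmap, ref.plus_seq)
        assert missense.cls == "missense"

    def test_frameshift_p_notation_matches_direct_translation(self, ref, cmap, catalogue):
        """fsTer offset agrees with translating the edited transcript."""
        from Bio.Seq import Seq

        (v,) = catalogue["del2"].variants
        cons = classify_consequence(v, cmap, ref.plus_seq)
        assert cons.cls == "frameshift"
        if cons.p_notation and "fsTer" in cons.p_notation:
            # re-derive the stop offset independently
            T = revcomp(apply_variant_set(ref.plus_seq, VariantSet([v])))
            seg = [s for s in cmap.segments if s.kind == "coding"][0]
            t_cds_start = ref.length - seg.end + 1
            aa = str(Seq(T[t_cds_start - 1 :][: (len(T) - t_cds_start + 1) // 3 * 3]).translate())
            assert "*" in aa

    def test_noncoding_variant(self, ref, cmap):
        v = Variant(10, 10, ref.plus_seq[9], "A" if ref.plus_seq[9] != "A" else "C")
        assert classify_consequence(v, cmap, ref.plus_seq).cls == "noncoding"

    def test_boundary_spanning_flagged(self, ref, cmap):
        seg = [s for s in cmap.segments if s.kind == "coding"][0]
        v = Variant(seg.start - 2, seg.start + 2, ref.plus_seq[seg.start - 3 : seg.start + 2], "")
        cons = classify_consequence(v, cmap, ref.plus_seq)
        assert cons.cls == "frameshift" and cons.boundary_warning

    def test_randomized_frameshift_agrees_with_translation_parity(self, toy):
        rng = np.random.default_rng(17)
        ref, cmap = toy
        seq = ref.plus_seq
        for _ in range(200):
            start = int(rng.integers(4, 22))
            dl = int(rng.integers(1, 5))
            if rng.random() < 0.5:
                v = Variant(start, start + dl - 1, seq[start - 1 : start + dl - 1], "")
            else:
                ins = "".join(rng.choice(list("ACGT"), size=dl))
                v = Variant(start, start - 1, "", ins)
            cons = classify_consequence(v, cmap, seq)
            if cons.cls in ("frameshift", "inframe_indel"):
                assert (cons.cls == "frameshift") == (v.net % 3 != 0)


class TestPrioritize:
    def test_only_frameshift_and_nonsense_survive(self, toy):
        ref, cmap = toy
        from orf15asm.calls import VariantCall

        variants = [
            Variant(7, 8, ref.plus_seq[6:8], ""),  # frameshift
            Variant(6, 6, "A", "G"),  # silent
            Variant(4, 4, "G", "C"),  # missense
            Variant(25, 25, "G", "T"),  # nonsense
        ]
        calls = [VariantCall(v, caller="assembly") for v in variants]
        calls = attach_consequences(calls, cmap, ref)
        kept = prioritize(calls)
        assert sorted(c.consequence.cls for c in kept) == ["frameshift", "nonsense"]

    def test_all_silent_empty(self, toy):
        ref, cmap = toy
        from orf15asm.calls import VariantCall

        calls = attach_consequences(
            [VariantCall(Variant(6, 6, "A", "G"), caller="assembly")], cmap, ref
        )
        assert prioritize(calls) == []


class TestFrequency:
    def test_exact_key_match_and_miss(self, toy):
        ref, cmap = toy
        from orf15asm.calls import VariantCall

        raw = [VariantCall(Variant(7, 7, ref.plus_seq[6], "T" if ref.plus_seq[6] != "T" else "A"),
                           caller="assembly")]
        fin = finalize_calls(raw, ref, cmap)
        pos, ra, aa = fin[0].vcf_fields
        table = [FrequencyRecord("chrT", pos, ra, aa, 12.5, "rs42")]
        hit = annotate_frequency(fin, table, "chrT")[0]
        assert hit.frequency_percent == 12.5 and hit.rsid == "rs42"
        miss = annotate_frequency(fin, [], "chrT")[0]
        assert miss.frequency_percent is None and "frequency:NA" in miss.flags

    def test_intra_repeat_del_key_is_left_aligned_not_hgvs(self):
        """The 3'-shifted HGVS coordinate must never key the lookup."""
        seq = "CCATTTGCC" + "ACGTTGCAAGGCTTACGGATCCATGCAAGT" * 2
        ref = AmpliconReference(
            name="r", plus_seq=seq, locus=("chrT", 501, 500 + len(seq)),
            primer_fwd=(1, 3), primer_rev=(len(seq) - 2, len(seq)),
            coding_strand="plus",
        )
        cmap = CoordinateMap("NM_X", "same", (Segment(1, len(seq), "coding", 1),))
        from orf15asm.calls import VariantCall

        fin = finalize_calls([VariantCall(Variant(4, 4, "T", ""), caller="assembly")], ref, cmap)
        pos, ra, aa = fin[0].vcf_fields
        hgvs_pos = 500 + fin[0].variant.start  # would be the wrong key
        assert pos != hgvs_pos
        table = [FrequencyRecord("chrT", pos, ra, aa, 5.0)]
        assert annotate_frequency(fin, table, "chrT")[0].frequency_percent == 5.0
        wrong = [FrequencyRecord("chrT", hgvs_pos, ra, aa, 5.0)]
        assert annotate_frequency(fin, wrong, "chrT")[0].frequency_percent is None

    def test_malformed_tsv_rows_skipped(self):
        text = "chrom\tpos\tref\talt\tfreq_percent\trsid\n" \
               "chrX\t100\tA\tG\t1.5\trs1\n" \
               "chrX\tnot_a_number\tA\tG\t1.5\trs2\n"
        records = read_frequency_table(text)
        assert len(records) == 1 and records[0].rsid == "rs1"


class TestVcf:
    def test_coordinates_and_anchoring(self, toy):
        ref, cmap = toy
        from orf15asm.calls import VariantCall

        p = 7
        alt = "T" if ref.plus_seq[p - 1] != "T" else "A"
        raw = [
            VariantCall(Variant(p, p, ref.plus_seq[p - 1], alt), caller="assembly",
                        zygosity="hemizygous"),
            VariantCall(Variant(11, 12, ref.plus_seq[10:12], ""), caller="assembly",
                        zygosity="hemizygous"),
        ]
        fin = finalize_calls(raw, ref, cmap)
        text = write_vcf(fin, ref, "S1")
        rows = [l.split("\t") for l in text.splitlines() if not l.startswith("#")]
        assert rows[0][0] == "chrT"
        assert int(rows[0][1]) == 1001 + p - 1  # POS = locus.start + p - 1
        del_row = rows[1]
        assert len(del_row[3]) == len(del_row[4]) + 2  # anchored deletion

    def test_round_trip_with_pysam(self, tmp_path, ref, cmap, catalogue):
        pysam = pytest.importorskip("pysam")
        seq = ref.plus_seq
        contig = apply_variant_set(seq, catalogue["del2"])
        fin = finalize_calls(calls_from_alignment(global_align(contig, seq)), ref, cmap)
        path = tmp_path / "x.vcf"
        path.write_text(write_vcf(fin, ref, "S1"))
        back = list(pysam.VariantFile(str(path)).fetch())
        assert len(back) == len(fin)
        for rec, call in zip(back, fin):
            pos, ra, aa = call.vcf_fields
            assert (rec.pos, rec.ref, rec.alts[0]) == (pos, ra, aa)

    def test_unanchorable_indel_rejected(self):
        seq = "ACGTTGCAAGGCTTACGGATCCATGCAAGT"
        ref = AmpliconReference(
            name="r", plus_seq=seq, locus=("chrT", 1, len(seq)),
            primer_fwd=(1, 3), primer_rev=(len(seq) - 2, len(seq)),
        )
        with pytest.raises(ValueError):
            left_aligned_vcf_fields(Variant(1, 2, seq[:2], ""), seq, ref.locus)
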