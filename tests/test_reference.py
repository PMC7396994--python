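"""Variant algebra: application, equivalence, normalization, HGVS."""

import pytest
from hypothesis import given, settings, strategies as st

from orf15asm.reference import (
    AmpliconReference,
    CoordinateMap,
    HgvsError,
    OverlapError,
    RefMismatchError,
    Segment,
    Variant,
    VariantSet,
    apply_variant_set,
    classify_dup,
    normalize_3prime,
    normalize_5prime,
    parse_hgvs_c,
    revcomp,
    sets_equivalent,
    to_hgvs_c,
)


def brute_edit(ref, start, end, alt):
    """Independent string-surgery oracle for a single interval replacement."""
    return ref[: start - 1] + alt + ref[end:]


class TestApply:
    @pytest.mark.parametrize(
        "ref,variants,expected",
        [
            ("ACGT", [], "ACGT"),
            ("ACGT", [Variant(2, 2, "C", "T")], "ATGT"),
            # duplication of the first 6-mer of a 6-bp tandem
            (
                "AAGGAGAAGGAG",
                [Variant(1, 6, "AAGGAG", "AAGGAGAAGGAG")],
                "AAGGAGAAGGAGAAGGAG",
            ),
            # insertion encoded as an empty interval after position 2
            ("ACGT", [Variant(3, 2, "", "TT")], "ACTTGT"),
            ("ACGT", [Variant(1, 4, "ACGT", "")], ""),
        ],
    )
    def test_examples(self, ref, variants, expected):
        assert apply_variant_set(ref, VariantSet(variants)) == expected
        for v in variants:
            assert brute_edit(ref, v.start, v.end, v.alt) == expected

    def test_ref_mismatch_reports_position(self):
        with pytest.raises(RefMismatchError, match="2-2"):
            apply_variant_set("ACGT", VariantSet([Variant(2, 2, "G", "T")]))

    def test_overlap_rejected(self):
        with pytest.raises(OverlapError):
            VariantSet([Variant(2, 4, "CGT", ""), Variant(3, 3, "G", "A")])

    def test_length_change_is_net_sum(self):
        ref = "ACGTACGTACGT"
        vs = VariantSet([Variant(2, 3, "CG", ""), Variant(7, 6, "", "AAAA")])
        assert len(apply_variant_set(ref, vs)) == len(ref) + sum(v.net for v in vs)


class TestKind:
    @pytest.mark.parametrize(
        "v,kind",
        [
            (Variant(2, 2, "C", "T"), "SNV"),
            (Variant(2, 3, "CG", ""), "del"),
            (Variant(3, 2, "", "AT"), "ins"),
            (Variant(2, 3, "CG", "CGCG"), "dup"),
            (Variant(2, 3, "CG", "TT"), "delins"),
        ],
    )
    def test_derived_kind(self, v, kind):
        assert v.kind == kind


class TestEquivalence:
    def test_reflexive(self):
        a = VariantSet([Variant(2, 2, "C", "T")])
        assert sets_equivalent("ACGT", a, a)

    def test_distinct_products(self):
        a = VariantSet([Variant(2, 2, "C", "T")])
        b = VariantSet([Variant(3, 3, "G", "A")])
        assert not sets_equivalent("ACGT", a, b)

    def test_long_insertion_vs_two_duplications(self):
        """Two wildly different namings of one repeat-tract allele agree.

        Mirrors the classic long-insertion-plus-SNVs versus dup-plus-dup
        ambiguity: both sets are constructed from the same edited string via
        different decompositions and must compare equal by application.
        """
        unit = "AAGGAGGAAGGGGAGGAAGGAGAAGGG"  # 27 bp
        assert len(unit) == 27
        ref = "CTTCTTAC" + unit * 3 + "TTCACCTA"
        # representation B: duplicate the first unit, then a 24-mer further in
        dup1 = Variant(9, 35, unit, unit + unit)
        seg24 = ref[44:68]
        dup2 = Variant(45, 68, seg24, seg24 + seg24)
        b = VariantSet([dup1, dup2])
        edited = apply_variant_set(ref, b)
        # representation A, built from the same edited string via a different
        # decomposition: one 51-bp insertion plus the compensating point
        # edits left over downstream of it
        ins51 = edited[35 : 35 + 51]
        base = apply_variant_set(ref, VariantSet([Variant(36, 35, "", ins51)]))
        mism = [i for i, (x, y) in enumerate(zip(edited, base)) if x != y]
        runs: list[list[int]] = []
        for i in mism:
            if runs and i == runs[-1][-1] + 1:
                runs[-1].append(i)
            else:
                runs.append([i])
        extras = [
            Variant(
                run[0] - 50,
                run[-1] - 50,
                ref[run[0] - 51 : run[-1] - 50],
                "".join(edited[i] for i in run),
            )
            for run in runs
        ]
        a = VariantSet([Variant(36, 35, "", ins51)] + extras)
        kinds = sorted(v.kind for v in a)
        assert "ins" in kinds and "delins" in kinds and "SNV" in kinds
        assert apply_variant_set(ref, a) == edited
        assert sets_equivalent(ref, a, b)
        assert not sets_equivalent(ref, a, VariantSet([dup1]))

    def test_equivalence_relation_on_random_pairs(self):
        import numpy as np

        rng = np.random.default_rng(5)
        for _ in range(50):
            L = int(rng.integers(20, 60))
            ref = "".join(rng.choice(list("ACGT"), size=L))
            p = int(rng.integers(1, L - 5))
            d = int(rng.integers(1, 4))
            a = VariantSet([Variant(p, p + d - 1, ref[p - 1 : p + d - 1], "")])
            shifted = normalize_3prime(ref, a.variants[0])
            b = VariantSet([shifted])
            assert sets_equivalent(ref, a, b)
            assert sets_equivalent(ref, b, a)  # symmetric


class TestNormalize:
    def test_del_shifts_to_tract_end(self):
        v = normalize_3prime("ATTTG", Variant(2, 2, "T", ""))
        assert (v.start, v.end) == (4, 4)
        all_equiv = [
            s
            for s in range(1, 6)
            if "ATTTG"[: s - 1] + "ATTTG"[s:] == "ATTG"
        ]
        assert v.start == max(all_equiv)

    def test_nonrepetitive_del_unchanged(self):
        v = Variant(2, 2, "C", "")
        assert normalize_3prime("ACGT", v) == v

    def test_ins_shifts_through_dinucleotide_tract(self):
        ref = "CAGAGAGAGT"
        v = normalize_3prime(ref, Variant(2, 1, "", "AG"))
        assert v.kind == "dup" and v.end == 9

    def test_product_preserved_and_idempotent(self):
        ref = "CCAAGAAGAAGTT"
        v = Variant(4, 6, "AGA", "")
        n1 = normalize_3prime(ref, v)
        assert apply_variant_set(ref, VariantSet([n1])) == apply_variant_set(
            ref, VariantSet([v])
        )
        assert normalize_3prime(ref, n1) == n1

    def test_left_alignment_mirrors(self):
        v = normalize_5prime("ATTTG", Variant(4, 4, "T", ""))
        assert (v.start, v.end) == (2, 2)

    @given(st.data())
    @settings(max_examples=150, deadline=None)
    def test_normalize_never_changes_product(self, data):
        unit = data.draw(st.text(alphabet="ACGT", min_size=1, max_size=4))
        copies = data.draw(st.integers(2, 5))
        flank = data.draw(st.text(alphabet="ACGT", min_size=3, max_size=8))
        ref = flank + unit * copies + flank
        L = len(ref)
        start = data.draw(st.integers(1, L))
        dl = data.draw(st.integers(1, min(4, L - start + 1)))
        if data.draw(st.booleans()):
            v = Variant(start, start + dl - 1, ref[start - 1 : start + dl - 1], "")
        else:
            ins = data.draw(st.text(alphabet="ACGT", min_size=1, max_size=6))
            v = Variant(start, start - 1, "", ins)
        n = normalize_3prime(ref, v)
        assert apply_variant_set(ref, VariantSet([n])) == apply_variant_set(
            ref, VariantSet([v])
        )


class TestClassifyDup:
    def test_preceding_copy_becomes_dup(self):
        ref = "TTGAGCC"
        v = classify_dup(ref, Variant(6, 5, "", "GAG"))
        assert v.kind == "dup" and (v.start, v.end) == (3, 5)

    def test_no_preceding_copy_stays_ins(self):
        ref = "TTGAGCC"
        v = classify_dup(ref, Variant(6, 5, "", "TTT"))
        assert v.kind == "ins"

    def test_27mer_dup_in_repeat_tract(self):
        unit = "AAGGAGGAAGGGGAGGAAGGAGAAGGG"
        ref = "CCTT" + unit * 2 + "AATT"
        ins_point = 4 + 27 * 2
        v = classify_dup(ref, Variant(ins_point + 1, ins_point, "", unit))
        assert v.kind == "dup"
        assert (v.start, v.end) == (ins_point - 26, ins_point)

    def test_ins_longer_than_context_never_dup(self):
        v = classify_dup("ACG", Variant(3, 2, "", "ACGT"))
        assert v.kind == "ins"

    def test_reexpanded_dup_is_sequence_identical(self):
        ref = "TTGAGCC"
        ins = Variant(6, 5, "", "GAG")
        dup = classify_dup(ref, ins)
        assert apply_variant_set(ref, VariantSet([dup])) == apply_variant_set(
            ref, VariantSet([ins])
        )


class TestHgvs:
    """Rendering and parsing against a small hand-built opposite-strand map."""

    @pytest.fixture(scope="session")
    def setup(self):
        import numpy as np

        rng = np.random.default_rng(11)
        plus = "".join(rng.choice(list("ACGT"), size=400))
        cmap = CoordinateMap(
            "NM_SMALL",
            "opposite",
            (
                Segment(1, 130, "utr3", 1),
                Segment(131, 330, "coding", 2701),
                Segment(331, 400, "intron_offset", 1754),
            ),
        )
        return plus, cmap

    def test_two_bp_deletion_form(self, setup):
        plus, cmap = setup
        # transcript positions 2790-2791 correspond to plus 240-241:
        # c = 2701 + (330 - p)
        v = Variant(240, 241, plus[239:241], "")
        assert to_hgvs_c(v, cmap, plus) == "c.2790_2791del"

    def test_intron_offset_snv_form(self, setup):
        plus, cmap = setup
        # K = p - 330 for the intron segment; K = 103 -> p = 433? out of range
        # segment is [331, 400] with anchor 1754; K = 70 - (400 - p)
        p = 350
        v = Variant(p, p, plus[p - 1], "A" if plus[p - 1] != "A" else "G")
        h = to_hgvs_c(v, cmap, plus)
        assert h.startswith("c.1754-")
        k = int(h.split("-")[1][:2])
        assert k == 70 - (400 - p)

    def test_utr3_single_base_del_form(self, setup):
        plus, cmap = setup
        p = 6  # c.* index = 1 + (130 - p)
        v = Variant(p, p, plus[p - 1], "")
        h = to_hgvs_c(v, cmap, plus)
        assert h == f"c.*{1 + (130 - p)}del{revcomp(plus[p - 1])}"

    def test_snv_alleles_complemented(self, setup):
        plus, cmap = setup
        p = 200
        alt = "A" if plus[p - 1] != "A" else "C"
        h = to_hgvs_c(Variant(p, p, plus[p - 1], alt), cmap, plus)
        assert h.endswith(f"{revcomp(plus[p - 1])}>{revcomp(alt)}")

    @pytest.mark.parametrize(
        "bad", ["p.Glu931GlyfsTer147", "c.12+3del", "garbage", "c.10_12inv"]
    )
    def test_unsupported_forms_rejected(self, setup, bad):
        plus, cmap = setup
        with pytest.raises(HgvsError):
            parse_hgvs_c(bad, cmap, plus)

    @given(st.data())
    @settings(max_examples=200, deadline=None)
    def test_round_trip_apply_identity(self, setup, data):
        """print -> parse -> apply equals direct application."""
        plus, cmap = setup
        p = data.draw(st.integers(20, 380))
        choice = data.draw(st.sampled_from(["SNV", "del", "ins", "delins"]))
        if choice == "SNV":
            alt = data.draw(st.sampled_from([b for b in "ACGT" if b != plus[p - 1]]))
            v = Variant(p, p, plus[p - 1], alt)
        elif choice == "del":
            dl = data.draw(st.integers(1, 6))
            end = min(p + dl - 1, 395)
            v = Variant(p, end, plus[p - 1 : end], "")
        elif choice == "ins":
            ins = data.draw(st.text(alphabet="ACGT", min_size=1, max_size=8))
            v = Variant(p + 1, p, "", ins)
        else:
            dl = data.draw(st.integers(2, 5))
            end = min(p + dl - 1, 395)
            alt = data.draw(st.text(alphabet="ACGT", min_size=2, max_size=6))
            v = Variant(p, end, plus[p - 1 : end], alt)
            if v.kind != "delins":
                return
        h = to_hgvs_c(v, cmap, plus)
        back = parse_hgvs_c(h, cmap, plus)
        assert apply_variant_set(plus, VariantSet([back])) == apply_variant_set(
            plus, VariantSet([v])
        )


class TestAmpliconReference:
    def test_locus_span_must_match(self):
        with pytest.raises(ValueError, match="does not match"):
            AmpliconReference(
                name="x", plus_seq="ACGT", locus=("chrX", 1, 5),
                primer_fwd=(1, 2), primer_rev=(3, 4),
            )

    def test_alphabet_enforced(self):
        with pytest.raises(ValueError, match="non-ACGT"):
            AmpliconReference(
                name="x", plus_seq="ACGN", locus=("chrX", 1, 4),
                primer_fwd=(1, 2), primer_rev=(3, 4),
            )
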