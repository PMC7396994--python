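"""Variant calling from a contig/reference alignment.

Maximal runs of non-match alignment columns are segmented into events: a run
without gaps yields one SNV per mismatch column (the per-column dialect of
classic SNP callers); a run containing any gap becomes a single event — a
deletion if only reference bases are present, an insertion if only contig
bases, and a delins otherwise. This run-merging rule is what turns the
characteristic "mismatch hugging an indel" pattern of repeat-tract edits into
one coherent call instead of fragments.

Finalized calls carry two renderings of the same edit: HGVS c. (3'-shifted on
the transcript sense, duplication-aware) and VCF (left-aligned on the genomic
plus strand, anchor-based). The two standards genuinely disagree inside
repeats; both come from the one internal interval-replacement variant, and
applying the finalized set to the reference must reproduce the de-gapped
contig exactly.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from typing import Optional, Sequence

from Bio.Seq import Seq
from Bio.SeqUtils import seq3

from .align import PairwiseAlignment
from .reference import (
    AmpliconReference,
    CoordinateMap,
    Variant,
    VariantSet,
    apply_variant_set,
    normalize_5prime,
    normalize_transcript_3prime,
    revcomp,
    to_hgvs_c,
)

CONSEQUENCE_CLASSES = ("frameshift", "nonsense", "inframe_indel", "missense", "silent", "noncoding")


@dataclass(frozen=True)
class ConsequenceCall:
    cls: str
    p_notation: Optional[str] = None
    boundary_warning: bool = False

    def __post_init__(self) -> None:
        if self.cls not in CONSEQUENCE_CLASSES:
            raise ValueError(f"unknown consequence class {self.cls!r}")


@dataclass
class VariantCall:
    """One called variant with its provenance and renderings."""

    variant: Variant
    caller: str  # "assembly" | "baseline"
    zygosity: str = "unknown"
    support: str = ""  # contig id or depth summary
    hgvs_c: Optional[str] = None
    vcf_fields: Optional[tuple[int, str, str]] = None  # (POS, REF, ALT), genomic
    consequence: Optional[ConsequenceCall] = None
    frequency_percent: Optional[float] = None
    rsid: Optional[str] = None
    flags: list = field(default_factory=list)

    def key(self) -> Optional[tuple[int, str, str]]:
        """Cross-pipeline identity: the left-aligned VCF rendering."""
        return self.vcf_fields


def calls_from_alignment(
    aln: PairwiseAlignment, caller: str = "assembly", support: str = "", zygosity: str = "unknown"
) -> list[VariantCall]:
    """Segment non-match column runs into SNV / del / ins / delins events.

    Runs touching an alignment terminus that contain gap columns are treated
    as unaligned overhangs (free end gaps), not variants, and are skipped.
    Coordinates are ungapped reference (amplicon plus-strand) positions.
    """
    rr, qr = aln.ref_row, aln.query_row
    n = len(rr)
    calls: list[VariantCall] = []
    runs: list[tuple[int, int]] = []  # column spans [a, b)
    a = None
    for i in range(n + 1):
        is_match = i < n and rr[i] == qr[i] and rr[i] != "-"
        if not is_match and i < n:
            if a is None:
                a = i
        else:
            if a is not None:
                runs.append((a, i))
                a = None
    # reference position before each column
    ref_pos = [0] * (n + 1)
    p = 0
    for i in range(n):
        if rr[i] != "-":
            p += 1
        ref_pos[i + 1] = p

    for a, b in runs:
        cols_r = rr[a:b]
        cols_q = qr[a:b]
        has_gap = "-" in cols_r or "-" in cols_q
        touches_end = a == 0 or b == n
        if has_gap and touches_end:
            continue  # overhang, not a variant
        if not has_gap:
            for i in range(a, b):
                pos = ref_pos[i + 1]
                calls.append(
                    VariantCall(
                        Variant(pos, pos, rr[i], qr[i], zygosity=zygosity),
                        caller=caller,
                        support=support,
                        zygosity=zygosity,
                    )
                )
            continue
        ref_bases = cols_r.replace("-", "")
        query_bases = cols_q.replace("-", "")
        start = ref_pos[a] + 1 if ref_bases else ref_pos[a] + 1
        if ref_bases:
            v = Variant(start, start + len(ref_bases) - 1, ref_bases, query_bases, zygosity=zygosity)
        else:
            # pure insertion between ref_pos[a] and ref_pos[a]+1
            v = Variant(ref_pos[a] + 1, ref_pos[a], "", query_bases, zygosity=zygosity)
        calls.append(VariantCall(v, caller=caller, support=support, zygosity=zygosity))
    return calls


def left_aligned_vcf_fields(
    v: Variant, ref_seq: str, locus: tuple[str, int, int], min_start: int = 1
) -> tuple[int, str, str]:
    """Left-aligned, anchor-based (POS, REF, ALT) on the genomic plus strand."""
    chrom, gstart, _ = locus
    if v.kind == "SNV":
        return (gstart + v.start - 1, v.ref, v.alt)
    if v.kind == "delins":
        return (gstart + v.start - 1, v.ref, v.alt)
    shifted = normalize_5prime(ref_seq, v, min_start=min_start)
    if shifted.kind == "dup":
        # anchor before the duplicated segment; ALT carries the extra copy
        anchor_pos = shifted.start - 1
        if anchor_pos < 1:
            anchor = ref_seq[shifted.end - 1]
            return (gstart + shifted.end - 1, anchor, anchor + shifted.ref)
        anchor = ref_seq[anchor_pos - 1]
        return (gstart + anchor_pos - 1, anchor + shifted.ref, anchor + shifted.alt)
    if shifted.kind == "del":
        anchor_pos = shifted.start - 1
        if anchor_pos < 1:
            raise ValueError("deletion at amplicon start cannot be anchored")
        anchor = ref_seq[anchor_pos - 1]
        return (gstart + anchor_pos - 1, anchor + shifted.ref, anchor)
    if shifted.kind == "ins":
        anchor_pos = shifted.start - 1
        if anchor_pos < 1:
            raise ValueError("insertion before amplicon start cannot be anchored")
        anchor = ref_seq[anchor_pos - 1]
        return (gstart + anchor_pos - 1, anchor, anchor + shifted.alt)
    raise AssertionError(f"unexpected kind {shifted.kind}")


def finalize_calls(
    calls: Sequence[VariantCall], ref: AmpliconReference, cmap: CoordinateMap
) -> list[VariantCall]:
    """Normalize, dup-classify and render every raw call.

    Indels are 3'-shifted on the transcript sense (capped so they cannot
    slide into a neighbouring call) and re-expressed as duplications where an
    exact preceding copy exists; HGVS and left-aligned VCF strings are
    attached. The finalized set must stay sequence-equivalent to the raw set;
    a violation is an internal-consistency error.
    """
    seq = ref.plus_seq
    raw_sorted = sorted(calls, key=lambda c: (c.variant.start, c.variant.end))
    out: list[VariantCall] = []
    for i, call in enumerate(raw_sorted):
        v = call.variant
        lo = raw_sorted[i - 1].variant.end + 1 if i > 0 else 1
        hi = raw_sorted[i + 1].variant.start - 1 if i + 1 < len(raw_sorted) else len(seq)
        if v.kind in ("del", "ins", "dup"):
            norm = normalize_transcript_3prime(seq, v, cmap, max_shift_interval=(lo, hi))
        else:
            norm = v
        vcf = left_aligned_vcf_fields(norm, seq, ref.locus, min_start=lo)
        hgvs = to_hgvs_c(norm, cmap, seq)
        out.append(
            dc_replace_call(call, variant=norm, hgvs_c=hgvs, vcf_fields=vcf)
        )
    raw_product = apply_variant_set(seq, VariantSet([c.variant for c in raw_sorted]))
    fin_product = apply_variant_set(seq, VariantSet([c.variant for c in out]))
    if raw_product != fin_product:
        raise RuntimeError("normalization changed the edited product (internal error)")
    return out


def dc_replace_call(call: VariantCall, **kw) -> VariantCall:
    new = VariantCall(
        variant=kw.get("variant", call.variant),
        caller=call.caller,
        zygosity=call.zygosity,
        support=call.support,
        hgvs_c=kw.get("hgvs_c", call.hgvs_c),
        vcf_fields=kw.get("vcf_fields", call.vcf_fields),
        consequence=kw.get("consequence", call.consequence),
        frequency_percent=kw.get("frequency_percent", call.frequency_percent),
        rsid=kw.get("rsid", call.rsid),
        flags=list(call.flags),
    )
    return new


# ---------------------------------------------------------------------------
# Consequence classification


def _transcript_seq(ref_seq: str, cmap: CoordinateMap) -> str:
    return ref_seq if cmap.orientation == "same" else revcomp(ref_seq)


def _coding_segment(cmap: CoordinateMap):
    segs = [s for s in cmap.segments if s.kind == "coding"]
    if len(segs) != 1:
        raise ValueError("consequence classification expects exactly one coding segment")
    return segs[0]


def classify_consequence(
    v: Variant, cmap: CoordinateMap, ref_seq: str
) -> ConsequenceCall:
    """Classify a finalized variant by its effect on the reading frame.

    Coding indels with net length not divisible by three are frameshifts
    (p-notation derived by translating the edited transcript from the first
    affected codon to the first stop); stop-gain SNVs are nonsense; in-frame
    indels, missense and silent SNVs, and non-coding variants are labelled
    accordingly. A variant spanning a segment boundary is conservatively
    reported as a frameshift candidate with a warning flag.
    """
    seg = _coding_segment(cmap)
    L = len(ref_seq)
    lo, hi = (v.start, v.end) if v.end >= v.start else (v.end, v.start)
    ins_like = v.kind == "ins"
    if ins_like:
        lo, hi = v.end, v.start  # flanking bases
    overlaps = not (hi < seg.start or lo > seg.end)
    inside = seg.start <= lo and hi <= seg.end
    if not overlaps:
        return ConsequenceCall("noncoding")
    if not inside:
        return ConsequenceCall("frameshift", boundary_warning=True)

    T = _transcript_seq(ref_seq, cmap)
    # transcript-sense coordinates of the coding segment and variant
    if cmap.orientation == "same":
        t_cds_start = seg.start
        tv = v
        t_seq = ref_seq
    else:
        t_cds_start = L - seg.end + 1
        from .reference import map_variant_rc

        tv = map_variant_rc(v, L)
        t_seq = T
    c_of = lambda t: seg.c_anchor + (t - t_cds_start)  # transcript c. coordinate

    if v.kind == "SNV":
        c = c_of(tv.start)
        codon_no = (c + 2) // 3
        codon_c_start = 3 * codon_no - 2
        t0 = t_cds_start + (codon_c_start - seg.c_anchor)
        codon_ref = t_seq[t0 - 1 : t0 + 2]
        offset = c - codon_c_start
        codon_alt = codon_ref[:offset] + tv.alt + codon_ref[offset + 1 :]
        if len(codon_ref) < 3:
            return ConsequenceCall("frameshift", boundary_warning=True)
        aa_ref = str(Seq(codon_ref).translate())
        aa_alt = str(Seq(codon_alt).translate())
        if aa_alt == "*" and aa_ref != "*":
            return ConsequenceCall("nonsense", p_notation=f"p.{seq3(aa_ref)}{codon_no}Ter")
        if aa_alt == aa_ref:
            return ConsequenceCall("silent", p_notation="p.=")
        return ConsequenceCall(
            "missense", p_notation=f"p.{seq3(aa_ref)}{codon_no}{seq3(aa_alt)}"
        )

    net = v.net
    if net % 3 == 0:
        return ConsequenceCall("inframe_indel")
    # frameshift: translate reference and edited transcript from the first
    # codon touching the variant through the transcript 3' end
    c_first = c_of(tv.start if not ins_like else tv.start)
    codon_no = (c_first + 2) // 3
    codon_c_start = 3 * codon_no - 2
    t0 = t_cds_start + (codon_c_start - seg.c_anchor)
    tail_ref = t_seq[t0 - 1 :]
    edited = apply_variant_set(t_seq, VariantSet([tv]))
    tail_alt = edited[t0 - 1 :]
    aa_ref = str(Seq(tail_ref[: len(tail_ref) - len(tail_ref) % 3]).translate())
    aa_alt = str(Seq(tail_alt[: len(tail_alt) - len(tail_alt) % 3]).translate())
    idx = 0
    while idx < min(len(aa_ref), len(aa_alt)) and aa_ref[idx] == aa_alt[idx]:
        idx += 1
    if idx >= len(aa_ref) or idx >= len(aa_alt):
        return ConsequenceCall("frameshift", p_notation=None)
    first_ref, first_alt = aa_ref[idx], aa_alt[idx]
    n_aa = codon_no + idx
    stop = aa_alt.find("*", idx)
    if first_alt == "*":
        p = f"p.{seq3(first_ref)}{n_aa}Ter"
    elif stop != -1:
        p = f"p.{seq3(first_ref)}{n_aa}{seq3(first_alt)}fsTer{stop - idx + 1}"
    else:
        p = f"p.{seq3(first_ref)}{n_aa}{seq3(first_alt)}fs"
    return ConsequenceCall("frameshift", p_notation=p)


def attach_consequences(
    calls: Sequence[VariantCall], cmap: CoordinateMap, ref: AmpliconReference
) -> list[VariantCall]:
    out = []
    for c in calls:
        cons = classify_consequence(c.variant, cmap, ref.plus_seq)
        out.append(dc_replace_call(c, consequence=cons))
    return out


def prioritize(calls: Sequence[VariantCall]) -> list[VariantCall]:
    """Keep only nonsense and frameshift calls (the pathogenic classes that
    dominate this locus); everything else stays in the full report."""
    return [
        c
        for c in calls
        if c.consequence is not None and c.consequence.cls in ("frameshift", "nonsense")
    ]


# ---------------------------------------------------------------------------
# Frequency annotation


@dataclass(frozen=True)
class FrequencyRecord:
    chrom: str
    pos: int
    ref: str
    alt: str
    frequency_percent: float
    rsid: Optional[str] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.frequency_percent <= 100.0:
            raise ValueError("frequency must be a percentage in [0, 100]")

    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


def read_frequency_table(path_or_text) -> list[FrequencyRecord]:
    """Read a TSV with columns chrom, pos, ref, alt, freq_percent, rsid.

    Malformed rows are skipped; accepts a path, file handle, or raw text.
    """
    if hasattr(path_or_text, "read"):
        handle = path_or_text
    elif "\n" in str(path_or_text) or "\t" in str(path_or_text):
        handle = io.StringIO(str(path_or_text))
    else:
        handle = open(path_or_text)
    records: list[FrequencyRecord] = []
    with handle:
        reader = csv.DictReader(handle, delimiter="\t")
        for row in reader:
            try:
                records.append(
                    FrequencyRecord(
                        chrom=row["chrom"],
                        pos=int(row["pos"]),
                        ref=row["ref"].upper(),
                        alt=row["alt"].upper(),
                        frequency_percent=float(row["freq_percent"]),
                        rsid=(row.get("rsid") or None),
                    )
                )
            except (KeyError, TypeError, ValueError):
                continue  # malformed row: skip
    return records


def annotate_frequency(
    calls: Sequence[VariantCall], table: Sequence[FrequencyRecord], chrom: str
) -> list[VariantCall]:
    """Attach population frequencies by exact left-aligned VCF key.

    Matching is deliberately exact on (chrom, pos, ref, alt): population
    databases left-align indels, so the 3'-shifted HGVS rendering must never
    be used to build the lookup key. Misses get an explicit ``NA`` flag.
    """
    index = {r.key(): r for r in table}
    out = []
    for c in calls:
        if c.vcf_fields is None:
            out.append(c)
            continue
        pos, ref_a, alt_a = c.vcf_fields
        rec = index.get((chrom, pos, ref_a, alt_a))
        if rec is None:
            new = dc_replace_call(c)
            if "frequency:NA" not in new.flags:
                new.flags.append("frequency:NA")
            out.append(new)
        else:
            out.append(
                dc_replace_call(c, frequency_percent=rec.frequency_percent, rsid=rec.rsid)
            )
    return out


# ---------------------------------------------------------------------------
# VCF output


def write_vcf(
    calls: Sequence[VariantCall],
    ref: AmpliconReference,
    sample_id: str = "SAMPLE",
) -> str:
    """Render finalized calls as VCF 4.2 text (sorted, anchored, left-aligned)."""
    chrom, gstart, gend = ref.locus
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={chrom},length={gend}>",
        f"##region={chrom}:{gstart}-{gend}",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##INFO=<ID=HGVSC,Number=1,Type=String,Description="HGVS c. notation">',
        '##INFO=<ID=CSQ,Number=1,Type=String,Description="Consequence class">',
        '##INFO=<ID=FREQ,Number=1,Type=Float,Description="Population frequency, percent">',
        f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample_id}",
    ]
    gt_map = {"hemizygous": "1", "homozygous": "1/1", "heterozygous": "0/1", "unknown": "./1"}
    body = []
    for c in calls:
        if c.vcf_fields is None:
            raise ValueError("write_vcf requires finalized calls")
        pos, ref_a, alt_a = c.vcf_fields
        info = []
        if c.hgvs_c:
            info.append(f"HGVSC={c.hgvs_c}")
        if c.consequence:
            info.append(f"CSQ={c.consequence.cls}")
        if c.frequency_percent is not None:
            info.append(f"FREQ={c.frequency_percent}")
        body.append(
            (
                pos,
                f"{chrom}\t{pos}\t{c.rsid or '.'}\t{ref_a}\t{alt_a}\t.\tPASS\t"
                f"{';'.join(info) or '.'}\tGT\t{gt_map.get(c.zygosity, './1')}",
            )
        )
    body.sort(key=lambda t: t[0])
    return "\n".join(lines + [b for _, b in body]) + "\n"
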