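"""Reference, coordinate and variant model for a single PCR amplicon.

Everything in this package works in 1-based coordinates on the *plus strand*
of the amplicon (the strand stored in the reference FASTA). The coding strand
of RPGR ORF15 is the minus strand of the genomic plus strand, so transcript
(HGVS c.) coordinates run antiparallel to the amplicon for the real locus and
for the default synthetic references; :class:`CoordinateMap` captures that.

Variants are stored as interval replacements: the reference substring over
``[start, end]`` is replaced by ``alt``. A pure insertion after position ``p``
is encoded as ``start = p + 1, end = p`` with an empty ``ref``. A duplication
is an interval whose ``alt`` equals ``ref + ref`` — applying it appends an
exact extra copy of the interval. This representation keeps the equivalence
algebra trivial: two variant sets describe the same allele if and only if
applying them to the reference yields the same string. VCF anchor bases are
added only at export time.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from typing import Iterable, Literal, Optional, Sequence

_COMP = str.maketrans("ACGTacgt", "TGCAtgca")
_ALPHABET = frozenset("ACGT")

Zygosity = Literal["hemizygous", "homozygous", "heterozygous", "unknown"]


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGT string."""
    return seq.translate(_COMP)[::-1]


def complement(seq: str) -> str:
    return seq.translate(_COMP)


class RefMismatchError(ValueError):
    """A variant's ref allele disagrees with the reference sequence."""


class OverlapError(ValueError):
    """Two variants in one set occupy overlapping reference intervals."""


class HgvsError(ValueError):
    """Unparseable or unsupported HGVS c. expression."""


class UnmappableError(ValueError):
    """An amplicon position falls outside every mapped segment."""


# ---------------------------------------------------------------------------
# Reference


@dataclass(frozen=True)
class AmpliconReference:
    """A single long-range PCR amplicon and its genomic anchoring.

    Parameters
    ----------
    name:
        Record name (FASTA header).
    plus_seq:
        Upper-case ACGT sequence of the amplicon plus strand.
    locus:
        ``(chrom, start, end)``, 1-based inclusive genomic span; the span
        length must equal ``len(plus_seq)``.
    primer_fwd, primer_rev:
        1-based inclusive primer intervals in amplicon coordinates.
    coding_strand:
        ``"plus"`` or ``"minus"`` — which amplicon strand carries the coding
        sequence. ORF15 is transcribed from the minus strand of the standard
        genomic plus strand.
    tandem_block:
        Optional ``(start, end, unit_len)`` of an embedded exact tandem repeat
        (plus-strand coordinates); recorded by the synthetic generator so that
        duplication truth sets can be placed inside it.
    """

    name: str
    plus_seq: str
    locus: tuple[str, int, int]
    primer_fwd: tuple[int, int]
    primer_rev: tuple[int, int]
    coding_strand: Literal["plus", "minus"] = "minus"
    tandem_block: Optional[tuple[int, int, int]] = None

    def __post_init__(self) -> None:
        chrom, start, end = self.locus
        if end - start + 1 != len(self.plus_seq):
            raise ValueError(
                f"locus span {chrom}:{start}-{end} ({end - start + 1} bp) does "
                f"not match sequence length {len(self.plus_seq)}"
            )
        if set(self.plus_seq) - _ALPHABET:
            bad = sorted(set(self.plus_seq) - _ALPHABET)
            raise ValueError(f"sequence contains non-ACGT symbols: {bad}")
        for label, (a, b) in (("primer_fwd", self.primer_fwd), ("primer_rev", self.primer_rev)):
            if not (1 <= a <= b <= len(self.plus_seq)):
                raise ValueError(f"{label} interval {a}-{b} outside amplicon")

    @property
    def length(self) -> int:
        return len(self.plus_seq)

    def g_fraction(self) -> float:
        return self.plus_seq.count("G") / len(self.plus_seq)


# ---------------------------------------------------------------------------
# Coordinate map (amplicon plus strand <-> transcript c. coordinates)


@dataclass(frozen=True)
class Segment:
    """One mapped amplicon interval.

    ``c_anchor`` is the transcript coordinate attached to the transcript-5'
    edge of the segment: the c. position itself for ``coding`` segments, the
    coordinate of the adjacent exonic base for ``intron_offset`` segments
    (offsets are emitted as ``c.<anchor>-<K>``), and the ``*N`` offset of the
    transcript-5' edge for ``utr3`` segments.
    """

    start: int
    end: int
    kind: Literal["coding", "intron_offset", "utr3"]
    c_anchor: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("segment start > end")
        if self.kind not in ("coding", "intron_offset", "utr3"):
            raise ValueError(f"unknown segment kind {self.kind!r}")


@dataclass(frozen=True)
class CoordinateMap:
    """Maps amplicon plus-strand positions to transcript c. labels."""

    transcript_id: str
    orientation: Literal["same", "opposite"]
    segments: tuple[Segment, ...]

    def __post_init__(self) -> None:
        segs = sorted(self.segments, key=lambda s: s.start)
        for a, b in zip(segs, segs[1:]):
            if a.end >= b.start:
                raise ValueError("coordinate map segments overlap")

    def segment_at(self, pos: int) -> Segment:
        for seg in self.segments:
            if seg.start <= pos <= seg.end:
                return seg
        raise UnmappableError(f"amplicon position {pos} is outside every mapped segment")

    def _t_offset(self, seg: Segment, pos: int) -> int:
        """Transcript-sense offset of ``pos`` from the segment's 5' edge."""
        return (pos - seg.start) if self.orientation == "same" else (seg.end - pos)

    def c_coding(self, pos: int) -> int:
        """Coding c. coordinate of an amplicon position (coding segments only)."""
        seg = self.segment_at(pos)
        if seg.kind != "coding":
            raise UnmappableError(f"position {pos} is not in a coding segment")
        return seg.c_anchor + self._t_offset(seg, pos)

    def c_label(self, pos: int) -> str:
        """HGVS position label (without the leading ``c.``) for a position."""
        seg = self.segment_at(pos)
        off = self._t_offset(seg, pos)
        if seg.kind == "coding":
            return str(seg.c_anchor + off)
        if seg.kind == "utr3":
            return f"*{seg.c_anchor + off}"
        # intron_offset: offsets count backwards from the adjacent exon base
        k = (seg.end - seg.start + 1) - off
        return f"{seg.c_anchor}-{k}"

    def t_index(self, pos: int, length: int) -> int:
        """Transcript-sense linear index (1 at the transcript-5' amplicon end)."""
        return pos if self.orientation == "same" else length + 1 - pos

    def resolve(self, kind: str, anchor: int, offset: int) -> int:
        """Amplicon position for a parsed HGVS position.

        ``kind``/``anchor`` identify the segment class; ``offset`` is the
        coding coordinate itself for coding positions, the ``*N`` value for
        utr3, or the ``-K`` intron offset (positive K).
        """
        for seg in self.segments:
            length = seg.end - seg.start + 1
            if kind == "coding" and seg.kind == "coding":
                delta = offset - seg.c_anchor
                if 0 <= delta < length:
                    return seg.start + delta if self.orientation == "same" else seg.end - delta
            elif kind == "utr3" and seg.kind == "utr3":
                delta = offset - seg.c_anchor
                if 0 <= delta < length:
                    return seg.start + delta if self.orientation == "same" else seg.end - delta
            elif kind == "intron_offset" and seg.kind == "intron_offset" and seg.c_anchor == anchor:
                delta = length - offset  # transcript-sense offset from 5' edge
                if 0 <= delta < length:
                    return seg.start + delta if self.orientation == "same" else seg.end - delta
        raise UnmappableError(f"no segment maps {kind} anchor {anchor} offset {offset}")


# ---------------------------------------------------------------------------
# Variants


@dataclass(frozen=True)
class Variant:
    """An interval replacement edit on the amplicon plus strand.

    ``start``/``end`` are 1-based inclusive; ``end == start - 1`` encodes a
    pure insertion after ``start - 1``. ``ref`` must equal the reference
    substring over the interval.
    """

    start: int
    end: int
    ref: str
    alt: str
    zygosity: Zygosity = "unknown"

    def __post_init__(self) -> None:
        if self.end < self.start - 1:
            raise ValueError(f"invalid interval [{self.start}, {self.end}]")
        if self.end - self.start + 1 != len(self.ref):
            raise ValueError(
                f"interval [{self.start}, {self.end}] does not match ref length {len(self.ref)}"
            )
        if not self.alt and not self.ref:
            raise ValueError("empty variant (no ref, no alt)")
        for allele in (self.ref, self.alt):
            if set(allele) - _ALPHABET:
                raise ValueError(f"non-ACGT allele {allele!r}")

    @property
    def kind(self) -> str:
        """Derived class: SNV, del, ins, dup, or delins."""
        if len(self.ref) == 1 and len(self.alt) == 1:
            return "SNV"
        if not self.alt:
            return "del"
        if not self.ref:
            return "ins"
        if self.alt == self.ref + self.ref:
            return "dup"
        return "delins"

    @property
    def net(self) -> int:
        return len(self.alt) - len(self.ref)

    def check_against(self, ref_seq: str) -> None:
        if self.start < 1 or self.end > len(ref_seq):
            raise RefMismatchError(
                f"variant interval [{self.start}, {self.end}] outside reference of "
                f"length {len(ref_seq)}"
            )
        found = ref_seq[self.start - 1 : self.end]
        if found != self.ref:
            raise RefMismatchError(
                f"ref allele mismatch at {self.start}-{self.end}: variant says "
                f"{self.ref!r}, reference has {found!r}"
            )


@dataclass(frozen=True)
class VariantSet:
    """A sorted, pairwise non-overlapping collection of variants."""

    variants: tuple[Variant, ...]

    def __init__(self, variants: Iterable[Variant] = ()) -> None:
        ordered = tuple(sorted(variants, key=lambda v: (v.start, v.end)))
        for a, b in zip(ordered, ordered[1:]):
            if a.end >= b.start:
                raise OverlapError(
                    f"variants at [{a.start},{a.end}] and [{b.start},{b.end}] overlap"
                )
        object.__setattr__(self, "variants", ordered)

    def __iter__(self):
        return iter(self.variants)

    def __len__(self) -> int:
        return len(self.variants)

    def check_against(self, ref_seq: str) -> None:
        for v in self.variants:
            v.check_against(ref_seq)


def apply_variant_set(ref_seq: str, vs: VariantSet | Sequence[Variant]) -> str:
    """Apply a variant set to a reference string.

    Edits are applied right to left so earlier coordinates stay valid. The
    length change equals the sum of ``len(alt) - len(ref)`` over the set.
    """
    if not isinstance(vs, VariantSet):
        vs = VariantSet(vs)
    vs.check_against(ref_seq)
    out = ref_seq
    for v in reversed(vs.variants):
        out = out[: v.start - 1] + v.alt + out[v.end :]
    return out


def sets_equivalent(ref_seq: str, a: VariantSet, b: VariantSet) -> bool:
    """True iff both sets edit ``ref_seq`` to the identical string.

    Two call sets that look nothing alike in HGVS terms (e.g. a long insertion
    plus nearby SNVs versus two tandem duplications) can still describe the
    same allele; this is the ground-truth comparison the whole pipeline is
    judged by.
    """
    return apply_variant_set(ref_seq, a) == apply_variant_set(ref_seq, b)


# ---------------------------------------------------------------------------
# Normalization


def _shift_right(ref_seq: str, v: Variant, max_end: Optional[int]) -> Variant:
    """Shift an indel to its highest-coordinate equivalent position."""
    limit = len(ref_seq) if max_end is None else min(max_end, len(ref_seq))
    if v.kind == "del":
        s0, L = v.start - 1, len(v.ref)
        while s0 + L < limit and ref_seq[s0] == ref_seq[s0 + L]:
            s0 += 1
        return replace(v, start=s0 + 1, end=s0 + L, ref=ref_seq[s0 : s0 + L])
    if v.kind in ("ins", "dup"):
        if v.kind == "dup":
            v = dup_to_ins(v)
        alt, i = v.alt, v.start - 1  # insert before 0-based index i
        while i < limit and alt[0] == ref_seq[i]:
            alt = alt[1:] + ref_seq[i]
            i += 1
        return replace(v, start=i + 1, end=i, ref="", alt=alt)
    return v


def _shift_left(ref_seq: str, v: Variant, min_start: int = 1) -> Variant:
    """Shift an indel to its lowest-coordinate equivalent position."""
    if v.kind == "del":
        s0, L = v.start - 1, len(v.ref)
        while s0 >= min_start and ref_seq[s0 - 1] == ref_seq[s0 + L - 1]:
            s0 -= 1
        return replace(v, start=s0 + 1, end=s0 + L, ref=ref_seq[s0 : s0 + L])
    if v.kind in ("ins", "dup"):
        if v.kind == "dup":
            v = dup_to_ins(v)
        alt, i = v.alt, v.start - 1
        while i > min_start - 1 and alt[-1] == ref_seq[i - 1]:
            alt = ref_seq[i - 1] + alt[:-1]
            i -= 1
        return replace(v, start=i + 1, end=i, ref="", alt=alt)
    return v


def normalize_3prime(ref_seq: str, v: Variant, max_end: Optional[int] = None) -> Variant:
    """3'-shift an indel within ``ref_seq`` (highest equivalent coordinate).

    SNVs and delins are returned unchanged. The edited product is invariant:
    applying the result to ``ref_seq`` gives the same string as applying the
    input. A duplication is shifted via its insertion form and re-classified,
    so the operation is idempotent. ``max_end`` optionally caps the shift (used
    to keep normalized calls from sliding into a neighbouring variant).
    """
    if v.kind not in ("del", "ins", "dup"):
        return v
    shifted = _shift_right(ref_seq, v, max_end)
    if shifted.kind == "ins":
        shifted = classify_dup(ref_seq, shifted)
    return shifted


def normalize_5prime(ref_seq: str, v: Variant, min_start: int = 1) -> Variant:
    """Left-align an indel (lowest equivalent coordinate, VCF convention)."""
    if v.kind not in ("del", "ins", "dup"):
        return v
    return _shift_left(ref_seq, v, min_start)


def dup_to_ins(v: Variant) -> Variant:
    """Re-express a duplication as the equivalent pure insertion after it."""
    if v.kind != "dup":
        raise ValueError("not a duplication")
    return replace(v, start=v.end + 1, end=v.end, ref="", alt=v.ref)


def classify_dup(ref_seq: str, v: Variant) -> Variant:
    """Re-express an insertion as a duplication when one exists.

    If the inserted string equals the reference segment immediately 5' of the
    insertion point (same length), the variant becomes a duplication of that
    segment; otherwise it is returned unchanged. Insertions longer than the
    available 5' context are never classified as duplications.
    """
    if v.kind != "ins":
        return v
    L = len(v.alt)
    p = v.start - 1  # 0-based insertion index == number of bases 5' of the site
    if L == 0 or p < L:
        return v
    if ref_seq[p - L : p] == v.alt:
        return Variant(
            start=p - L + 1, end=p, ref=v.alt, alt=v.alt + v.alt, zygosity=v.zygosity
        )
    return v


def map_variant_rc(v: Variant, length: int) -> Variant:
    """Mirror a variant onto the reverse-complement strand of a sequence."""
    return Variant(
        start=length - v.end + 1,
        end=length - v.start + 1,
        ref=revcomp(v.ref),
        alt=revcomp(v.alt),
        zygosity=v.zygosity,
    )


def normalize_transcript_3prime(
    ref_seq: str, v: Variant, cmap: CoordinateMap, max_shift_interval: Optional[tuple[int, int]] = None
) -> Variant:
    """3'-shift and dup-classify in *transcript* sense.

    For an opposite-orientation transcript the transcript 3' direction is the
    amplicon 5' direction, so the variant is mirrored onto the reverse
    complement, shifted right there, and mirrored back.
    ``max_shift_interval`` is a plus-strand interval (lo, hi) the normalized
    variant must stay inside (exclusive of neighbouring variants).
    """
    if v.kind not in ("del", "ins", "dup"):
        return v
    if cmap.orientation == "same":
        cap = None if max_shift_interval is None else max_shift_interval[1]
        return normalize_3prime(ref_seq, v, max_end=cap)
    L = len(ref_seq)
    rc_seq = revcomp(ref_seq)
    rv = map_variant_rc(v, L)
    cap = None if max_shift_interval is None else L - max_shift_interval[0] + 1
    out = normalize_3prime(rc_seq, rv, max_end=cap)
    return map_variant_rc(out, L)


# ---------------------------------------------------------------------------
# HGVS c. rendering and parsing


def _transcript_alleles(v: Variant, cmap: CoordinateMap) -> tuple[str, str]:
    if cmap.orientation == "same":
        return v.ref, v.alt
    return revcomp(v.ref), revcomp(v.alt)


def _range_label(v_start: int, v_end: int, cmap: CoordinateMap, length: int) -> tuple[str, str]:
    """Transcript-ordered (5', 3') position labels for a plus-strand interval."""
    ends = sorted((v_start, v_end), key=lambda p: cmap.t_index(p, length))
    return cmap.c_label(ends[0]), cmap.c_label(ends[1])


def to_hgvs_c(v: Variant, cmap: CoordinateMap, ref_seq: str) -> str:
    """HGVS c. string for a variant (3'-normalized on the transcript sense).

    Emitted dialect: ``c.N R>A`` SNVs (transcript-strand alleles), ``c.XdelR``
    / ``c.X_Ydel`` deletions, ``c.Xdup`` / ``c.X_Ydup`` duplications,
    ``c.X_YinsSEQ`` insertions, and ``c.XdelinsSEQ`` / ``c.X_YdelinsSEQ``
    replacements; intronic positions use the ``c.A-K`` form and 3' UTR
    positions the ``c.*N`` form.
    """
    v.check_against(ref_seq)
    L = len(ref_seq)
    tref, talt = _transcript_alleles(v, cmap)
    kind = v.kind
    if kind == "SNV":
        return f"c.{cmap.c_label(v.start)}{tref}>{talt}"
    if kind == "del":
        if len(v.ref) == 1:
            return f"c.{cmap.c_label(v.start)}del{tref}"
        lo, hi = _range_label(v.start, v.end, cmap, L)
        return f"c.{lo}_{hi}del"
    if kind == "dup":
        if len(v.ref) == 1:
            return f"c.{cmap.c_label(v.start)}dup"
        lo, hi = _range_label(v.start, v.end, cmap, L)
        return f"c.{lo}_{hi}dup"
    if kind == "ins":
        # flanking plus-strand positions are (start-1, start); order them in
        # transcript sense
        p5, p3 = v.start - 1, v.start
        if cmap.t_index(p5, L) > cmap.t_index(p3, L):
            p5, p3 = p3, p5
        return f"c.{cmap.c_label(p5)}_{cmap.c_label(p3)}ins{talt}"
    # delins
    if len(v.ref) == 1:
        return f"c.{cmap.c_label(v.start)}delins{talt}"
    lo, hi = _range_label(v.start, v.end, cmap, L)
    return f"c.{lo}_{hi}delins{talt}"


_POS_RE = re.compile(r"^(?:\*(?P<utr>\d+)|(?P<base>\d+)(?:-(?P<off>\d+))?)$")
_HGVS_RE = re.compile(
    r"^c\.(?P<p1>[^_]+?)(?:_(?P<p2>[^_]+?))?"
    r"(?P<op>(?:[ACGT]>[ACGT])|delins[ACGT]+|del[ACGT]*|dup|ins[ACGT]+)$"
)


def _parse_pos(token: str, cmap: CoordinateMap) -> int:
    m = _POS_RE.match(token)
    if not m:
        raise HgvsError(f"cannot parse position {token!r}")
    if m.group("utr") is not None:
        return cmap.resolve("utr3", 0, int(m.group("utr")))
    base = int(m.group("base"))
    if m.group("off") is not None:
        return cmap.resolve("intron_offset", base, int(m.group("off")))
    return cmap.resolve("coding", 0, base)


def parse_hgvs_c(text: str, cmap: CoordinateMap, ref_seq: str) -> Variant:
    """Parse the HGVS c. dialect emitted by :func:`to_hgvs_c`.

    Inverse of :func:`to_hgvs_c` up to 3' normalization. Protein-level and
    other unsupported notations are rejected with :class:`HgvsError`.
    """
    m = _HGVS_RE.match(text.strip())
    if not m:
        raise HgvsError(f"unsupported or malformed HGVS expression {text!r}")
    op = m.group("op")
    L = len(ref_seq)
    opposite = cmap.orientation == "opposite"
    p1 = _parse_pos(m.group("p1"), cmap)
    p2 = _parse_pos(m.group("p2"), cmap) if m.group("p2") else None

    def plus_interval(a: int, b: Optional[int]) -> tuple[int, int]:
        if b is None:
            return a, a
        return (min(a, b), max(a, b))

    if ">" in op:
        tref, talt = op[0], op[2]
        if p2 is not None:
            raise HgvsError(f"range not allowed for SNV: {text!r}")
        ref_b, alt_b = (complement(tref), complement(talt)) if opposite else (tref, talt)
        v = Variant(start=p1, end=p1, ref=ref_b, alt=alt_b)
        v.check_against(ref_seq)
        return v
    if op.startswith("delins"):
        seq = op[len("delins") :]
        s, e = plus_interval(p1, p2)
        alt = revcomp(seq) if opposite else seq
        v = Variant(start=s, end=e, ref=ref_seq[s - 1 : e], alt=alt)
        if v.kind not in ("delins", "SNV", "dup"):
            pass
        return v
    if op.startswith("del"):
        stated = op[len("del") :]
        s, e = plus_interval(p1, p2)
        v = Variant(start=s, end=e, ref=ref_seq[s - 1 : e], alt="")
        if stated:
            tref = revcomp(v.ref) if opposite else v.ref
            if tref != stated:
                raise HgvsError(
                    f"{text!r}: stated deleted allele {stated} does not match "
                    f"reference {tref}"
                )
        return v
    if op == "dup":
        s, e = plus_interval(p1, p2)
        seg = ref_seq[s - 1 : e]
        return Variant(start=s, end=e, ref=seg, alt=seg + seg)
    if op.startswith("ins"):
        seq = op[len("ins") :]
        if p2 is None:
            raise HgvsError(f"insertion requires flanking range: {text!r}")
        s, e = plus_interval(p1, p2)
        if e != s + 1:
            raise HgvsError(f"insertion flanks must be adjacent: {text!r}")
        alt = revcomp(seq) if opposite else seq
        return Variant(start=s + 1, end=s, ref="", alt=alt)
    raise HgvsError(f"unsupported operation in {text!r}")
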