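"""A deliberately naive mapping/pileup caller, plus cross-pipeline concordance.

This module stands in for the conventional "map reads, then call by allele
fraction" secondary analysis. It seeds each read at the *leftmost* reference
occurrence of its first seedable k-mer and extends with a unit-cost banded
alignment — precisely the combination that goes wrong in a low-complexity
repeat tract: reads carrying an extra repeat unit get anchored one unit off
or absorb the length difference as mismatches, and the resulting split read
support surfaces as "heterozygous" SNVs in haploid male samples. The module
exists to reproduce that failure mode class, not to re-implement a
production mapper; the assembly pipeline is the accurate path.

Concordance: every unique variant (keyed by its left-aligned VCF rendering,
so that differently named but identical edits match) is tallied across
samples for both pipelines, and assigned call quality *high* only when its
per-sample presence is identical in both — any discordance marks it *low*.
"""

from __future__ import annotations

import re
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import edlib

from .calls import VariantCall, left_aligned_vcf_fields
from .reference import AmpliconReference, Variant, revcomp


@dataclass(frozen=True)
class BaselineParams:
    seed_k: int = 31
    band: int = 40
    min_depth: int = 20
    het_min_af: float = 0.2
    hom_min_af: float = 0.8

    def __post_init__(self) -> None:
        if not 0 < self.het_min_af < self.hom_min_af <= 1.0:
            raise ValueError("allele-fraction bands must satisfy 0 < het < hom <= 1")


@dataclass
class ReadPlacement:
    read_id: str
    ref_start: int  # 1-based
    strand: str  # "+" or "-"
    ops: list  # [(op, length)] with op in M/X/I/D (M match, X mismatch)

    def consumed_read(self) -> int:
        return sum(n for op, n in self.ops if op in ("M", "X", "I"))


_CIG_RE = re.compile(r"(\d+)([=XIDM])")


def _cigar_ops(cigar: str) -> list:
    return [(m.group(2), int(m.group(1))) for m in _CIG_RE.finditer(cigar)]


def _index_ref(ref_seq: str, k: int) -> dict:
    idx: dict = {}
    for i in range(len(ref_seq) - k + 1):
        km = ref_seq[i : i + k]
        if km not in idx:  # leftmost occurrence only — naive by design
            idx[km] = i
    return idx


class BaselineMapper:
    """Seed-and-extend placement of reads onto one amplicon reference."""

    def __init__(self, ref: AmpliconReference, params: BaselineParams = BaselineParams()):
        self.ref = ref
        self.params = params
        self._index = _index_ref(ref.plus_seq, params.seed_k)

    def place_read(self, read_id: str, seq: str) -> Optional[ReadPlacement]:
        """Best-effort placement; ``None`` when no seed k-mer matches.

        The first k-mer (scanning left to right) with a reference hit anchors
        the read at that k-mer's *leftmost* reference occurrence; the read is
        then aligned end-to-end against a banded reference window with unit
        costs (edlib). Both strands are tried; the fewer-edit strand wins.
        """
        k = self.params.seed_k
        best: Optional[tuple[int, ReadPlacement]] = None
        for strand, s in (("+", seq), ("-", revcomp(seq))):
            if len(s) < k:
                continue
            hit = None
            for off in range(0, len(s) - k + 1):
                pos = self._index.get(s[off : off + k])
                if pos is not None:
                    hit = (off, pos)
                    break
            if hit is None:
                continue
            off, pos = hit
            start0 = max(pos - off - self.params.band, 0)
            end0 = min(pos - off + len(s) + self.params.band, len(self.ref.plus_seq))
            window = self.ref.plus_seq[start0:end0]
            res = edlib.align(s, window, mode="HW", task="path")
            if res["editDistance"] < 0:
                continue
            loc = res["locations"][0]
            nice = edlib.getNiceAlignment(res, s, window)
            ops = _ops_from_nice(nice)
            placement = ReadPlacement(
                read_id=read_id, ref_start=start0 + loc[0] + 1, strand=strand, ops=ops
            )
            cand = (res["editDistance"], placement)
            if best is None or cand[0] < best[0]:
                best = cand
        return best[1] if best else None


def _ops_from_nice(nice: dict) -> list:
    q, t = nice["query_aligned"], nice["target_aligned"]
    ops: list = []
    for a, b in zip(q, t):
        if a == "-":
            op = "D"
        elif b == "-":
            op = "I"
        elif a == b:
            op = "M"
        else:
            op = "X"
        if ops and ops[-1][0] == op:
            ops[-1][1] += 1
        else:
            ops.append([op, 1])
    return [(op, n) for op, n in ops]


@dataclass
class Pileup:
    """Per-position allele tallies over the amplicon plus strand."""

    length: int
    base_counts: list  # list of dict base -> count
    del_counts: dict  # (start, end) -> count
    ins_counts: dict  # (after_pos, seq) -> count
    depth: list

    @classmethod
    def empty(cls, length: int) -> "Pileup":
        return cls(
            length=length,
            base_counts=[defaultdict(int) for _ in range(length + 1)],
            del_counts=defaultdict(int),
            ins_counts=defaultdict(int),
            depth=[0] * (length + 1),
        )

    def add_placement(self, placement: ReadPlacement, seq: str) -> None:
        s = seq if placement.strand == "+" else revcomp(seq)
        rp = placement.ref_start
        qp = 0
        for op, n in placement.ops:
            if op in ("M", "X"):
                for i in range(n):
                    if 1 <= rp + i <= self.length:
                        self.base_counts[rp + i][s[qp + i]] += 1
                        self.depth[rp + i] += 1
                rp += n
                qp += n
            elif op == "D":
                if 1 <= rp <= self.length:
                    self.del_counts[(rp, rp + n - 1)] += 1
                    for i in range(n):
                        if rp + i <= self.length:
                            self.depth[rp + i] += 1
                rp += n
            elif op == "I":
                self.ins_counts[(rp - 1, s[qp : qp + n])] += 1
                qp += n


def build_pileup(
    ref: AmpliconReference,
    reads: Iterable[tuple[str, str]],
    params: BaselineParams = BaselineParams(),
) -> tuple[Pileup, int, int]:
    """Map every read and accumulate the pileup; returns (pileup, placed, total)."""
    mapper = BaselineMapper(ref, params)
    pile = Pileup.empty(ref.length)
    placed = total = 0
    for read_id, seq in reads:
        total += 1
        pl = mapper.place_read(read_id, seq)
        if pl is None:
            continue
        placed += 1
        pile.add_placement(pl, seq)
    return pile, placed, total


def pileup_call(
    pileup: Pileup,
    ref: AmpliconReference,
    params: BaselineParams = BaselineParams(),
    sample_sex: str = "unknown",
) -> list[VariantCall]:
    """Allele-fraction threshold calling from the pileup.

    At positions with depth >= ``min_depth``, a non-reference allele with
    fraction >= ``hom_min_af`` becomes a hom/hemi call and one in
    [``het_min_af``, ``hom_min_af``) a heterozygous call; deletions and
    insertions are called from their span/string tallies the same way.
    """
    seq = ref.plus_seq
    hom_z = "hemizygous" if sample_sex == "male" else "homozygous"
    calls: list[VariantCall] = []

    def zygo(af: float) -> Optional[str]:
        if af >= params.hom_min_af:
            return hom_z
        if af >= params.het_min_af:
            return "heterozygous"
        return None

    for pos in range(1, pileup.length + 1):
        depth = pileup.depth[pos]
        if depth < params.min_depth:
            continue
        ref_base = seq[pos - 1]
        for base, count in sorted(pileup.base_counts[pos].items()):
            if base == ref_base:
                continue
            z = zygo(count / depth)
            if z is None:
                continue
            v = Variant(pos, pos, ref_base, base, zygosity=z)
            calls.append(_mk_call(v, ref, z, f"depth={depth};alt={count}"))
    for (ds, de), count in sorted(pileup.del_counts.items()):
        depth = pileup.depth[ds]
        if depth < params.min_depth:
            continue
        z = zygo(count / depth)
        if z is None:
            continue
        v = Variant(ds, de, seq[ds - 1 : de], "", zygosity=z)
        calls.append(_mk_call(v, ref, z, f"depth={depth};alt={count}"))
    for (after, ins_seq), count in sorted(pileup.ins_counts.items()):
        if after < 1 or after > pileup.length:
            continue
        depth = pileup.depth[after]
        if depth < params.min_depth:
            continue
        z = zygo(count / depth)
        if z is None:
            continue
        v = Variant(after + 1, after, "", ins_seq, zygosity=z)
        calls.append(_mk_call(v, ref, z, f"depth={depth};alt={count}"))
    return calls


def _mk_call(v: Variant, ref: AmpliconReference, zygosity: str, support: str) -> VariantCall:
    try:
        vcf = left_aligned_vcf_fields(v, ref.plus_seq, ref.locus)
    except ValueError:
        vcf = None
    return VariantCall(
        variant=v, caller="baseline", zygosity=zygosity, support=support, vcf_fields=vcf
    )


def flag_het_in_haploid(calls: Sequence[VariantCall], sample_sex: str) -> list[VariantCall]:
    """Mark heterozygous calls in male (haploid X) samples as artifacts.

    A heterozygous genotype on a single-copy locus is biologically impossible
    and is the signature low-quality marker of the standard pipeline here.
    Unknown sex leaves calls unflagged (with a warning flag on none).
    """
    out = []
    for c in calls:
        if sample_sex == "male" and c.zygosity == "heterozygous":
            if "het_in_haploid" not in c.flags:
                c.flags.append("het_in_haploid")
        out.append(c)
    return out


# ---------------------------------------------------------------------------
# Concordance


@dataclass
class ConcordanceRow:
    key: tuple  # (pos, ref, alt)
    baseline_samples: int
    het_count: int
    het_male_count: int
    hom_hemi_count: int
    novel_samples: int
    quality: str  # "high" | "low"

    def to_tsv_row(self) -> str:
        pos, ref_a, alt_a = self.key
        novel = f"Yes ({self.novel_samples})" if self.novel_samples else "No"
        return (
            f"{pos}\t{ref_a}\t{alt_a}\t{self.baseline_samples}\t"
            f"{self.het_count} ({self.het_male_count})\t{self.hom_hemi_count}\t"
            f"{novel}\t{self.quality.capitalize()}"
        )


CONCORDANCE_HEADER = (
    "pos\tref\talt\t#_samples\thet_(het_males)\thom_hemi\tnovel_pipeline\tcall_quality"
)


def concordance_table(
    baseline_calls: dict[str, Sequence[VariantCall]],
    novel_calls: dict[str, Sequence[VariantCall]],
    sexes: dict[str, str],
) -> list[ConcordanceRow]:
    """Per-variant cross-pipeline tally with high/low call quality.

    Quality is *high* iff the per-sample presence of the variant is identical
    in both pipelines across every sample; variants absent everywhere yield
    no row. Deterministic and symmetric in sample order.
    """
    samples = sorted(set(baseline_calls) | set(novel_calls))

    def presence(calls_by_sample):
        seen: dict = defaultdict(set)
        for sample in samples:
            for c in calls_by_sample.get(sample, ()):  # keyed left-aligned
                if c.vcf_fields is not None:
                    seen[c.vcf_fields].add(sample)
        return seen

    base_seen = presence(baseline_calls)
    novel_seen = presence(novel_calls)
    rows: list[ConcordanceRow] = []
    for key in sorted(set(base_seen) | set(novel_seen)):
        b_samples = base_seen.get(key, set())
        n_samples = novel_seen.get(key, set())
        het = het_m = hom = 0
        for sample in b_samples:
            for c in baseline_calls.get(sample, ()):  # count zygosity classes
                if c.vcf_fields == key:
                    if c.zygosity == "heterozygous":
                        het += 1
                        if sexes.get(sample) == "male":
                            het_m += 1
                    elif c.zygosity in ("homozygous", "hemizygous"):
                        hom += 1
                    break
        quality = "high" if b_samples == n_samples else "low"
        rows.append(
            ConcordanceRow(
                key=key,
                baseline_samples=len(b_samples),
                het_count=het,
                het_male_count=het_m,
                hom_hemi_count=hom,
                novel_samples=len(n_samples),
                quality=quality,
            )
        )
    return rows
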