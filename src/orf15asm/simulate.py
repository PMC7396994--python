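"""Synthetic ORF15-like references and paired-end amplicon reads.

Patient reads for the real locus cannot be shared, so every test and
benchmark in this package runs on synthetic data that reproduces the
*structural* difficulties of the region: a ~2.1 kb amplicon whose coding
(minus) strand is a low-complexity purine-rich run of Glu/Gly codons — hence
a plus strand with well under 7% G — containing an exact tandem repeat block,
flanked by unique primer sites; deep 2x151 paired-end coverage from ~273 bp
fragments; and primer-site over-representation.

The generator does not emulate platform error profiles, PCR stutter or
chimeras, or amplification failure; substitution errors are uniform and
sequencing indel errors default to off, so that indel calls downstream are
attributable to the variants that were spiked in, not to the error model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np

from .reference import (
    AmpliconReference,
    CoordinateMap,
    Segment,
    Variant,
    VariantSet,
    apply_variant_set,
    revcomp,
)

# Purine-only Glu/Gly-heavy codon pool for the coding strand. No C anywhere
# (keeps plus-strand G near zero) and no GGG (avoids long G homopolymers).
DEFAULT_CODON_POOL: tuple[tuple[str, float], ...] = (
    ("GAA", 0.30),
    ("GAG", 0.30),
    ("GGA", 0.20),
    ("AGG", 0.10),
    ("AAG", 0.10),
)

DEFAULT_LOCUS = ("chrX", 38144633, 38146732)


@dataclass(frozen=True)
class RepeatModel:
    """Shape of the synthetic amplicon (coding-strand view)."""

    codon_pool: tuple[tuple[str, float], ...] = DEFAULT_CODON_POOL
    target_length: int = 2100
    unique_flank_length: int = 60
    tandem_block: Optional[tuple[int, int]] = (27, 3)  # (unit length, copies)

    def __post_init__(self) -> None:
        if not self.codon_pool:
            raise ValueError("codon pool is empty")
        if self.target_length < 2 * self.unique_flank_length + 300:
            raise ValueError("target_length too short for flanks + core")
        if self.tandem_block is not None:
            unit, copies = self.tandem_block
            if unit % 3 or unit <= 0 or copies < 2:
                raise ValueError("tandem unit must be a positive codon multiple, >=2 copies")


@dataclass(frozen=True)
class SimulationConfig:
    """Sequencing-run emulation parameters."""

    seed: int = 0
    coverage: float = 1000.0
    read_length: int = 151
    fragment_mean: float = 273.0
    fragment_sd: float = 40.0
    sub_error_rate: float = 0.001
    indel_error_rate: float = 0.0
    primer_boost: float = 3.0
    ploidy: str = "haploid"
    allele_ratio: float = 0.5
    base_quality: int = 30

    def __post_init__(self) -> None:
        for rate in (self.sub_error_rate, self.indel_error_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("error rates must lie in [0, 1]")
        if self.ploidy not in ("haploid", "diploid"):
            raise ValueError("ploidy must be haploid or diploid")
        if not 0.0 <= self.allele_ratio <= 1.0:
            raise ValueError("allele_ratio must lie in [0, 1]")


def _balanced_flank(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def synthesize_reference(
    model: RepeatModel = RepeatModel(), seed: int = 0
) -> AmpliconReference:
    """Build a deterministic ORF15-like amplicon reference.

    The coding strand is drawn codon by codon from the weighted pool, with the
    tandem block (drawn once, then repeated exactly) embedded mid-core; the
    stored plus strand is its reverse complement. For the default purine-only
    pool the plus-strand G fraction stays far below the 7% threshold the
    selection stage relies on.
    """
    rng = np.random.default_rng(seed)
    flank_a = _balanced_flank(rng, model.unique_flank_length)
    flank_b = _balanced_flank(rng, model.unique_flank_length)
    core_len = model.target_length - 2 * model.unique_flank_length
    if core_len % 3:
        raise ValueError("core length must be a codon multiple")
    codons, weights = zip(*model.codon_pool)
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    n_codons = core_len // 3

    block = ""
    block_codons = 0
    copies = 0
    if model.tandem_block is not None:
        unit_len, copies = model.tandem_block
        unit_codons = unit_len // 3
        while True:
            unit = "".join(rng.choice(codons, size=unit_codons, p=w))
            # the unit must not be internally periodic, or copies blur together
            if all(unit[i:] != unit[: len(unit) - i] for i in range(3, len(unit), 3)):
                break
        block = unit * copies
        block_codons = (unit_len * copies) // 3

    free_codons = n_codons - block_codons
    if free_codons < 0:
        raise ValueError("tandem block larger than core")
    left_codons = free_codons // 2
    left = "".join(rng.choice(codons, size=left_codons, p=w))
    right = "".join(rng.choice(codons, size=free_codons - left_codons, p=w))
    coding = flank_a + left + block + right + flank_b

    plus = revcomp(coding)
    L = len(plus)
    block_span = None
    if block:
        # coding-strand block occupies [bs, be]; mirror to plus coordinates
        bs = model.unique_flank_length + len(left) + 1
        be = bs + len(block) - 1
        block_span = (L - be + 1, L - bs + 1, model.tandem_block[0])
    chrom, gstart, _ = DEFAULT_LOCUS
    return AmpliconReference(
        name=f"orf15_synthetic_seed{seed}",
        plus_seq=plus,
        locus=(chrom, gstart, gstart + L - 1),
        primer_fwd=(1, 25),
        primer_rev=(L - 24, L),
        coding_strand="minus",
        tandem_block=block_span,
    )


def default_coordinate_map(ref: AmpliconReference, model: RepeatModel = RepeatModel()) -> CoordinateMap:
    """Transcript map for a synthetic reference.

    The transcript runs opposite to the plus strand. The transcript-5' flank
    is treated as intron (offsets against the first coding base, anchored at
    c.1753 so codon boundaries fall on the segment edge), the core as coding,
    and the transcript-3' flank as 3' UTR — mirroring how the real amplicon
    covers intronic sequence, the ORF15 coding stretch, and UTR.
    """
    L = ref.length
    fl = model.unique_flank_length
    anchor = 1753  # codon-aligned (1753 = 3*584 + 1)
    return CoordinateMap(
        transcript_id="SYNTH_ORF15",
        orientation="opposite",
        segments=(
            Segment(1, fl, "utr3", 1),
            Segment(fl + 1, L - fl, "coding", anchor),
            Segment(L - fl + 1, L, "intron_offset", anchor),
        ),
    )


# ---------------------------------------------------------------------------
# Truth-set catalogue


def _find_plus(ref_seq: str, pattern: str, lo: int, hi: int, avoid: range) -> int:
    """1-based position of the first ``pattern`` inside [lo, hi] not in ``avoid``."""
    idx = ref_seq.find(pattern, lo - 1, hi)
    while idx != -1:
        if (idx + 1) not in avoid:
            return idx + 1
        idx = ref_seq.find(pattern, idx + 1, hi)
    raise ValueError(f"pattern {pattern!r} not found in [{lo}, {hi}]")


def spike_standard_truthsets(
    ref: AmpliconReference, zygosity: str = "hemizygous"
) -> dict[str, VariantSet]:
    """One named truth set per variant class the pipeline must recover.

    Classes mirror the real mutational spectrum of the locus: a single SNV,
    2-bp and 4-bp deletions, a 2-bp delins, 15/21/27-bp duplications placed
    inside the tandem block, a 51-bp insertion, and an empty set. Coordinates
    are derived from the reference content, so the catalogue adapts to any
    generated reference.
    """
    seq = ref.plus_seq
    L = len(seq)
    if ref.tandem_block is None:
        raise ValueError("reference has no tandem block; duplication classes unavailable")
    bs, be, unit = ref.tandem_block
    block_range = range(bs - unit, be + unit + 1)
    lo, hi = 100, L - 100

    def var(start, end, alt):
        return Variant(start, end, seq[start - 1 : end], alt, zygosity=zygosity)

    def dup(start, length):
        segment = seq[start - 1 : start - 1 + length]
        return Variant(start, start + length - 1, segment, segment + segment, zygosity=zygosity)

    # SNV: a transition at the first plus-strand T outside the block
    p = _find_plus(seq, "T", lo, hi, block_range)
    snv = var(p, p, "C")
    # 2-bp GG deletion (transcript sense) == plus-strand CC
    p = _find_plus(seq, "CC", lo, hi, block_range)
    del2 = var(p, p + 1, "")
    # 4-bp deletion
    p = _find_plus(seq, "CTC", lo, hi, block_range)
    del4 = var(p, p + 3, "")
    # 2-bp delins (plus CC -> TT, i.e. transcript GG -> AA)
    p = _find_plus(seq, "CC", (lo + hi) // 2, hi, block_range)
    alt2 = "TT" if seq[p - 1 : p + 1] != "TT" else "AA"
    delins2 = var(p, p + 1, alt2)
    # duplications inside the tandem block
    dup15 = dup(bs, 15)
    dup21 = dup(bs, 21)
    dup27 = dup(bs, unit)
    # 51-bp insertion: Glu/Gly-codon string on the transcript strand
    codons = ["GAA", "GAG", "GGA", "AGG", "GAA", "GAG", "GGA", "GAA", "GAG",
              "GGA", "AAG", "GAG", "GAA", "GGA", "GAG", "GAA", "AGG"]
    ins_seq_plus = revcomp("".join(codons))
    assert len(ins_seq_plus) == 51
    p = _find_plus(seq, "T", (lo + hi) // 3, hi, block_range)
    ins51 = Variant(p + 1, p, "", ins_seq_plus, zygosity=zygosity)

    catalogue = {
        "snv": VariantSet([snv]),
        "del2": VariantSet([del2]),
        "del4": VariantSet([del4]),
        "delins2": VariantSet([delins2]),
        "dup15": VariantSet([dup15]),
        "dup21": VariantSet([dup21]),
        "dup27": VariantSet([dup27]),
        "ins51": VariantSet([ins51]),
        "no_variant": VariantSet(),
    }
    for vs in catalogue.values():
        vs.check_against(seq)
    return catalogue


# ---------------------------------------------------------------------------
# Read simulation


@dataclass
class SimulatedSample:
    """In-memory FASTQ pair plus the truth record that produced it."""

    r1: list[tuple[str, str, str]]  # (name, seq, qual)
    r2: list[tuple[str, str, str]]
    truth: tuple[VariantSet, ...]
    config: SimulationConfig

    @property
    def reads(self) -> list[str]:
        return [seq for _, seq, _ in self.r1] + [seq for _, seq, _ in self.r2]


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _add_errors(seq: str, rng: np.random.Generator, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.flatnonzero(rng.random(arr.size) < rate)
    if hits.size:
        # substitute with a uniformly drawn *different* base
        orig = arr[hits]
        subs = _BASES[rng.integers(0, 3, size=hits.size)]
        same = subs == orig
        while np.any(same):
            subs[same] = _BASES[rng.integers(0, 3, size=int(same.sum()))]
            same = subs == orig
        arr[hits] = subs
    return arr.tobytes().decode()


def _add_indel_errors(seq: str, rng: np.random.Generator, rate: float) -> str:
    """Inject 1-bp insertion/deletion errors (off by default)."""
    out: list[str] = []
    for ch in seq:
        r = rng.random()
        if r < rate / 2:
            continue  # deletion
        if r < rate:
            out.append("ACGT"[rng.integers(0, 4)])  # insertion before the base
        out.append(ch)
    return "".join(out)


def simulate_sample(
    ref: AmpliconReference,
    truth: Union[VariantSet, Sequence[VariantSet]],
    cfg: SimulationConfig,
) -> SimulatedSample:
    """Draw paired-end reads from the edited amplicon.

    Fragments have normal(fragment_mean, fragment_sd) lengths clamped to at
    least one read length; starts are uniform with a multiplicative weight of
    ``primer_boost`` on fragments overlapping either primer span (rejection
    sampled, so the total pair count stays at coverage * length / (2 * read
    length)). Mates face inward; either fragment strand is sequenced first
    with equal probability. Deterministic per config seed.
    """
    if isinstance(truth, VariantSet):
        truth_sets: tuple[VariantSet, ...] = (truth,)
    else:
        truth_sets = tuple(truth)
    if cfg.ploidy == "diploid":
        if len(truth_sets) == 1:
            truth_sets = (truth_sets[0], truth_sets[0])
        if len(truth_sets) != 2:
            raise ValueError("diploid simulation needs two truth sets")
    haplotypes = [apply_variant_set(ref.plus_seq, vs) for vs in truth_sets]
    if cfg.coverage <= 0 or not ref.plus_seq:
        raise ValueError("coverage must be positive and reference non-empty")

    rng = np.random.default_rng(cfg.seed)
    rl = cfg.read_length
    mean_len = int(round(np.mean([len(h) for h in haplotypes])))
    n_pairs = int(round(cfg.coverage * mean_len / (2 * rl)))

    r1: list[tuple[str, str, str]] = []
    r2: list[tuple[str, str, str]] = []
    qual = chr(cfg.base_quality + 33) * rl
    boost = max(cfg.primer_boost, 1.0)
    fwd_lo, fwd_hi = ref.primer_fwd
    made = 0
    while made < n_pairs:
        if cfg.ploidy == "diploid" and rng.random() < cfg.allele_ratio:
            hap_i = 1
        else:
            hap_i = 0
        hap = haplotypes[hap_i]
        hl = len(hap)
        rev_lo = hl - (ref.length - ref.primer_rev[0])  # rev primer tracks the 3' end
        flen = int(round(rng.normal(cfg.fragment_mean, cfg.fragment_sd)))
        flen = min(max(flen, rl), hl)
        start = int(rng.integers(0, hl - flen + 1))
        touches_primer = (start + 1 <= fwd_hi) or (start + flen >= rev_lo)
        w = boost if touches_primer else 1.0
        if boost > 1.0 and rng.random() >= w / boost:
            continue
        frag = hap[start : start + flen]
        fwd = frag[:rl]
        rev = revcomp(frag[-rl:])
        if rng.random() < 0.5:
            fwd, rev = rev, fwd
        fwd = _add_errors(fwd, rng, cfg.sub_error_rate)
        rev = _add_errors(rev, rng, cfg.sub_error_rate)
        if cfg.indel_error_rate > 0:
            fwd = _add_indel_errors(fwd, rng, cfg.indel_error_rate)[:rl]
            rev = _add_indel_errors(rev, rng, cfg.indel_error_rate)[:rl]
        made += 1
        name = f"sim.{made}"
        r1.append((f"{name}/1", fwd, qual))
        r2.append((f"{name}/2", rev, qual))
    return SimulatedSample(r1=r1, r2=r2, truth=truth_sets, config=cfg)
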