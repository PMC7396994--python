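"""Contig filtering, orientation, scoring, and the three-round cascade.

The amplicon's plus strand carries less than 7% G, so G-content both rejects
unrelated sequence and fixes strand: a contig failing the threshold is
re-tested as its reverse complement (the downstream aligner does not
reverse-complement). Survivors are pre-filtered on size (>400, <2300 bp) and
mean k-mer coverage (>30, strict), ranked, and a contig counts as
*satisfactory* when its length falls strictly inside (2040, 2300).

If round 1 (plain multi-k assembly) yields no satisfactory contig, round 2
reruns assembly with the top-ranked contigs (at most five) plus the reference
as trusted inputs; round 3 uses k = {77, 99, 127} with the prior top contigs
as untrusted and the reference alone as trusted. All bound comparisons are
strict, exactly as configured.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .assemble import AssemblyParams, Contig, assemble_multi_k
from .reference import AmpliconReference, revcomp


@dataclass(frozen=True)
class SelectionThresholds:
    g_max: float = 0.15
    prefilter_size: tuple[int, int] = (400, 2300)  # open interval
    coverage_min: float = 30.0  # strict >
    satisfactory_size: tuple[int, int] = (2040, 2300)  # open interval
    max_trusted: int = 5
    round2_k: tuple[int, ...] = (55, 77, 99, 127)
    round3_k: tuple[int, ...] = (77, 99, 127)

    def __post_init__(self) -> None:
        if not 0 < self.g_max < 1:
            raise ValueError("g_max must lie in (0, 1)")
        plo, phi = self.prefilter_size
        slo, shi = self.satisfactory_size
        if not (plo <= slo and shi <= phi):
            raise ValueError("satisfactory window must lie within the prefilter window")


@dataclass
class RoundLog:
    """Per-round record of what the cascade saw and decided."""

    rounds: list[dict] = field(default_factory=list)
    selected_id: Optional[str] = None
    # all satisfactory contigs of the deciding round; a second, different one
    # is a candidate second allele in female samples
    satisfactory: list = field(default_factory=list)

    @property
    def rounds_used(self) -> int:
        return len(self.rounds)

    def add(self, **entry) -> None:
        if self.rounds_used >= 3:
            raise ValueError("at most three assembly rounds")
        self.rounds.append(entry)

    def to_dict(self) -> dict:
        return {"rounds_used": self.rounds_used, "selected": self.selected_id, "rounds": self.rounds}


def g_fraction(seq: str) -> float:
    """Fraction of G bases on the given strand."""
    if not seq:
        raise ValueError("empty sequence")
    return seq.count("G") / len(seq)


def orient_contig(seq: str, g_max: float = 0.15) -> tuple[Optional[str], float, float]:
    """Orient a contig onto the G-poor (plus) strand.

    Returns ``(oriented_seq, g_forward, g_revcomp)``; ``oriented_seq`` is
    ``None`` when neither strand passes the threshold (both fractions are
    still reported, so rejections are explainable).
    """
    g_fwd = g_fraction(seq)
    g_rev = seq.count("C") / len(seq)  # G fraction of the reverse complement
    if g_fwd < g_max:
        return seq, g_fwd, g_rev
    if g_rev < g_max:
        return revcomp(seq), g_fwd, g_rev
    return None, g_fwd, g_rev


def prefilter_contigs(
    contigs: Sequence[Contig], thresholds: SelectionThresholds = SelectionThresholds()
) -> list[Contig]:
    """Keep orientable contigs strictly inside the size window with cov > 30.

    Kept contigs are re-emitted with their plus-strand (oriented) sequence.
    """
    lo, hi = thresholds.prefilter_size
    kept: list[Contig] = []
    for c in contigs:
        if not (lo < c.length < hi):
            continue
        if not (c.mean_cov > thresholds.coverage_min):
            continue
        oriented, _, _ = orient_contig(c.seq, thresholds.g_max)
        if oriented is None:
            continue
        kept.append(Contig(id=c.id, seq=oriented, mean_cov=c.mean_cov))
    return kept


def rank_contigs(
    contigs: Sequence[Contig], thresholds: SelectionThresholds = SelectionThresholds()
) -> list[Contig]:
    """Deterministic total order: satisfactory-size first, then coverage,
    then length, then id."""
    lo, hi = thresholds.satisfactory_size

    def key(c: Contig):
        inside = lo < c.length < hi
        return (not inside, -c.mean_cov, -c.length, c.id)

    return sorted(contigs, key=key)


def select_satisfactory(
    ranked: Sequence[Contig], thresholds: SelectionThresholds = SelectionThresholds()
) -> Optional[Contig]:
    """First contig whose length lies strictly inside the satisfactory window."""
    lo, hi = thresholds.satisfactory_size
    for c in ranked:
        if lo < c.length < hi:
            return c
    return None


def run_assembly_rounds(
    reads: Sequence[str],
    ref: AmpliconReference,
    thresholds: SelectionThresholds = SelectionThresholds(),
    params: AssemblyParams = AssemblyParams(),
) -> tuple[Optional[Contig], RoundLog]:
    """Up to three assembly rounds, stopping at the first satisfactory contig.

    Returns ``(contig, log)``; the contig is ``None`` (a reportable failure,
    not an exception) when even round 3 yields nothing satisfactory.
    """
    log = RoundLog()
    kmer_cache: dict = {}
    prior_top: list[Contig] = []

    def run_round(round_no: int, k_list, trusted, untrusted):
        nonlocal prior_top
        rp = AssemblyParams(
            k_list=tuple(k for k in k_list),
            min_kmer_count=params.min_kmer_count,
            trusted_contigs=tuple(trusted),
            untrusted_contigs=tuple(untrusted),
            tip_length_factor=params.tip_length_factor,
            bubble_max_divergence=params.bubble_max_divergence,
        )
        contigs = assemble_multi_k(reads, rp, kmer_cache=kmer_cache)
        kept = prefilter_contigs(contigs, thresholds)
        ranked = rank_contigs(kept, thresholds)
        selected = select_satisfactory(ranked, thresholds)
        if selected is not None:
            lo, hi = thresholds.satisfactory_size
            log.satisfactory = [c for c in ranked if lo < c.length < hi]
        if ranked:
            prior_top = ranked[: thresholds.max_trusted]
        elif contigs:
            fallback = sorted(contigs, key=lambda c: (-c.length, -c.mean_cov, c.id))
            prior_top = fallback[: thresholds.max_trusted]
        log.add(
            round=round_no,
            total_contigs=len(contigs),
            prefiltered=len(kept),
            selected=None if selected is None else selected.id,
            rejected=len(contigs) - len(kept),
        )
        return selected

    selected = run_round(1, params.k_list, (), ())
    if selected is None and reads:
        trusted = [c.seq for c in prior_top] + [ref.plus_seq]
        selected = run_round(2, thresholds.round2_k, trusted, ())
    if selected is None and reads:
        untrusted = [c.seq for c in prior_top]
        selected = run_round(3, thresholds.round3_k, [ref.plus_seq], untrusted)
    if selected is not None:
        log.selected_id = selected.id
    return selected, log
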