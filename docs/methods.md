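# Methods

## The problem

*RPGR* exon ORF15 is a ~1.7 kb stretch of highly repetitive, purine-rich,
low-complexity coding sequence (Glu/Gly codon runs) inside a ~2.1 kb
long-range PCR amplicon (hg19 chrX:38144633-38146732). Two properties make
it pathological for conventional NGS secondary analysis. First, the coding
(minus) strand is almost all A/G, so the plus strand carries under 7% G — an
extreme composition that also makes strand identity trivially detectable.
Second, the repeat structure means short reads map ambiguously: a read
carrying one extra repeat unit can be placed a unit off with few or no
mismatches, and mappers resolve the length difference inconsistently across
reads. Downstream allele-fraction callers then see split support and emit
heterozygous SNVs in hemizygous males — biologically impossible calls — while
genuinely present 15-51 bp duplications fall below calling thresholds.

The package's answer is to reconstruct each sample's entire amplicon de novo
and compare whole sequences: one contig against one reference, where a 27 bp
duplication is a single unambiguous gap run rather than a cloud of
misplaced reads.

## Assembly model

The assembler is an edge-centric de Bruijn graph: edges are k-mers, nodes
are (k−1)-mers. K-mers from both strands of every read are counted as-is
(no canonicalization); the graph is therefore strand-mirrored, and every
simplification removes a k-mer together with its reverse complement so the
mirror symmetry is an invariant. Reverse-complement twins are merged only at
contig emission. At amplicon scale this costs a factor of two in memory and
removes a whole class of orientation bugs; final orientation is decided
later by the G-content rule.

Edges below `min_kmer_count` (default 3) are pruned unless they occur in a
*trusted* contig; *untrusted* contigs contribute a pseudo-count of one and
remain subject to the prune. Assembly iterates k ascending (default
{21, 33, 55, 77, 99, 127}, all below the 151 bp read length; the selection
cascade uses {55, 77, 99, 127} in round 2 and {77, 99, 127} in round 3),
feeding each round's contigs to the next round as untrusted input. Small k
provides connectivity at low or uneven coverage; large k resolves the repeat
tract (an exact tandem of unit *u* and span *s* is linear in the graph once
k > s − u).

Graph cleaning has two moves, iterated to a fixed point:

- **Tip clipping.** A dead-end unitig shorter than `2k` bases is removed
  *only when a strictly higher-coverage branch enters (or leaves) the same
  junction*. The coverage condition matters: a genuine amplicon terminus is
  also a dead end, and when a sequencing-error bubble happens to open a
  junction within 2k bases of the amplicon end, an unconditional length rule
  would amputate the true terminal path (observed as contigs ~100 bp short
  before the rule was conditioned on domination).
- **Bubble popping.** Two unitigs sharing both endpoints whose sequences
  differ by at most `bubble_max_divergence` (default 3) edits — measured
  with edlib — collapse onto the higher-coverage branch, ties broken
  lexicographically. At 1000× depth with a 0.1% substitution error rate,
  recurrent error k-mers clear the count-3 prune at a few dozen positions
  per k; bubbles are how they die.

`mean_cov` of a contig is the mean count of its edges — the assembler's
native statistic — and is what the `> 30` coverage filter applies to, since
no other definition of contig coverage is available at selection time.

## Selection cascade

All bound comparisons are strict, exactly as configured: G-content < 0.15
per strand (else the reverse complement is tested, else reject), prefilter
400 < length < 2300 and mean coverage > 30, satisfactory window
2040 < length < 2300. The satisfactory lower bound is 2040 rather than the
round-number 2000 because selection should describe contigs that actually
span the amplicon minus primer slack; the bound is exposed in
`SelectionThresholds` for anyone who wants the looser value. Ranking is a
fixed lexicographic order — inside the satisfactory window first, then
higher coverage, then longer, then identifier — chosen to be a deterministic
total order rather than a tuned score. Round 2 passes at most five
top-ranked contigs plus the reference as trusted inputs; round 3 demotes
prior contigs to untrusted and trusts the reference alone, so a
read-unsupported chimera cannot be laundered into the final graph twice.

A second satisfactory contig with a different sequence is reported as a
candidate second allele (and the calls marked heterozygous); otherwise
zygosity is hemizygous for males and unknown for females. Single-contig
assembly cannot phase a truly diploid female sample — flagging, not
resolution, is the design.

## Alignment and calling

The contig is aligned to the reference by an affine-gap Gotoh DP (match +1,
mismatch −2, gap open −12, gap extend −0.5; a run of length L costs
`open + (L−1)·extend`). The open/extend asymmetry is deliberate: inside the
repeat tract it makes one contiguous 27-column gap vastly cheaper than any
mismatch-interleaved alternative, which is what keeps duplication calls
whole. Terminal gaps are free only on the contig side (contigs overhang the
reference when primer-proximal fragments are over-represented); terminal
reference gaps are charged, and terminal gap runs are excluded from variant
calling as unaligned overhang. The row-wise DP resolves the within-row gap
recursion with a running prefix maximum, which is valid because re-opening a
gap from a gap state can never beat extending (open ≤ extend); the
implementation refuses parameter sets violating that.

Non-match column runs become calls: gap-free runs as per-column SNVs (the
dialect of column-based SNP callers — adjacent SNVs are not merged into
MNVs), runs containing any gap as a single del/ins/delins event. Each indel
is then rendered twice from the same internal variant: 3′-shifted on the
transcript sense for HGVS (with an insertion equal to its immediately 5′
reference segment re-expressed as a duplication, never when the insertion
exceeds the available 5′ context), and left-aligned with a VCF anchor base
on the genomic plus strand. Normalization shifts are capped at neighbouring
variants so a shifted call cannot collide with another call, and the
finalized set must reproduce the de-gapped contig exactly — a hard runtime
invariant, not a test-only property.

Consequences come from direct translation: coding indels with net length
≢ 0 (mod 3) are frameshifts, with p-notation derived by translating the
edited transcript from the first affected codon to the first stop (reading
through into 3′ UTR sequence; if no stop is reached the `Ter` offset is
omitted); stop-gain SNVs are nonsense; the prioritized set is exactly
{frameshift, nonsense}, reflecting the mutational spectrum of the locus.
Variants spanning a segment boundary are conservatively labelled frameshift
with a warning flag. Frequency annotation joins on the exact left-aligned
(chrom, pos, ref, alt) key — never the HGVS rendering, which inside repeats
disagrees with the left-aligned key by construction.

## The baseline and concordance

The comparison pipeline is a minimal seed-and-extend mapper plus
allele-fraction caller: each read anchors at the *leftmost* reference
occurrence of its first seedable 31-mer and is extended end-to-end by
unit-cost banded alignment (edlib); at positions with depth ≥ 20, alternate
alleles with fraction ≥ 0.8 become hom/hemi calls and [0.2, 0.8)
heterozygous calls. The leftmost-seed heuristic and unit costs are the
point, not a shortcut: they reproduce the class of repeat-tract artifacts
(split support, spurious heterozygous SNVs in males, missed ≥ 20 bp
duplications) that motivate the assembly approach. The baseline makes no
attempt to match any production mapper's exact false-positive inventory.

Cross-pipeline identity uses the left-aligned VCF key, so differently named
but sequence-identical edits match. A variant's call quality is *high* only
when its per-sample presence is identical in both pipelines across the
cohort; any discordance is *low*. Heterozygous calls in male samples carry
an explicit artifact flag.

## Synthetic data: what it does and does not emulate

The generator builds the coding strand from a weighted purine-only codon
pool (GAA/GAG/GGA/AGG/AAG; no C keeps plus-strand G near zero, no GGG avoids
G homopolymers), embeds one exact tandem block (default 27 bp × 3) mid-core,
adds 60 bp balanced-composition flanks as primer sites, and stores the
reverse complement as the plus strand — giving ~2.1 kb references with
~1.5-2% plus-strand G. Reads are 2×151 bp inward-facing pairs from
normal(273, 40) fragments (clamped to ≥ 151), starts uniform with a
multiplicative weight (default 3) on fragments overlapping a primer span,
rejection-sampled so the pair count stays at `coverage·L/302`. Errors are
uniform substitutions (default 0.001/base); a 1 bp indel-error channel
exists but defaults to off so that indel calls are attributable to spiked
variants rather than the error model. Qualities are constant Q30 — nothing
downstream reads them.

Not emulated: platform-specific error profiles, PCR stutter and chimeras,
coverage bias beyond the primer weight, amplification failure, and real
primer-terminus pile-up. On that last point, the fragment model bounds what
primer "over-representation" can mean: a position inside a 25 bp terminal
primer span is reachable only by fragments starting within those 25 slots,
so its absolute depth stays well below the interior plateau at any modest
weight; the property tested (and the honest claim) is *relative* enrichment
— primer-span depth at weight 3 is ≥ 1.5× the depth at weight 1 — alongside
interior depth within 10% of nominal and the analytic pair count. Passing
tests on this generator therefore demonstrate correct handling of repeat
structure, depth, and read geometry, not robustness to real instrument
noise.

Truth sets are derived from reference content (pattern searches and the
recorded tandem-block coordinates), one per class: SNV, 2 bp GG-deletion
(transcript sense), 4 bp deletion, 2 bp delins, 15/21/27 bp duplications
inside the tandem block, a 51 bp Glu/Gly-codon insertion, and an empty set.

## Validation problem sizes

The test suite and `scripts/acceptance.py` use: 100 random 300-600 bp
references for the assembler oracle; 500 random pairs of length ≤ 12 for
the exhaustive alignment oracle (≈ C(24,12) ≈ 2.7 M alignments at the worst
size, enumerated directly); 1000 randomized repeat-tract indels for the
normalization oracle; 20 seeds per variant class at 1000× coverage and
0.1% error for end-to-end recovery (pass bound 19/20 per class); and 10
seeds for the baseline failure-mode reproduction. One full acceptance run
is dominated by the 160 recovery assemblies (~2 s each).

## Known limitations

- Diploid female samples are flagged, not phased; a single selected contig
  represents one allele.
- The assembler has no paired-end scaffolding or read-threading repeat
  resolution; tandem repeats with span − unit ≥ 127 bp are out of reach at
  the default k ladder (the real tract's informative units are shorter).
- HGVS support covers the emitted dialect (SNV/del/ins/dup/delins, intronic
  `c.A-K`, UTR `c.*N`) — not inversions, alleles, or mosaicism.
- The frequency join is exact-key; a database that normalizes differently
  (e.g. not left-aligned) will silently miss.
- Baseline concordance counts depend on the synthetic cohort composition
  and are not comparable to any published cohort's tallies.
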