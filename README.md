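# orf15asm

De novo assembly-based variant calling for the *RPGR* ORF15 long-range PCR
amplicon — the purine-rich, low-complexity terminal exon that is a mutation
hotspot for X-linked retinitis pigmentosa and a notorious failure zone for
standard map-then-call NGS analysis.

## Who this is for

Groups running targeted deep sequencing of ORF15 (or a similarly
low-complexity amplicon) who need indel calls they can trust. Conventional
secondary analysis (BWA-MEM-style mapping followed by allele-fraction or
haplotype calling) systematically miscalls this region: it reports
impossible "heterozygous" SNVs in hemizygous males and misses indels of
≥ 15-20 bp inside the repeat tract. Reconstructing each sample's amplicon by
de novo assembly and then comparing whole contigs against the reference
sidesteps both failure modes.

## What it does

For each sample (paired-end FASTQ from one ~2.1 kb amplicon,
hg19 chrX:38144633-38146732):

1. **Assembly** — iterative de Bruijn graph assembly over ascending odd k
   (default k ∈ {21, 33, 55, 77, 99, 127}), counting k-mers from both read
   strands, pruning edges below a count threshold, clipping dominated tips
   and popping small bubbles. Contigs from each k seed the next round.
2. **Selection** — contigs are oriented by G-content (the amplicon plus
   strand carries < 7% G, so a contig failing the 15% bound is re-tested as
   its reverse complement), pre-filtered on size (> 400 and < 2300 bp) and
   mean k-mer coverage (> 30), and ranked. A contig is *satisfactory* when
   its length is > 2040 and < 2300 bp. If round 1 fails, round 2 reruns
   assembly with the top contigs plus the reference as *trusted* inputs
   (exempt from the coverage prune); round 3 uses k = {77, 99, 127} with the
   prior top contigs as untrusted and the reference alone trusted.
3. **Calling** — the selected contig is globally aligned to the reference
   (affine gaps: match +1, mismatch −2, open −12, extend −0.5, free contig
   end-gaps). Runs of non-match columns become calls: gap-free runs yield
   per-column SNVs; runs containing a gap yield one del/ins/delins event.
   Indels are 3′-shifted on the transcript sense for HGVS c. output
   (duplication-aware: an insertion equal to the segment immediately 5′ of
   it is re-expressed as `dup`) and left-aligned with an anchor base for
   VCF 4.2 output. Frameshift/nonsense consequences are derived by
   translation; only those classes enter the prioritized set; calls are
   annotated against a local population-frequency TSV by exact left-aligned
   key.
4. **Baseline + concordance** — a deliberately naive seed-and-extend pileup
   caller reproduces the conventional pipeline's behaviour, and a
   per-variant concordance table assigns each variant a *high* call quality
   only when its per-sample presence is identical in both pipelines.

Patient reads for this locus cannot be shared, so the package ships a
synthetic-data generator (`orf15asm.simulate`) producing ORF15-like
references (Glu/Gly codon core, embedded exact tandem repeat, < 7% plus-
strand G), 2×151 bp paired reads at configurable depth with primer-site
over-representation, and a catalogue of truth variant sets (SNV, 2/4-bp
deletions, 2-bp delins, 15/21/27-bp duplications, 51-bp insertion).

## Worked example

```sh
orf15asm simulate --out-dir demo --seed 3 --coverage 400 --classes del2,no_variant
orf15asm run --sample-id del2 --sex male \
    --r1 demo/del2_R1.fastq.gz --r2 demo/del2_R2.fastq.gz \
    --reference demo/reference.fasta --reference-config demo/reference.yaml \
    --out-dir demo/out
```

prints

```
del2: contig NODE_1_length_2096_cov_62.83, 1 calls, 1 prioritized
```

meaning assembly round 1 produced a satisfactory 2096 bp contig at mean
k-mer coverage 62.8, and exactly one variant was called and prioritized. The
VCF in `demo/out/del2.vcf` contains the spiked 2-bp deletion, left-aligned
and anchored:

```
chrX  38144733  .  TCC  T  .  PASS  HGVSC=c.3690_3691del;CSQ=frameshift  GT  1
```

`c.3690_3691del` is the same edit 3′-shifted on the transcript sense — the
two renderings disagree on position by design, exactly as the HGVS and VCF
standards do inside repeats. `orf15asm cohort` runs both pipelines over a
sample manifest and writes the per-variant concordance table with high/low
call quality.

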