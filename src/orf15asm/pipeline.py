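"""End-to-end orchestration: per-sample runs, cohorts, reports.

``run_sample`` executes the assembly-based chain (assembly rounds → contig
selection → alignment → calling → normalization → consequence →
prioritization → frequency annotation → VCF), and ``run_cohort`` adds the
naive baseline caller per sample plus the cross-pipeline concordance table.
Everything is deterministic given the config; per-sample failures inside a
cohort are isolated into failure reports rather than aborting the run.
"""

from __future__ import annotations

import logging
import traceback
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from . import io as oio
from .align import AlignParams, global_align
from .assemble import AssemblyParams, Contig
from .baseline import (
    BaselineParams,
    build_pileup,
    concordance_table,
    CONCORDANCE_HEADER,
    flag_het_in_haploid,
    pileup_call,
)
from .calls import (
    VariantCall,
    annotate_frequency,
    attach_consequences,
    calls_from_alignment,
    finalize_calls,
    prioritize,
    read_frequency_table,
    write_vcf,
)
from .reference import AmpliconReference, CoordinateMap
from .select import RoundLog, SelectionThresholds, run_assembly_rounds
from .simulate import SimulationConfig

logger = logging.getLogger("orf15asm")


@dataclass
class PipelineConfig:
    thresholds: SelectionThresholds = field(default_factory=SelectionThresholds)
    assembly: AssemblyParams = field(default_factory=AssemblyParams)
    align: AlignParams = field(default_factory=AlignParams)
    baseline: BaselineParams = field(default_factory=BaselineParams)
    simulate: SimulationConfig = field(default_factory=SimulationConfig)
    frequency_table: Optional[str] = None
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        def build(klass, key):
            sub = d.get(key, {})
            if not isinstance(sub, dict):
                raise ValueError(f"config section {key!r} must be a mapping")
            kw = dict(sub)
            for name in ("k_list", "round2_k", "round3_k", "prefilter_size", "satisfactory_size",
                         "trusted_contigs", "untrusted_contigs"):
                if name in kw and kw[name] is not None:
                    kw[name] = tuple(kw[name])
            return klass(**kw)

        return cls(
            thresholds=build(SelectionThresholds, "thresholds"),
            assembly=build(AssemblyParams, "assembly"),
            align=build(AlignParams, "align"),
            baseline=build(BaselineParams, "baseline"),
            simulate=build(SimulationConfig, "simulate"),
            frequency_table=d.get("frequency_table"),
            seed=int(d.get("seed", 0)),
        )

    def to_dict(self) -> dict:
        from dataclasses import asdict

        return {
            "thresholds": asdict(self.thresholds),
            "assembly": asdict(self.assembly),
            "align": asdict(self.align),
            "baseline": asdict(self.baseline),
            "simulate": asdict(self.simulate),
            "frequency_table": self.frequency_table,
            "seed": self.seed,
        }


@dataclass(frozen=True)
class ManifestEntry:
    sample_id: str
    sex: str  # male | female | unknown
    r1: str
    r2: str

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female", "unknown"):
            raise ValueError(f"sex must be male/female/unknown, got {self.sex!r}")


@dataclass
class SampleManifest:
    entries: tuple[ManifestEntry, ...]

    def __init__(self, entries: Sequence[ManifestEntry]):
        ids = [e.sample_id for e in entries]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate sample ids in manifest: {dup}")
        paths = [p for e in entries for p in (e.r1, e.r2)]
        if len(set(paths)) != len(paths):
            raise ValueError("manifest FASTQ paths must be distinct")
        object.__setattr__(self, "entries", tuple(entries))

    def __iter__(self):
        return iter(self.entries)

    def __len__(self):
        return len(self.entries)

    @classmethod
    def from_tsv(cls, path) -> "SampleManifest":
        entries = []
        for line_no, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ValueError(f"{path}:{line_no}: expected 4 tab-separated fields")
            entries.append(ManifestEntry(*parts))
        return cls(entries)


@dataclass
class SampleReport:
    sample_id: str
    sex: str
    round_log: RoundLog
    contig: Optional[Contig]
    raw_calls: list = field(default_factory=list)
    finalized_calls: list = field(default_factory=list)
    prioritized_calls: list = field(default_factory=list)
    candidate_second_allele: Optional[str] = None
    failure: Optional[str] = None

    @property
    def resolved(self) -> bool:
        return self.contig is not None and self.failure is None

    def to_dict(self) -> dict:
        def call_dict(c: VariantCall) -> dict:
            d = oio.variant_to_dict(c.variant)
            d.update(
                caller=c.caller,
                zygosity=c.zygosity,
                support=c.support,
                hgvs_c=c.hgvs_c,
                vcf=list(c.vcf_fields) if c.vcf_fields else None,
                consequence=None if c.consequence is None else c.consequence.cls,
                p_notation=None if c.consequence is None else c.consequence.p_notation,
                frequency_percent=c.frequency_percent,
                rsid=c.rsid,
                flags=list(c.flags),
            )
            return d

        return {
            "sample_id": self.sample_id,
            "sex": self.sex,
            "resolved": self.resolved,
            "failure": self.failure,
            "round_log": self.round_log.to_dict(),
            "contig": None if self.contig is None else {
                "id": self.contig.id, "length": self.contig.length, "mean_cov": self.contig.mean_cov,
            },
            "candidate_second_allele": self.candidate_second_allele,
            "raw_calls": [call_dict(c) for c in self.raw_calls],
            "finalized_calls": [call_dict(c) for c in self.finalized_calls],
            "prioritized_calls": [call_dict(c) for c in self.prioritized_calls],
        }


def _zygosity_for(sex: str, n_passing_contigs: int) -> str:
    if n_passing_contigs >= 2:
        return "heterozygous"
    if sex == "male":
        return "hemizygous"
    return "unknown"


def call_contig(
    contig: Contig,
    ref: AmpliconReference,
    cmap: CoordinateMap,
    align_params: AlignParams = AlignParams(),
    zygosity: str = "unknown",
) -> tuple[list[VariantCall], list[VariantCall]]:
    """Align one selected contig and produce (raw, finalized) call lists."""
    aln = global_align(contig.seq, ref.plus_seq, align_params)
    raw = calls_from_alignment(aln, caller="assembly", support=contig.id, zygosity=zygosity)
    finalized = finalize_calls(raw, ref, cmap)
    return raw, finalized


def run_sample_reads(
    sample_id: str,
    sex: str,
    reads: Sequence[str],
    ref: AmpliconReference,
    cmap: CoordinateMap,
    config: PipelineConfig = PipelineConfig(),
    frequency_records=None,
) -> SampleReport:
    """The assembly pipeline on an in-memory read list."""
    contig, log = run_assembly_rounds(reads, ref, config.thresholds, config.assembly)
    if contig is None:
        return SampleReport(
            sample_id=sample_id, sex=sex, round_log=log, contig=None,
            failure="no satisfactory contig after three assembly rounds",
        )
    # a second passing contig, when present, flags a candidate second allele
    second = next((c for c in log.satisfactory[1:] if c.seq != contig.seq), None)
    zygosity = _zygosity_for(sex, 2 if second is not None else 1)
    raw, finalized = call_contig(contig, ref, cmap, config.align, zygosity)
    finalized = attach_consequences(finalized, cmap, ref)
    if frequency_records is not None:
        finalized = annotate_frequency(finalized, frequency_records, ref.locus[0])
    prioritized = prioritize(finalized)
    return SampleReport(
        sample_id=sample_id,
        sex=sex,
        round_log=log,
        contig=contig,
        raw_calls=raw,
        finalized_calls=finalized,
        prioritized_calls=prioritized,
        candidate_second_allele=None if second is None else second.id,
    )


def run_sample(
    entry: ManifestEntry,
    ref: AmpliconReference,
    cmap: CoordinateMap,
    config: PipelineConfig = PipelineConfig(),
    out_dir=None,
) -> SampleReport:
    """FASTQ pair in, report + VCF out."""
    r1 = oio.read_fastq(entry.r1)
    r2 = oio.read_fastq(entry.r2)
    reads = [seq for _, seq, _ in r1] + [seq for _, seq, _ in r2]
    freq = None
    if config.frequency_table:
        freq = read_frequency_table(config.frequency_table)
    report = run_sample_reads(entry.sample_id, entry.sex, reads, ref, cmap, config, freq)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        oio.write_yaml(report.to_dict(), out / f"{entry.sample_id}.report.yaml")
        if report.resolved:
            (out / f"{entry.sample_id}.vcf").write_text(
                write_vcf(report.finalized_calls, ref, entry.sample_id)
            )
    return report


def run_baseline_reads(
    reads: Sequence[tuple[str, str]],
    ref: AmpliconReference,
    sex: str,
    params: BaselineParams = BaselineParams(),
) -> list[VariantCall]:
    pile, placed, total = build_pileup(ref, reads, params)
    logger.debug("baseline placed %d/%d reads", placed, total)
    calls = pileup_call(pile, ref, params, sample_sex=sex)
    return flag_het_in_haploid(calls, sex)


@dataclass
class CohortResult:
    reports: dict
    baseline_calls: dict
    concordance: list
    summary: dict


def run_cohort(
    manifest: SampleManifest,
    ref: AmpliconReference,
    cmap: CoordinateMap,
    config: PipelineConfig = PipelineConfig(),
    out_dir=None,
) -> CohortResult:
    """Both pipelines on every sample, plus the concordance table.

    Per-sample exceptions become failure reports; the cohort continues.
    """
    reports: dict = {}
    baseline_by_sample: dict = {}
    novel_by_sample: dict = {}
    sexes = {e.sample_id: e.sex for e in manifest}
    for entry in manifest:
        try:
            report = run_sample(entry, ref, cmap, config, out_dir=out_dir)
            r1 = oio.read_fastq(entry.r1)
            r2 = oio.read_fastq(entry.r2)
            read_pairs = [(n, s) for n, s, _ in r1] + [(n, s) for n, s, _ in r2]
            baseline = run_baseline_reads(read_pairs, ref, entry.sex, config.baseline)
        except Exception as exc:  # isolate per-sample failures
            logger.error("sample %s failed: %s", entry.sample_id, exc)
            logger.debug("%s", traceback.format_exc())
            reports[entry.sample_id] = SampleReport(
                sample_id=entry.sample_id, sex=entry.sex, round_log=RoundLog(),
                contig=None, failure=str(exc),
            )
            continue
        reports[entry.sample_id] = report
        baseline_by_sample[entry.sample_id] = baseline
        novel_by_sample[entry.sample_id] = report.finalized_calls
    rows = concordance_table(baseline_by_sample, novel_by_sample, sexes)
    summary = {
        "samples": len(manifest),
        "resolved": sum(1 for r in reports.values() if r.resolved),
        "unresolved": sum(1 for r in reports.values() if not r.resolved),
        "samples_with_prioritized": sum(
            1 for r in reports.values() if r.prioritized_calls
        ),
        "unique_variants_novel": len(
            {c.vcf_fields for r in reports.values() for c in r.finalized_calls if c.vcf_fields}
        ),
        "unique_variants_baseline": len(
            {c.vcf_fields for calls in baseline_by_sample.values() for c in calls if c.vcf_fields}
        ),
        "high_quality_variants": sum(1 for row in rows if row.quality == "high"),
        "low_quality_variants": sum(1 for row in rows if row.quality == "low"),
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "concordance.tsv").write_text(
            "\n".join([CONCORDANCE_HEADER] + [r.to_tsv_row() for r in rows]) + "\n"
        )
        oio.write_yaml(summary, out / "cohort_summary.yaml")
        oio.write_yaml(config.to_dict(), out / "resolved_config.yaml")
    return CohortResult(
        reports=reports,
        baseline_calls=baseline_by_sample,
        concordance=rows,
        summary=summary,
    )
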