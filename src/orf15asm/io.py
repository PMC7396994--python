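"""File I/O: FASTA/FASTQ, locus config, truth records, reports."""

from __future__ import annotations

import gzip
import json
from pathlib import Path
from typing import Optional, Sequence

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .assemble import Contig, parse_contig_id
from .reference import AmpliconReference, CoordinateMap, Segment, Variant, VariantSet


def read_reference_fasta(path, locus_config: dict) -> AmpliconReference:
    """Load a single-record amplicon FASTA plus its locus/primer config."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise ValueError(f"expected exactly one FASTA record in {path}, found {len(records)}")
    rec = records[0]
    loc = locus_config["locus"]
    tb = locus_config.get("tandem_block")
    return AmpliconReference(
        name=rec.id,
        plus_seq=str(rec.seq).upper(),
        locus=(loc["chrom"], int(loc["start"]), int(loc["end"])),
        primer_fwd=tuple(locus_config["primer_fwd"]),
        primer_rev=tuple(locus_config["primer_rev"]),
        coding_strand=locus_config.get("coding_strand", "minus"),
        tandem_block=tuple(tb) if tb else None,
    )


def write_reference_fasta(ref: AmpliconReference, path) -> None:
    SeqIO.write([SeqRecord(Seq(ref.plus_seq), id=ref.name, description="")], str(path), "fasta")


def coordinate_map_from_config(cfg: dict) -> CoordinateMap:
    return CoordinateMap(
        transcript_id=cfg["transcript_id"],
        orientation=cfg["orientation"],
        segments=tuple(
            Segment(int(s["start"]), int(s["end"]), s["kind"], int(s["c_anchor"]))
            for s in cfg["segments"]
        ),
    )


def coordinate_map_to_config(cmap: CoordinateMap) -> dict:
    return {
        "transcript_id": cmap.transcript_id,
        "orientation": cmap.orientation,
        "segments": [
            {"start": s.start, "end": s.end, "kind": s.kind, "c_anchor": s.c_anchor}
            for s in cmap.segments
        ],
    }


def reference_config(ref: AmpliconReference, cmap: Optional[CoordinateMap] = None) -> dict:
    chrom, start, end = ref.locus
    cfg = {
        "locus": {"chrom": chrom, "start": start, "end": end},
        "primer_fwd": list(ref.primer_fwd),
        "primer_rev": list(ref.primer_rev),
        "coding_strand": ref.coding_strand,
        "tandem_block": list(ref.tandem_block) if ref.tandem_block else None,
    }
    if cmap is not None:
        cfg["coordinate_map"] = coordinate_map_to_config(cmap)
    return cfg


def _open_maybe_gz(path, mode: str):
    path = str(path)
    if path.endswith(".gz"):
        if "w" in mode:
            # fixed mtime and no filename header: identical content gives
            # byte-identical files
            import io as _io

            gz = gzip.GzipFile(filename="", mode="wb", fileobj=open(path, "wb"), mtime=0)
            return _io.TextIOWrapper(gz, encoding="ascii")
        return gzip.open(path, mode + "t")
    return open(path, mode)


def write_fastq(records: Sequence[tuple[str, str, str]], path) -> None:
    """Write 4-line FASTQ records; ``.gz`` paths are gzipped with a fixed
    mtime so identical inputs give byte-identical files."""
    with _open_maybe_gz(path, "w") as fh:
        for name, seq, qual in records:
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")


def read_fastq(path) -> list[tuple[str, str, str]]:
    """Read (name, seq, qual) triples; raises with file/line context on
    truncated records."""
    out = []
    with _open_maybe_gz(path, "r") as fh:
        lines = fh.read().splitlines()
    if len(lines) % 4:
        raise ValueError(f"{path}: truncated FASTQ (line {len(lines)} ends mid-record)")
    for i in range(0, len(lines), 4):
        header, seq, plus, qual = lines[i : i + 4]
        if not header.startswith("@") or not plus.startswith("+"):
            raise ValueError(f"{path}: malformed record at line {i + 1}")
        if len(seq) != len(qual):
            raise ValueError(f"{path}: length mismatch at line {i + 1}")
        out.append((header[1:], seq.upper(), qual))
    return out


def write_contigs_fasta(contigs: Sequence[Contig], path) -> None:
    SeqIO.write(
        [SeqRecord(Seq(c.seq), id=c.id, description="") for c in contigs], str(path), "fasta"
    )


def read_contigs_fasta(path) -> list[Contig]:
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        _, length, cov = parse_contig_id(rec.id)
        out.append(Contig(id=rec.id, seq=str(rec.seq).upper(), mean_cov=cov))
    return out


def variant_to_dict(v: Variant) -> dict:
    return {
        "start": v.start,
        "end": v.end,
        "ref": v.ref,
        "alt": v.alt,
        "kind": v.kind,
        "zygosity": v.zygosity,
    }


def variant_from_dict(d: dict) -> Variant:
    return Variant(
        start=int(d["start"]),
        end=int(d["end"]),
        ref=d["ref"],
        alt=d["alt"],
        zygosity=d.get("zygosity", "unknown"),
    )


def write_truth(truth: Sequence[VariantSet], hgvs: Sequence[list], path) -> None:
    payload = {
        "alleles": [
            {"variants": [variant_to_dict(v) for v in vs], "hgvs_c": list(h)}
            for vs, h in zip(truth, hgvs)
        ]
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def read_truth(path) -> list[VariantSet]:
    payload = yaml.safe_load(Path(path).read_text())
    return [
        VariantSet([variant_from_dict(d) for d in allele["variants"]])
        for allele in payload["alleles"]
    ]


def write_yaml(data: dict, path) -> None:
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def write_json(data: dict, path) -> None:
    Path(path).write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")
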