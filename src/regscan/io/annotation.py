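"""Gene annotation readers: GFF3 and BED12, normalised to one gene model.

Both dialects resolve to the same internal :class:`GeneModel` in 0-based
half-open coordinates; GFF3's 1-based closed convention is shifted on read.
The TSS is derived from the transcript span and strand (first transcribed
base), as in RefSeq-style annotations that carry no explicit TSS field.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import IO

from ..errors import FormatError, ValidationError
from ..intervals import GenomeInterval, merge


@dataclass
class GeneModel:
    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    span: GenomeInterval
    exons: list[GenomeInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValidationError(
                f"transcript {self.transcript_id}: strand must be + or -")
        for ex in self.exons:
            if ex.start < self.span.start or ex.end > self.span.end:
                raise ValidationError(
                    f"transcript {self.transcript_id}: exon {ex} outside span "
                    f"{self.span}")
        self.exons = sorted(self.exons, key=lambda e: e.start)

    @property
    def tss(self) -> int:
        """First transcribed base: span start on +, span end - 1 on -."""
        return self.span.start if self.strand == "+" else self.span.end - 1


def _parse_gff3_attrs(text: str) -> dict[str, str]:
    out = {}
    for part in text.strip().rstrip(";").split(";"):
        if not part:
            continue
        k, _, v = part.partition("=")
        out[k.strip()] = v.strip()
    return out


def _read_gff3(stream: IO[str]) -> list[GeneModel]:
    transcripts: dict[str, dict] = {}
    exon_lines: list[tuple[int, str, int, int]] = []
    for ln, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 9:
            raise FormatError(f"expected 9 GFF3 columns, got {len(cols)}", ln)
        chrom, _src, ftype, start, end, _score, strand, _frame, attrs = cols
        try:
            start_i, end_i = int(start), int(end)
        except ValueError:
            raise FormatError(f"non-integer coordinates {start!r}/{end!r}", ln)
        a = _parse_gff3_attrs(attrs)
        if ftype in ("mRNA", "transcript"):
            tid = a.get("ID")
            if not tid:
                raise FormatError("transcript feature lacks ID attribute", ln)
            transcripts[tid] = dict(
                gene_id=a.get("Parent", tid), chrom=chrom, strand=strand,
                start=start_i - 1, end=end_i, exons=[], line=ln)
        elif ftype == "exon":
            parent = a.get("Parent")
            if not parent:
                raise FormatError("exon feature lacks Parent attribute", ln)
            exon_lines.append((ln, parent, start_i - 1, end_i))
    models: list[GeneModel] = []
    for ln, parent, s, e in exon_lines:
        if parent not in transcripts:
            raise FormatError(f"exon Parent {parent!r} unknown", ln)
        t = transcripts[parent]
        if s < t["start"] or e > t["end"]:
            raise FormatError(
                f"exon {s + 1}-{e} outside transcript span of {parent}", ln)
        t["exons"].append(GenomeInterval(t["chrom"], s, e))
    for tid, t in transcripts.items():
        models.append(GeneModel(
            gene_id=t["gene_id"], transcript_id=tid, chrom=t["chrom"],
            strand=t["strand"],
            span=GenomeInterval(t["chrom"], t["start"], t["end"],
                                strand=t["strand"], name=tid),
            exons=t["exons"]))
    return models


def _read_bed12(stream: IO[str]) -> list[GeneModel]:
    models: list[GeneModel] = []
    for ln, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith(("#", "track", "browser")):
            continue
        cols = line.split("\t")
        if len(cols) < 12:
            raise FormatError(f"expected 12 BED12 columns, got {len(cols)}", ln)
        chrom, start, end, name, _score, strand = cols[:6]
        start_i, end_i = int(start), int(end)
        block_count = int(cols[9])
        sizes = [int(x) for x in cols[10].rstrip(",").split(",")]
        offsets = [int(x) for x in cols[11].rstrip(",").split(",")]
        if len(sizes) != block_count or len(offsets) != block_count:
            raise FormatError("block count does not match block lists", ln)
        # name carries "gene_id:transcript_id", or one id doubling as both
        gene_id, _, transcript_id = name.partition(":")
        transcript_id = transcript_id or gene_id
        exons = []
        for sz, off in zip(sizes, offsets):
            es, ee = start_i + off, start_i + off + sz
            if ee > end_i:
                raise FormatError(f"block {es}-{ee} outside transcript span", ln)
            exons.append(GenomeInterval(chrom, es, ee))
        models.append(GeneModel(
            gene_id=gene_id, transcript_id=transcript_id, chrom=chrom,
            strand=strand,
            span=GenomeInterval(chrom, start_i, end_i, strand=strand,
                                name=transcript_id),
            exons=exons))
    return models


def read_gene_annotation(stream: IO[str], dialect: str = "GFF3") -> list[GeneModel]:
    """Read gene models from ``GFF3`` or ``BED12``."""
    if dialect == "GFF3":
        return _read_gff3(stream)
    if dialect == "BED12":
        return _read_bed12(stream)
    raise ValidationError(f"unknown annotation dialect {dialect!r}")


def write_gff3(models: list[GeneModel], stream: IO[str]) -> None:
    stream.write("##gff-version 3\n")
    for m in models:
        stream.write("\t".join([
            m.chrom, "regscan", "mRNA", str(m.span.start + 1), str(m.span.end),
            ".", m.strand, ".",
            f"ID={m.transcript_id};Parent={m.gene_id}"]) + "\n")
        for ex in m.exons:
            stream.write("\t".join([
                m.chrom, "regscan", "exon", str(ex.start + 1), str(ex.end),
                ".", m.strand, ".", f"Parent={m.transcript_id}"]) + "\n")


def all_exons(models: list[GeneModel]) -> list[GenomeInterval]:
    """Merged union of every exon of every transcript (the scan mask)."""
    out: list[GenomeInterval] = []
    for m in models:
        out.extend(m.exons)
    return merge(out)
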