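"""Plain BED reading/writing for peaks, reference regions and calls."""

from __future__ import annotations

from typing import IO, Iterable

from ..errors import FormatError
from ..intervals import GenomeInterval


def read_bed(stream: IO[str]) -> list[GenomeInterval]:
    """Read BED3/BED6 intervals (name/score/strand optional)."""
    out: list[GenomeInterval] = []
    for ln, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith(("#", "track", "browser")):
            continue
        cols = line.split("\t")
        if len(cols) < 3:
            raise FormatError(f"expected >= 3 BED columns, got {len(cols)}", ln)
        try:
            start, end = int(cols[1]), int(cols[2])
        except ValueError:
            raise FormatError(f"non-integer BED coordinates {cols[1]!r}/{cols[2]!r}", ln)
        name = cols[3] if len(cols) > 3 and cols[3] != "." else None
        strand = cols[5] if len(cols) > 5 and cols[5] in "+-" else "."
        try:
            out.append(GenomeInterval(cols[0], start, end, strand=strand, name=name))
        except Exception as e:
            raise FormatError(str(e), ln) from None
    return out


def write_bed(intervals: Iterable[GenomeInterval], stream: IO[str],
              scores: Iterable[float] | None = None) -> None:
    scores = list(scores) if scores is not None else None
    for i, iv in enumerate(intervals):
        score = f"{scores[i]:g}" if scores is not None else "0"
        stream.write("\t".join([
            iv.chrom, str(iv.start), str(iv.end), iv.name or ".",
            score, iv.strand if iv.strand != "." else "."]) + "\n")
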