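"""Genomic coordinates and exact interval-set algebra.

All coordinates in this package are 0-based half-open; conversion to the
1-based closed conventions of GFF and genome browsers happens only at I/O
boundaries.  The set operations are sort-sweep implementations working at
base-pair resolution; they are the common substrate of exon masking,
histone-mark intersection and reference-region merging.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping

from .errors import ValidationError

#: strand symbols accepted on a GenomeInterval
STRANDS = ("+", "-", ".")


@dataclass(frozen=True)
class GenomeInterval:
    """Half-open genomic span ``[start, end)`` on a named chromosome.

    ``name`` is free provenance (a peak id, a matrix id, a parent region);
    set operations that fragment an interval propagate it unchanged.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"malformed interval {self.chrom}:{self.start}-{self.end} "
                f"(need 0 <= start < end)"
            )
        if self.strand not in STRANDS:
            raise ValidationError(f"bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomeInterval") -> bool:
        return (self.chrom == other.chrom
                and self.start < other.end and other.start < self.end)

    def __str__(self) -> str:  # browser-style, 1-based closed
        return f"{self.chrom}:{self.start + 1}-{self.end}"


class ChromSizes(dict):
    """Mapping chromosome name -> length in bases."""

    def __init__(self, sizes: Mapping[str, int] = ()):
        super().__init__()
        for name, length in dict(sizes).items():
            if length <= 0:
                raise ValidationError(f"chromosome {name} has length {length}")
            self[name] = int(length)

    def validate(self, iv: GenomeInterval) -> None:
        if iv.chrom in self and iv.end > self[iv.chrom]:
            raise ValidationError(
                f"interval {iv} exceeds {iv.chrom} length {self[iv.chrom]}"
            )


def _by_chrom(intervals: Iterable[GenomeInterval]) -> dict[str, list[GenomeInterval]]:
    out: dict[str, list[GenomeInterval]] = {}
    for iv in intervals:
        out.setdefault(iv.chrom, []).append(iv)
    for ivs in out.values():
        ivs.sort(key=lambda i: (i.start, i.end))
    return out


def sort_intervals(intervals: Iterable[GenomeInterval]) -> list[GenomeInterval]:
    return sorted(intervals, key=lambda i: (i.chrom, i.start, i.end))


def merge(intervals: Iterable[GenomeInterval],
          join_touching: bool = True) -> list[GenomeInterval]:
    """Merge overlapping intervals per chromosome.

    With ``join_touching`` (the default) intervals that merely abut
    (``end == start``) are also joined, so "coincident" regions sharing a
    boundary collapse to one region.  Strand and name are dropped on merge.
    """
    out: list[GenomeInterval] = []
    grouped = _by_chrom(intervals)
    for chrom in sorted(grouped):
        cur_start = cur_end = None
        for iv in grouped[chrom]:
            if cur_start is None:
                cur_start, cur_end = iv.start, iv.end
                continue
            joins = iv.start <= cur_end if join_touching else iv.start < cur_end
            if joins:
                cur_end = max(cur_end, iv.end)
            else:
                out.append(GenomeInterval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        if cur_start is not None:
            out.append(GenomeInterval(chrom, cur_start, cur_end))
    return out


def intersect(a: Iterable[GenomeInterval],
              b: Iterable[GenomeInterval]) -> list[GenomeInterval]:
    """Base-level intersection of two interval sets (merged, sorted)."""
    am, bm = merge(a), merge(b)
    a_by, b_by = _by_chrom(am), _by_chrom(bm)
    out: list[GenomeInterval] = []
    for chrom in sorted(set(a_by) & set(b_by)):
        xs, ys = a_by[chrom], b_by[chrom]
        i = j = 0
        while i < len(xs) and j < len(ys):
            lo = max(xs[i].start, ys[j].start)
            hi = min(xs[i].end, ys[j].end)
            if lo < hi:
                out.append(GenomeInterval(chrom, lo, hi))
            if xs[i].end <= ys[j].end:
                i += 1
            else:
                j += 1
    return out


def subtract(a: Iterable[GenomeInterval],
             b: Iterable[GenomeInterval]) -> list[GenomeInterval]:
    """Base-level ``a minus b``.

    Unlike :func:`merge`/:func:`intersect` the minuend intervals are *not*
    merged first: each input interval of ``a`` is cut independently and its
    fragments keep its strand and name, so labels survive exon masking.
    """
    b_by = _by_chrom(merge(b))
    out: list[GenomeInterval] = []
    for iv in sort_intervals(a):
        cuts = b_by.get(iv.chrom, ())
        pos = iv.start
        for cut in cuts:
            if cut.end <= pos:
                continue
            if cut.start >= iv.end:
                break
            if cut.start > pos:
                out.append(replace(iv, start=pos, end=cut.start))
            pos = max(pos, cut.end)
            if pos >= iv.end:
                break
        if pos < iv.end:
            out.append(replace(iv, start=pos, end=iv.end))
    return sort_intervals(out)


def overlaps_any(query: GenomeInterval,
                 reference: Iterable[GenomeInterval]) -> bool:
    """True iff ``query`` shares at least one base with any reference interval."""
    return any(query.overlaps(r) for r in reference)


def complement_gaps(spans: Iterable[GenomeInterval], sizes: ChromSizes,
                    min_len: int) -> list[GenomeInterval]:
    """Maximal intervals free of ``spans``, at least ``min_len`` bases long.

    Chromosome ends count as gap boundaries, so a chromosome with no
    annotation yields one full-length gap.  This is how gene-free regions
    are found from a transcript annotation.
    """
    if min_len < 1:
        raise ValidationError(f"min_len must be >= 1, got {min_len}")
    merged = merge(spans)
    for iv in merged:
        sizes.validate(iv)
        if iv.chrom not in sizes:
            raise ValidationError(f"span on unknown chromosome {iv.chrom}")
    by = _by_chrom(merged)
    out: list[GenomeInterval] = []
    for chrom in sorted(sizes):
        pos = 0
        for iv in by.get(chrom, ()):
            if iv.start - pos >= min_len:
                out.append(GenomeInterval(chrom, pos, iv.start))
            pos = iv.end
        if sizes[chrom] - pos >= min_len:
            out.append(GenomeInterval(chrom, pos, sizes[chrom]))
    return out


def covered_bases(intervals: Iterable[GenomeInterval]) -> int:
    """Number of distinct bases covered by an interval set."""
    return sum(len(iv) for iv in merge(intervals))
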