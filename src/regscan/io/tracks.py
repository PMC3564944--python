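"""Per-base conservation score tracks (bedGraph and fixedStep WIG).

Scores emulate phastCons posteriors: values in [0, 1] per covered base.
Uncovered bases are stored as NaN at this level; whether missing means
"score zero" or "ignore" is a policy of the conservation module, not of
storage.
"""

from __future__ import annotations

from typing import IO

import numpy as np

from ..errors import FormatError, ValidationError
from ..intervals import ChromSizes, GenomeInterval


class ConservationTrack:
    """Per-chromosome float arrays in [0, 1] with NaN as the missing marker."""

    def __init__(self, sizes: ChromSizes):
        self.sizes = sizes
        self.scores: dict[str, np.ndarray] = {
            c: np.full(n, np.nan) for c, n in sizes.items()}

    def set_scores(self, chrom: str, start: int, values: np.ndarray) -> None:
        arr = self.scores[chrom]
        end = start + len(values)
        if end > arr.size:
            raise ValidationError(
                f"scores {chrom}:{start}-{end} exceed chromosome size {arr.size}")
        if not np.isnan(arr[start:end]).all():
            raise FormatError(
                f"overlapping score definitions at {chrom}:{start}-{end}")
        arr[start:end] = values

    def values(self, region: GenomeInterval) -> np.ndarray:
        """Raw per-base scores over a region (NaN where missing)."""
        if region.chrom not in self.scores:
            return np.full(len(region), np.nan)
        arr = self.scores[region.chrom]
        if region.end > arr.size:
            raise ValidationError(f"region {region} exceeds track bounds")
        return arr[region.start:region.end]


def _check_value(v: float, ln: int) -> float:
    if not 0.0 <= v <= 1.0:
        raise FormatError(f"score {v} outside [0, 1]", ln)
    return v


def read_score_track(stream: IO[str], sizes: ChromSizes,
                     dialect: str = "bedGraph") -> ConservationTrack:
    """Read a score track; ``bedGraph`` (0-based half-open) or
    ``fixedStep_WIG`` (1-based declarations)."""
    track = ConservationTrack(sizes)
    if dialect == "bedGraph":
        for ln, raw in enumerate(stream, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split()
            if len(cols) != 4:
                raise FormatError(f"expected 4 bedGraph columns, got {len(cols)}", ln)
            chrom, start, end, value = cols
            s, e = int(start), int(end)
            v = _check_value(float(value), ln)
            if chrom not in sizes:
                raise FormatError(f"unknown chromosome {chrom!r}", ln)
            try:
                track.set_scores(chrom, s, np.full(e - s, v))
            except FormatError as err:
                raise FormatError(str(err), ln) from None
    elif dialect == "fixedStep_WIG":
        chrom, pos, step = None, 0, 1
        for ln, raw in enumerate(stream, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track")):
                continue
            if line.startswith("fixedStep"):
                fields = dict(kv.split("=") for kv in line.split()[1:])
                chrom = fields["chrom"]
                pos = int(fields["start"]) - 1  # 1-based declaration
                step = int(fields.get("step", 1))
                span = int(fields.get("span", 1))
                if span != 1:
                    raise FormatError("only span=1 fixedStep is supported", ln)
                if chrom not in sizes:
                    raise FormatError(f"unknown chromosome {chrom!r}", ln)
            else:
                if chrom is None:
                    raise FormatError("data before any fixedStep declaration", ln)
                v = _check_value(float(line), ln)
                track.set_scores(chrom, pos, np.array([v]))
                pos += step
    else:
        raise ValidationError(f"unknown track dialect {dialect!r}")
    return track


def write_score_track(track: ConservationTrack, stream: IO[str],
                      dialect: str = "bedGraph") -> None:
    """Write covered bases back out; missing (NaN) stretches are omitted."""
    if dialect == "bedGraph":
        for chrom in sorted(track.scores):
            arr = track.scores[chrom]
            start = None
            for i in range(arr.size + 1):
                here = arr[i] if i < arr.size else np.nan
                if start is not None and (np.isnan(here) or here != arr[start]):
                    stream.write(f"{chrom}\t{start}\t{i}\t{arr[start]:g}\n")
                    start = None
                if start is None and i < arr.size and not np.isnan(here):
                    start = i
    elif dialect == "fixedStep_WIG":
        for chrom in sorted(track.scores):
            arr = track.scores[chrom]
            open_block = False
            for i in range(arr.size):
                if np.isnan(arr[i]):
                    open_block = False
                    continue
                if not open_block:
                    stream.write(f"fixedStep chrom={chrom} start={i + 1} step=1\n")
                    open_block = True
                stream.write(f"{arr[i]:g}\n")
    else:
        raise ValidationError(f"unknown track dialect {dialect!r}")
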