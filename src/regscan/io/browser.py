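"""Genome-browser custom-track export.

Two emissions of the same predictions are supported: UCSC custom tracks
(``track name=...`` declarations followed by 0-based half-open BED lines,
score = similarity x 1000 rounded) and GBrowse-style GFF2 (1-based closed
coordinates, raw similarity in the score column).  The two conventions
differ exactly by the (+1, closed) shift.
"""

from __future__ import annotations

from typing import IO, Iterable, Mapping

from ..errors import ValidationError
from ..intervals import GenomeInterval
from ..pwm import SiteHit


def _bed_line(iv: GenomeInterval, name: str, score: int, strand: str) -> str:
    return f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{strand}\n"


def _gff2_line(iv: GenomeInterval, source: str, feature: str, score: float,
               strand: str, group: str) -> str:
    return (f"{iv.chrom}\t{source}\t{feature}\t{iv.start + 1}\t{iv.end}\t"
            f"{score:g}\t{strand}\t.\t{group}\n")


def write_custom_tracks(hits: Iterable[SiteHit],
                        enhancers: Mapping[str, Iterable] | None,
                        dialect: str, stream: IO[str]) -> None:
    """Write site hits and per-class enhancer calls as browser tracks.

    ``enhancers`` maps a class label (e.g. ``active``) to calls carrying a
    ``region`` attribute; each class becomes its own track.
    """
    enhancers = enhancers or {}
    if dialect == "UCSC_custom":
        stream.write('track name=tfbs description="predicted binding sites" '
                     'useScore=1\n')
        for h in hits:
            stream.write(_bed_line(h.region, f"{h.tf_name}:{h.matrix_id}",
                                   round(h.similarity * 1000), h.strand))
        for label, calls in enhancers.items():
            stream.write(f'track name=enh_{label} '
                         f'description="{label} enhancers"\n')
            for c in calls:
                region = getattr(c, "region", c)
                stream.write(_bed_line(region, f"{label}", 0, "."))
    elif dialect == "GBrowse_GFF":
        for h in hits:
            stream.write(_gff2_line(h.region, "regscan", "TF_binding_site",
                                    h.similarity, h.strand,
                                    f'Site "{h.tf_name}:{h.matrix_id}"'))
        for label, calls in enhancers.items():
            for c in calls:
                region = getattr(c, "region", c)
                stream.write(_gff2_line(region, "regscan", "enhancer", 0.0,
                                        ".", f'Enhancer "{label}"'))
    else:
        raise ValidationError(f"unknown track dialect {dialect!r}")
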