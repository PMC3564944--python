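"""Multi-species promoter maps: the phylogenetic-footprinting alternative.

Instead of aligning promoters, each species' orthologous promoter is
scanned independently; a site family present at comparable TSS-relative
positions across species is the conservation evidence.  Promoters are
extracted strand-aware so every sequence reads toward the TSS, and all
coordinates are reported TSS-anchored: with a window of ``w`` bases the TSS
sits at relative position ``w``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

from Bio.Seq import Seq

from .enrichment import promoter_region
from .errors import ValidationError
from .intervals import ChromSizes, GenomeInterval, merge
from .io.annotation import GeneModel
from .pwm import SiteHit, WeightMatrix, scan_catalog


@dataclass
class Promoter:
    """One species' promoter read toward the TSS, anchored at ``window``."""

    species: str
    gene_id: str
    sequence: str
    window: int

    @property
    def offset(self) -> int:
        """Shift so truncated promoters still anchor the TSS at ``window``."""
        return self.window - len(self.sequence)


PromoterSet = dict[str, Promoter]


def extract_ortholog_promoters(
        annotations: Mapping[str, Sequence[GeneModel]],
        genomes: Mapping[str, Mapping[str, str]],
        gene_id: str, window: int,
        ortholog_table: Mapping[str, str]) -> PromoterSet:
    """Per-species promoter sequences for one gene's ortholog family.

    ``ortholog_table`` maps species -> ortholog gene id (at most one per
    species).  Species whose ortholog cannot be located are skipped with a
    warning, not errors: assemblies are incomplete in practice.
    """
    out: PromoterSet = {}
    for species in sorted(ortholog_table):
        target = ortholog_table[species]
        models = [m for m in annotations.get(species, [])
                  if m.gene_id == target or m.transcript_id == target]
        if not models:
            warnings.warn(f"{species}: ortholog {target!r} not in annotation; "
                          "skipped")
            continue
        gm = models[0]
        genome = genomes[species]
        sizes = ChromSizes({c: len(s) for c, s in genome.items()})
        prom = promoter_region(gm, window, sizes)
        seq = genome[gm.chrom][prom.start:prom.end]
        if gm.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        out[species] = Promoter(species=species, gene_id=target,
                                sequence=seq.upper(), window=window)
    return out


def multi_species_map(promoters: PromoterSet,
                      matrix_groups: Mapping[str, Sequence[WeightMatrix]],
                      threshold: float) -> dict[str, list[SiteHit]]:
    """Scan every species' promoter; hits in TSS-anchored coordinates.

    No conservation-track filter applies here: presence of the site in each
    species' independent scan is itself the cross-species evidence.  Hits
    carry the TF group name in ``tf_name``.
    """
    out: dict[str, list[SiteHit]] = {}
    for species, prom in sorted(promoters.items()):
        hits: list[SiteHit] = []
        for group_name in sorted(matrix_groups):
            for h in scan_catalog(species, prom.sequence,
                                  matrix_groups[group_name], threshold):
                shifted = GenomeInterval(
                    species, h.region.start + prom.offset,
                    h.region.end + prom.offset, strand=h.strand,
                    name=h.matrix_id)
                hits.append(SiteHit(
                    matrix_id=h.matrix_id, tf_name=group_name,
                    region=shifted, strand=h.strand,
                    similarity=h.similarity))
        hits.sort(key=lambda h: (h.region.start, h.strand, h.matrix_id))
        out[species] = hits
    return out


@dataclass
class CompositeWindow:
    """A short promoter stretch holding sites from two motif families."""

    species: str
    interval: GenomeInterval  # promoter-relative
    members: list[SiteHit]


def composite_windows(site_map: Mapping[str, Sequence[SiteHit]],
                      group_a: str, group_b: str,
                      max_span: int) -> list[CompositeWindow]:
    """Maximal windows of span <= ``max_span`` holding both families.

    Every (a, b) pair within the span bound contributes a window from the
    leftmost to the rightmost member; overlapping windows are merged per
    species and members recollected.
    """
    if max_span < 1:
        raise ValidationError(f"max_span must be >= 1, got {max_span}")
    out: list[CompositeWindow] = []
    for species in sorted(site_map):
        hits = site_map[species]
        a_hits = [h for h in hits if h.tf_name == group_a]
        b_hits = [h for h in hits if h.tf_name == group_b]
        raw: list[GenomeInterval] = []
        for a in a_hits:
            for b in b_hits:
                lo = min(a.region.start, b.region.start)
                hi = max(a.region.end, b.region.end)
                if hi - lo <= max_span:
                    raw.append(GenomeInterval(species, lo, hi))
        for win in merge(raw):
            members = [h for h in a_hits + b_hits
                       if h.region.start >= win.start and h.region.end <= win.end]
            members.sort(key=lambda h: h.region.start)
            out.append(CompositeWindow(species=species, interval=win,
                                       members=members))
    return out
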