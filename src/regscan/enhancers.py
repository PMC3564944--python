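"""Histone-mark combinatorics: calling putative, active and poised enhancers.

Within one developmental stage, every H3K4Me1-enriched region is a
*putative* enhancer.  Overlap tests against the other marks of the same
stage add further, non-exclusive labels: *promoter_excluded* when the
region touches no H3K4Me3 (separating enhancers from promoters), *active*
when it overlaps H3K27Ac, *poised* when it overlaps H3K27Me3.  Calls then
pass through exon subtraction (base-level, fragments keep their labels), a
minimum-length filter that removes sub-200 bp masking artifacts, and a mean
conservation cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .conservation import MAX_TOL, mean_score
from .errors import ValidationError
from .intervals import (ChromSizes, GenomeInterval, covered_bases, intersect,
                        merge, overlaps_any, sort_intervals, subtract)
from .io.tracks import ConservationTrack
from .params import Params

MARKS = ("H3K4Me1", "H3K4Me3", "H3K27Ac", "H3K27Me3")
CLASSES = ("putative", "promoter_excluded", "active", "poised")


@dataclass
class PeakSet:
    """ChIP-enriched regions for one (histone mark, stage) pair."""

    mark: str
    stage: str
    regions: list[GenomeInterval]

    def __post_init__(self) -> None:
        if self.mark not in MARKS:
            raise ValidationError(f"unknown histone mark {self.mark!r}")
        self.regions = sort_intervals(self.regions)


@dataclass(frozen=True)
class EnhancerCall:
    region: GenomeInterval
    stage: str
    classes: frozenset[str]
    mean_conservation: float | None = None
    parent_peak_id: str | None = None

    def __post_init__(self) -> None:
        unknown = self.classes - set(CLASSES)
        if unknown:
            raise ValidationError(f"unknown enhancer classes {sorted(unknown)}")
        if self.classes and "putative" not in self.classes:
            raise ValidationError("every labelled call must be putative")


def classify_stage(peaks: Sequence[PeakSet]) -> list[EnhancerCall]:
    """Label each H3K4Me1 region of one stage by its mark combination.

    Labels are independent memberships, not a partition: a region may be
    simultaneously active and poised.  Promoter exclusion withholds the
    label from whole regions that touch H3K4Me3 rather than trimming them.
    """
    stages = {p.stage for p in peaks}
    if len(stages) != 1:
        raise ValidationError(f"peaks span several stages: {sorted(stages)}")
    stage = stages.pop()
    by_mark: dict[str, PeakSet] = {}
    for p in peaks:
        if p.mark in by_mark:
            raise ValidationError(f"duplicate {p.mark} peak set for {stage}")
        by_mark[p.mark] = p
    if "H3K4Me1" not in by_mark:
        raise ValidationError(f"stage {stage} lacks an H3K4Me1 peak set")
    k4me3 = by_mark.get("H3K4Me3", PeakSet("H3K4Me3", stage, [])).regions
    k27ac = by_mark.get("H3K27Ac", PeakSet("H3K27Ac", stage, [])).regions
    k27me3 = by_mark.get("H3K27Me3", PeakSet("H3K27Me3", stage, [])).regions
    calls: list[EnhancerCall] = []
    for i, region in enumerate(by_mark["H3K4Me1"].regions):
        classes = {"putative"}
        if not overlaps_any(region, k4me3):
            classes.add("promoter_excluded")
        if overlaps_any(region, k27ac):
            classes.add("active")
        if overlaps_any(region, k27me3):
            classes.add("poised")
        peak_id = region.name or f"{stage}_K4Me1_{i}"
        calls.append(EnhancerCall(region=region, stage=stage,
                                  classes=frozenset(classes),
                                  parent_peak_id=peak_id))
    return calls


def apply_filters(calls: Iterable[EnhancerCall],
                  exons: Sequence[GenomeInterval],
                  track: ConservationTrack,
                  params: Params | None = None,
                  missing: str = "zero") -> list[EnhancerCall]:
    """Exon-subtract, then length-filter, then conservation-filter calls.

    Fragments produced by exon subtraction inherit the parent's stage,
    classes and peak id.
    """
    params = params or Params()
    exons_m = merge(exons)
    out: list[EnhancerCall] = []
    for call in calls:
        for frag in subtract([call.region], exons_m):
            if len(frag) < params.enh_min_len:
                continue
            m = mean_score(track, frag, missing)
            if m < params.enh_cons_min - MAX_TOL:
                continue
            out.append(replace(call, region=frag, mean_conservation=m))
    out.sort(key=lambda c: (c.region.chrom, c.region.start, c.region.end))
    return out


def call_enhancers(peaks_by_stage: Mapping[str, Sequence[PeakSet]],
                   exons: Sequence[GenomeInterval],
                   track: ConservationTrack,
                   params: Params | None = None) -> list[EnhancerCall]:
    """Full caller over every stage: classify then filter."""
    out: list[EnhancerCall] = []
    for stage in sorted(peaks_by_stage):
        calls = classify_stage(list(peaks_by_stage[stage]))
        out.extend(apply_filters(calls, exons, track, params))
    return out


def signature_matrix(reference: Sequence[GenomeInterval],
                     calls_by_stage: Mapping[str, Sequence[EnhancerCall]]
                     ) -> pd.DataFrame:
    """Count overlapping calls per (reference region, stage, class).

    Rows are merged reference regions (browser-style labels); columns are
    ``stage|class`` pairs; a cell counts the calls of that stage carrying
    that class which share at least one base with the region.
    """
    reference = merge(reference)
    columns = [(stage, cls) for stage in sorted(calls_by_stage)
               for cls in CLASSES]
    data = []
    for ref in reference:
        row = []
        for stage, cls in columns:
            row.append(sum(1 for c in calls_by_stage[stage]
                           if cls in c.classes and ref.overlaps(c.region)))
        data.append(row)
    return pd.DataFrame(
        data, index=[str(r) for r in reference],
        columns=[f"{s}|{c}" for s, c in columns])


def coverage_breakdown(peaks_by_stage: Mapping[str, Sequence[PeakSet]],
                       exons: Sequence[GenomeInterval],
                       sizes: ChromSizes) -> pd.DataFrame:
    """Genome coverage of H3K4Me1 and each intersection with a second mark.

    One row per (stage, combination), with and without exonic bases,
    reported in bases and as a fraction of the genome.
    """
    genome = sum(sizes.values())
    exons_m = merge(exons)
    rows = []
    for stage in sorted(peaks_by_stage):
        by_mark = {p.mark: p.regions for p in peaks_by_stage[stage]}
        k4me1 = by_mark.get("H3K4Me1", [])
        combos = [("H3K4Me1", merge(k4me1))]
        for other in ("H3K4Me3", "H3K27Ac", "H3K27Me3"):
            combos.append((f"H3K4Me1 & {other}",
                           intersect(k4me1, by_mark.get(other, []))))
        for label, regions in combos:
            bases = covered_bases(regions)
            nonexonic = covered_bases(subtract(regions, exons_m))
            rows.append({
                "stage": stage, "combination": label,
                "bases": bases, "fraction": bases / genome,
                "bases_nonexonic": nonexonic,
                "fraction_nonexonic": nonexonic / genome,
            })
    return pd.DataFrame(rows)
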