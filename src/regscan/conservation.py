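"""Mean conservation over intervals and the site/region conservation filters.

Sites can be tiered by mean phastCons-style score: *none* keeps everything
(the downloadable full set), *moderate* requires the mean to reach the
0.95 default, *maximum* requires a perfectly conserved window.  Enhancer
regions use a single lower cutoff (0.5 by default).

Bases absent from the track count as score 0 by default: in a
phastCons-style track unaligned sequence is evidence of non-conservation.
``missing="ignore"`` averages over covered bases only.
"""

from __future__ import annotations

import warnings
from dataclasses import replace
from typing import Iterable, Sequence

import numpy as np

from .errors import ValidationError
from .intervals import GenomeInterval
from .io.tracks import ConservationTrack
from .params import Params
from .pwm import SiteHit

#: tolerance applied to every conservation cutoff: keeps >= semantics exact
#: at printed boundaries (e.g. a window of identical 0.95 scores) despite
#: floating-point summation
MAX_TOL = 1e-9

LEVELS = ("none", "moderate", "maximum")


def mean_score(track: ConservationTrack, region: GenomeInterval,
               missing: str = "zero") -> float:
    """Arithmetic mean conservation over a region.

    ``missing="zero"`` counts uncovered bases as 0.0; ``missing="ignore"``
    averages over covered bases only (0.0 if none are covered).
    """
    if region.chrom not in track.scores:
        warnings.warn(f"chromosome {region.chrom} absent from track; "
                      f"treating {region} as unconserved")
        return 0.0
    vals = track.values(region)
    if missing == "zero":
        return float(np.nansum(vals) / len(region))
    if missing == "ignore":
        covered = ~np.isnan(vals)
        return float(vals[covered].mean()) if covered.any() else 0.0
    raise ValidationError(f"unknown missing policy {missing!r}")


def annotate_hits(hits: Iterable[SiteHit], track: ConservationTrack,
                  missing: str = "zero") -> list[SiteHit]:
    """Attach mean conservation to every hit (coordinates untouched)."""
    return [replace(h, mean_conservation=mean_score(track, h.region, missing))
            for h in hits]


def filter_sites(hits: Iterable[SiteHit], track: ConservationTrack,
                 level: str, params: Params | None = None,
                 missing: str = "zero") -> list[SiteHit]:
    """Keep hits meeting a conservation tier; always annotates the mean."""
    params = params or Params()
    if level not in LEVELS:
        raise ValidationError(f"unknown conservation level {level!r}")
    annotated = annotate_hits(hits, track, missing)
    if level == "none":
        return annotated
    cutoff = (params.site_cons_moderate if level == "moderate"
              else params.site_cons_maximum)
    return [h for h in annotated if h.mean_conservation >= cutoff - MAX_TOL]


def filter_regions(regions: Sequence, track: ConservationTrack,
                   min_mean: float, missing: str = "zero"):
    """Keep labelled regions with mean conservation >= ``min_mean``.

    Accepts bare :class:`GenomeInterval` objects or anything carrying a
    ``region`` attribute and a ``mean_conservation`` slot (enhancer calls);
    each survivor is annotated with its mean.
    """
    if not 0.0 <= min_mean <= 1.0:
        raise ValidationError(f"min_mean must lie in [0, 1], got {min_mean}")
    out = []
    for r in regions:
        iv = getattr(r, "region", r)
        m = mean_score(track, iv, missing)
        if m >= min_mean - MAX_TOL:
            if hasattr(r, "mean_conservation"):
                r = replace(r, mean_conservation=m)
            out.append(r)
    return out
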