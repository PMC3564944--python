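"""Assessment machinery for site and enhancer predictions.

Three instruments:

* confirmation rates — merge a reference annotation (experimentally
  validated regulatory regions) into non-overlapping regions, then count
  per enhancer class how many are touched by at least one call, optionally
  restricted to calls above a conservation cutoff;
* randomization p-values — an empirical null that re-places same-length
  regions uniformly in allowed (typically non-exonic) space, preserving
  count and lengths but not spacing, with the add-one estimator so zero is
  never reported;
* recovery curves — the prediction count / recovered-reference trade-off as
  the site conservation threshold rises.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .errors import ValidationError
from .intervals import GenomeInterval, merge, overlaps_any
from .pwm import SiteHit


@dataclass
class ClassConfirmation:
    total: int
    confirmed: int

    @property
    def fraction(self) -> float:
        return self.confirmed / self.total


ConfirmationReport = dict[str, ClassConfirmation]


def confirmation_rates(reference: Sequence[GenomeInterval],
                       calls_by_class: Mapping[str, Sequence],
                       cons_filter: float | None = None) -> ConfirmationReport:
    """Fraction of merged reference regions touched by each call class.

    ``calls_by_class`` maps a class label to calls carrying ``region`` and
    ``mean_conservation``; with ``cons_filter`` only calls at or above that
    mean conservation count as support.
    """
    if not reference:
        raise ValidationError("empty reference region set")
    merged = merge(reference)
    report: ConfirmationReport = {}
    for label in sorted(calls_by_class):
        calls = calls_by_class[label]
        if cons_filter is not None:
            calls = [c for c in calls
                     if (c.mean_conservation or 0.0) >= cons_filter]
        regions = [getattr(c, "region", c) for c in calls]
        confirmed = sum(1 for ref in merged if overlaps_any(ref, regions))
        report[label] = ClassConfirmation(total=len(merged), confirmed=confirmed)
    return report


def _place_random(lengths: Sequence[int], allowed: Sequence[GenomeInterval],
                  rng: np.random.Generator) -> list[GenomeInterval]:
    """Place intervals of the given lengths uniformly inside allowed space.

    For each length, candidate start positions are all offsets where the
    interval fits entirely inside one allowed interval; one is drawn
    uniformly.  Placements are independent (overlaps between placed
    intervals are allowed, mirroring how real calls may cluster).
    """
    placed = []
    for L in lengths:
        slots = [(iv, len(iv) - L + 1) for iv in allowed if len(iv) >= L]
        if not slots:
            raise ValidationError(
                f"no allowed interval can hold a region of length {L}")
        weights = np.array([s[1] for s in slots], dtype=float)
        pick = rng.choice(len(slots), p=weights / weights.sum())
        iv, n_starts = slots[pick]
        start = iv.start + int(rng.integers(n_starts))
        placed.append(GenomeInterval(iv.chrom, start, start + L))
    return placed


def overlap_statistic(placed: Sequence[GenomeInterval],
                      reference: Sequence[GenomeInterval]) -> int:
    """Number of reference regions hit by >= 1 placed interval."""
    return sum(1 for ref in reference if overlaps_any(ref, placed))


def randomization_pvalue(observed_stat: int, region_lengths: Sequence[int],
                         allowed_space: Sequence[GenomeInterval],
                         reference: Sequence[GenomeInterval],
                         n_perm: int, seed: int,
                         return_null: bool = False):
    """Empirical upper-tail p for an observed overlap statistic.

    Add-one estimator: ``p = (1 + #{perm >= obs}) / (1 + n_perm)``, so the
    smallest reportable value is ``1/(n_perm + 1)`` rather than zero.
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    allowed = merge(allowed_space)
    null = np.empty(n_perm, dtype=int)
    for b in range(n_perm):
        placed = _place_random(region_lengths, allowed, rng)
        null[b] = overlap_statistic(placed, reference)
    p = (1 + int((null >= observed_stat).sum())) / (1 + n_perm)
    return (p, null) if return_null else p


def randomized_null_pvalue(observed_stat: int, null: np.ndarray,
                           rng: np.random.Generator) -> float:
    """Tie-broken permutation p, exactly uniform under the null.

    ``(#{null > obs} + U * (1 + #{null == obs})) / (n + 1)`` with
    U ~ Uniform(0, 1); used for calibration checks of the discrete add-one
    estimator, not for reporting.
    """
    gt = int((null > observed_stat).sum())
    eq = int((null == observed_stat).sum())
    return (gt + rng.random() * (1 + eq)) / (null.size + 1)


@dataclass
class RecoveryRow:
    threshold: float
    n_predictions: int
    n_recovered: int

    @property
    def ratio(self) -> float:
        """Predictions per recovered reference region; inf when none."""
        return (self.n_predictions / self.n_recovered
                if self.n_recovered else math.inf)


RecoveryTable = list[RecoveryRow]


def recovery_curve(hits: Sequence[SiteHit],
                   reference: Sequence[GenomeInterval],
                   thresholds: Sequence[float]) -> RecoveryTable:
    """Prediction count and reference recovery per conservation threshold.

    A reference region is *recovered* at threshold t when it contains at
    least one hit with mean conservation >= t (any overlap base counts).
    """
    if list(thresholds) != sorted(thresholds):
        raise ValidationError("thresholds must be sorted ascending")
    table: RecoveryTable = []
    for t in thresholds:
        retained = [h for h in hits if (h.mean_conservation or 0.0) >= t]
        regions = [h.region for h in retained]
        recovered = sum(1 for ref in reference if overlaps_any(ref, regions))
        table.append(RecoveryRow(threshold=t, n_predictions=len(retained),
                                 n_recovered=recovered))
    return table
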