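"""Analysis parameters.

Every numeric threshold of the prediction protocol lives here, so a run is
fully described by one record: the relative matrix-similarity cutoff used by
the scanner, the two site-level conservation tiers (moderate/maximum), the
enhancer-level conservation and length filters, the promoter window used for
enrichment and comparative maps, and the minimum span of a gene-free region.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ValidationError


@dataclass
class Params:
    """Bundle of pipeline thresholds with their standard defaults.

    Attributes
    ----------
    similarity_threshold:
        Minimum min-max-normalised matrix similarity for a site to be
        reported (fraction of the per-matrix score range).
    site_cons_moderate:
        Mean per-base conservation a site needs to pass the *moderate*
        conservation tier.
    site_cons_maximum:
        Mean conservation for the *maximum* tier (perfectly conserved).
    enh_cons_min:
        Mean conservation below which a putative enhancer is discarded.
    enh_min_len:
        Minimum enhancer fragment length in bases after exon subtraction;
        shorter fragments are treated as masking artifacts.
    promoter_window:
        Bases upstream of the TSS that define a gene promoter.
    genefree_min_len:
        Minimum length of an annotation-free interval to count as a
        gene-free region.
    pseudocount:
        Additive per-cell pseudocount used when turning matrix counts into
        probabilities.
    n_permutations:
        Default permutation count for randomization p-values.
    rng_seed:
        Seed for every stochastic component.
    """

    similarity_threshold: float = 0.85
    site_cons_moderate: float = 0.95
    site_cons_maximum: float = 1.0
    enh_cons_min: float = 0.5
    enh_min_len: int = 200
    promoter_window: int = 2000
    genefree_min_len: int = 50_000
    pseudocount: float = 1.0
    n_permutations: int = 10_000
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("similarity_threshold", "site_cons_moderate",
                     "site_cons_maximum", "enh_cons_min"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1], got {v}")
        for name in ("enh_min_len", "promoter_window", "genefree_min_len",
                     "n_permutations"):
            v = getattr(self, name)
            if int(v) != v or v < 1:
                raise ValidationError(f"{name} must be a positive integer, got {v}")
            setattr(self, name, int(v))
        if self.pseudocount <= 0:
            raise ValidationError(f"pseudocount must be > 0, got {self.pseudocount}")
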