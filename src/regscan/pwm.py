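"""Position weight matrices and both-strand occurrence scanning.

A :class:`WeightMatrix` holds per-position nucleotide counts and the
probabilities derived from them with an additive pseudocount.  Windows are
scored by the sum of log-probabilities and reported on a per-matrix
min-max-normalised *similarity* scale: 1.0 at the consensus k-mer, 0.0 at
the anti-consensus.  This relative scale is what makes a single cutoff
(e.g. 85%) meaningful across matrices of different lengths and information
content.

Scanning evaluates every window on both strands, skipping windows that
contain an ``N`` or a masked base (typically annotated exons); minus-strand
windows are scored on the reverse complement and reported in forward
coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import ValidationError
from .intervals import GenomeInterval, merge
from .params import Params

BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(BASES)}
#: complement permutation of the A,C,G,T column order
_COMP = np.array([3, 2, 1, 0])


def normalize(counts: np.ndarray, pseudocount: float) -> np.ndarray:
    """Counts -> probabilities, ``(c + q) / (rowsum + 4q)`` per cell."""
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[1] != 4:
        raise ValidationError(f"counts must be Lx4, got shape {counts.shape}")
    if (counts < 0).any():
        raise ValidationError("negative matrix counts")
    if pseudocount <= 0:
        raise ValidationError("pseudocount must be positive")
    rowsum = counts.sum(axis=1, keepdims=True)
    return (counts + pseudocount) / (rowsum + 4.0 * pseudocount)


@dataclass
class WeightMatrix:
    """A TF binding model: counts, probabilities and score-range bounds."""

    id: str
    tf_name: str
    source: str  # JASPAR | TRANSFAC | user
    counts: np.ndarray  # L x 4, order A,C,G,T
    pseudocount: float = 1.0
    probabilities: np.ndarray = field(init=False)
    log_probabilities: np.ndarray = field(init=False)
    s_min: float = field(init=False)
    s_max: float = field(init=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.probabilities = normalize(self.counts, self.pseudocount)
        self.log_probabilities = np.log(self.probabilities)
        self.s_max = float(self.log_probabilities.max(axis=1).sum())
        self.s_min = float(self.log_probabilities.min(axis=1).sum())

    def __len__(self) -> int:
        return self.counts.shape[0]

    @property
    def length(self) -> int:
        return len(self)

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.probabilities.argmax(axis=1))

    def reverse_complement(self) -> "WeightMatrix":
        rc = self.counts[::-1, _COMP]
        return WeightMatrix(self.id, self.tf_name, self.source, rc,
                            pseudocount=self.pseudocount)

    def similarity(self, kmer: str) -> float:
        """Min-max-normalised log-probability score of a k-mer in [0, 1]."""
        if len(kmer) != len(self):
            raise ValidationError(
                f"k-mer length {len(kmer)} != matrix length {len(self)}")
        try:
            idx = [_CODE[b] for b in kmer.upper()]
        except KeyError as e:
            raise ValidationError(f"non-ACGT base {e.args[0]!r} in k-mer") from None
        score = float(self.log_probabilities[np.arange(len(self)), idx].sum())
        if self.s_max == self.s_min:  # fully uniform matrix
            return 1.0
        return (score - self.s_min) / (self.s_max - self.s_min)


def similarity(matrix: WeightMatrix, kmer: str) -> float:
    return matrix.similarity(kmer)


@dataclass(frozen=True)
class SiteHit:
    """One matrix occurrence above threshold, in forward coordinates."""

    matrix_id: str
    tf_name: str
    region: GenomeInterval
    strand: str
    similarity: float
    mean_conservation: float | None = None


def encode_sequence(seq: str) -> np.ndarray:
    """ACGT -> 0..3, anything else (N etc.) -> -1."""
    table = np.full(256, -1, dtype=np.int8)
    for b, i in _CODE.items():
        table[ord(b)] = i
        table[ord(b.lower())] = i
    return table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _window_similarities(codes: np.ndarray, matrix: WeightMatrix) -> np.ndarray:
    """Similarity of every forward window; NaN where a window has a bad base."""
    L = len(matrix)
    n = codes.size - L + 1
    if n <= 0:
        return np.empty(0)
    scores = np.zeros(n)
    bad = np.zeros(n, dtype=bool)
    safe = np.where(codes >= 0, codes, 0)
    for i in range(L):
        col = codes[i:i + n]
        bad |= col < 0
        scores += matrix.log_probabilities[i, safe[i:i + n]]
    if matrix.s_max == matrix.s_min:
        sims = np.ones(n)
    else:
        sims = (scores - matrix.s_min) / (matrix.s_max - matrix.s_min)
    sims[bad] = np.nan
    return sims


def scan_sequence(name: str, sequence: str, matrix: WeightMatrix,
                  threshold: float,
                  mask: Sequence[GenomeInterval] = ()) -> list[SiteHit]:
    """All windows with similarity >= threshold, both strands.

    Windows containing an ``N`` or any base inside ``mask`` are skipped
    entirely.  Minus-strand windows are scored on the reverse complement
    (implemented by scanning the reverse-complemented matrix forward) and
    reported at their forward coordinates with strand ``-``.  Hits are
    sorted by start, ``+`` before ``-`` at equal start; overlapping hits
    are all retained.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValidationError(f"threshold must lie in [0, 1], got {threshold}")
    codes = encode_sequence(sequence)
    for iv in mask:
        if iv.chrom == name:
            codes[iv.start:min(iv.end, codes.size)] = -1
    hits: list[SiteHit] = []
    L = len(matrix)
    strand_sims = (("+", _window_similarities(codes, matrix)),
                   ("-", _window_similarities(codes, matrix.reverse_complement())))
    for strand, sims in strand_sims:
        with np.errstate(invalid="ignore"):
            keep = np.nonzero(sims >= threshold)[0]
        for j in keep:
            hits.append(SiteHit(
                matrix_id=matrix.id, tf_name=matrix.tf_name,
                region=GenomeInterval(name, int(j), int(j) + L,
                                      strand=strand, name=matrix.id),
                strand=strand, similarity=float(sims[j])))
    hits.sort(key=lambda h: (h.region.start, h.strand))
    return hits


def scan_catalog(name: str, sequence: str, catalog: Iterable[WeightMatrix],
                 threshold: float,
                 mask: Sequence[GenomeInterval] = ()) -> list[SiteHit]:
    """Scan one sequence with every matrix of a catalog."""
    hits: list[SiteHit] = []
    for m in catalog:
        hits.extend(scan_sequence(name, sequence, m, threshold, mask))
    hits.sort(key=lambda h: (h.region.chrom, h.region.start, h.strand,
                             h.matrix_id))
    return hits


def scan_with_exon_mask(genome: dict[str, str], annotation,
                        catalog: Iterable[WeightMatrix],
                        params: Params) -> list[SiteHit]:
    """Exon-masked genome-wide scan.

    The mask is the merged union of all exons of all transcripts, so only
    intergenic and intronic windows are scored.
    """
    exons = []
    for gm in annotation:
        if gm.chrom not in genome:
            raise ValidationError(
                f"annotation chromosome {gm.chrom} absent from genome")
        exons.extend(gm.exons)
    mask = merge(exons)
    catalog = list(catalog)
    hits: list[SiteHit] = []
    for chrom in sorted(genome):
        chrom_mask = [iv for iv in mask if iv.chrom == chrom]
        hits.extend(scan_catalog(chrom, genome[chrom], catalog,
                                 params.similarity_threshold, chrom_mask))
    return hits
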