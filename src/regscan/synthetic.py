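"""Seeded synthetic fixtures emulating every external input of the pipeline.

The generator is outcome-first: a fixture *plan* states what the pipeline
should conclude (which planted sites survive which conservation tier, which
designed enhancer regions carry which class labels, which ones the length
or conservation filter must remove), and the generator solves for inputs —
genome sequence, matrix catalog, conservation track, peak sets, gene models
and reference regions — that realise the plan.  The plan is exported as a
machine-readable truth manifest so tests and the acceptance script can
verify pipeline output against designed truth without recomputing it.

Everything is a deterministic function of (seed, parameters).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Mapping, Sequence

import numpy as np
from Bio.Seq import Seq

from .errors import ValidationError
from .intervals import ChromSizes, GenomeInterval
from .io.annotation import GeneModel
from .io.tracks import ConservationTrack
from .params import Params
from .pwm import BASES, WeightMatrix
from .enhancers import CLASSES, PeakSet

# ---------------------------------------------------------------------------
# genome


def make_genome(seed: int, chrom_sizes: Mapping[str, int],
                gc_fraction: float = 0.43) -> dict[str, str]:
    """I.i.d. random chromosomes with the given GC content.

    The default GC fraction mirrors the fruit-fly euchromatin.  The same
    seed always yields byte-identical sequences.
    """
    if not 0.0 < gc_fraction < 1.0:
        raise ValidationError(f"gc_fraction must lie in (0, 1), got {gc_fraction}")
    rng = np.random.default_rng(seed)
    at = (1.0 - gc_fraction) / 2.0
    gc = gc_fraction / 2.0
    probs = [at, gc, gc, at]  # A, C, G, T
    genome = {}
    for chrom in sorted(chrom_sizes):
        codes = rng.choice(4, size=chrom_sizes[chrom], p=probs)
        genome[chrom] = "".join(BASES[c] for c in codes)
    return genome


# ---------------------------------------------------------------------------
# matrix catalog


def demo_catalog(pseudocount: float = 1.0) -> list[WeightMatrix]:
    """Three synthetic TF models with sharp, distinct consensus sequences.

    Counts are strongly peaked (18 of 20 observations on the consensus
    base) so the consensus k-mer scores 1.0 and single-mismatch windows
    drop well below typical thresholds.
    """
    consensi = {
        ("M001", "TF_alpha"): "TTGACTCATC",    # AP-1-like core
        ("M002", "TF_beta"): "GCACGTGTCC",     # E-box-like
        ("M003", "TF_gamma"): "CGTGGGAAAGTC",  # Su(H)-like
    }
    catalog = []
    for (mid, name), cons in consensi.items():
        L = len(cons)
        counts = np.full((L, 4), 2.0 / 3.0)
        for i, b in enumerate(cons):
            counts[i] = 2.0 / 3.0
            counts[i, BASES.index(b)] = 18.0
        catalog.append(WeightMatrix(id=mid, tf_name=name, source="user",
                                    counts=counts, pseudocount=pseudocount))
    return catalog


# ---------------------------------------------------------------------------
# planted sites


@dataclass(frozen=True)
class Placement:
    """Where to plant one site: matrix consensus (or an explicit k-mer)."""

    chrom: str
    start: int
    matrix_id: str
    strand: str = "+"
    kmer: str | None = None  # defaults to the matrix consensus
    cons_class: str = "none"  # none | moderate | maximum


@dataclass(frozen=True)
class PlantedSite:
    chrom: str
    start: int
    end: int
    strand: str
    matrix_id: str
    kmer: str
    similarity: float
    cons_class: str


def plant_sites(genome: dict[str, str], catalog: Sequence[WeightMatrix],
                placements: Sequence[Placement]
                ) -> tuple[dict[str, str], list[PlantedSite]]:
    """Overwrite the genome at each placement; return exact planted truth.

    The planted forward-strand text of a minus-strand site is the reverse
    complement of the k-mer, so a both-strand scan recovers it with strand
    ``-`` at the same forward interval.
    """
    by_id = {m.id: m for m in catalog}
    seqs = {c: list(s) for c, s in genome.items()}
    occupied: list[GenomeInterval] = []
    manifest: list[PlantedSite] = []
    for pl in placements:
        m = by_id[pl.matrix_id]
        kmer = (pl.kmer or m.consensus()).upper()
        iv = GenomeInterval(pl.chrom, pl.start, pl.start + len(m))
        for prev in occupied:
            if iv.overlaps(prev):
                raise ValidationError(f"overlapping placements at {iv}")
        occupied.append(iv)
        text = kmer if pl.strand == "+" else str(Seq(kmer).reverse_complement())
        if iv.end > len(seqs[pl.chrom]):
            raise ValidationError(f"placement {iv} beyond chromosome end")
        seqs[pl.chrom][iv.start:iv.end] = list(text)
        manifest.append(PlantedSite(
            chrom=pl.chrom, start=iv.start, end=iv.end, strand=pl.strand,
            matrix_id=pl.matrix_id, kmer=kmer,
            similarity=m.similarity(kmer), cons_class=pl.cons_class))
    return {c: "".join(s) for c, s in seqs.items()}, manifest


def scrub_spurious_consensus(genome: dict[str, str],
                             catalog: Sequence[WeightMatrix],
                             protected: Sequence[GenomeInterval]
                             ) -> dict[str, str]:
    """Mutate chance exact-consensus windows outside the planted sites.

    Random background occasionally contains a matrix consensus by chance;
    a designed-truth genome must not, or "recover exactly the manifest"
    would be seed-dependent.  Each offending window gets one base outside
    every protected interval flipped; rescan until clean.
    """
    from .pwm import scan_sequence  # local import avoids a cycle at load
    seqs = {c: list(s) for c, s in genome.items()}
    for _ in range(10):
        dirty = False
        for chrom, chars in seqs.items():
            text = "".join(chars)
            prot = [iv for iv in protected if iv.chrom == chrom]
            for m in catalog:
                for h in scan_sequence(chrom, text, m, 1.0):
                    if any(h.region.overlaps(p) for p in prot):
                        continue
                    for pos in range(h.region.start, h.region.end):
                        if not any(p.start <= pos < p.end for p in prot):
                            base = chars[pos]
                            chars[pos] = BASES[(BASES.index(base) + 1) % 4]
                            dirty = True
                            break
        if not dirty:
            return {c: "".join(s) for c, s in seqs.items()}
    raise ValidationError("could not scrub spurious consensus windows")


# ---------------------------------------------------------------------------
# conservation


def make_conservation(sizes: ChromSizes,
                      conserved_blocks: Sequence[tuple[GenomeInterval, float]],
                      background: float = 0.2, seed: int = 0,
                      jitter: float = 0.0,
                      missing: Sequence[GenomeInterval] = ()
                      ) -> ConservationTrack:
    """Background score everywhere, elevated blocks, optional missing holes.

    Each ``(interval, high)`` block scores ``high`` minus a uniform jitter
    in ``[0, jitter]`` per base (never below background); ``missing``
    stretches are erased to the missing marker afterwards.
    """
    for iv, high in conserved_blocks:
        if not 0.0 <= background <= high <= 1.0:
            raise ValidationError(
                f"need 0 <= background <= high <= 1, got {background}/{high}")
    rng = np.random.default_rng(seed)
    track = ConservationTrack(sizes)
    for chrom, n in sizes.items():
        track.scores[chrom][:] = background
    for iv, high in conserved_blocks:
        vals = np.full(len(iv), high)
        if jitter > 0:
            vals = np.maximum(background,
                              vals - rng.uniform(0, jitter, len(iv)))
        track.scores[iv.chrom][iv.start:iv.end] = vals
    for hole in missing:
        track.scores[hole.chrom][hole.start:hole.end] = np.nan
    return track


# ---------------------------------------------------------------------------
# gene models


def make_gene_models(plan: Sequence[dict]) -> list[GeneModel]:
    """Gene models from compact dicts (chrom/strand/span/exon list)."""
    out = []
    for g in plan:
        chrom, strand = g["chrom"], g["strand"]
        s, e = g["span"]
        tid = g.get("transcript_id", g["gene_id"] + ".t1")
        out.append(GeneModel(
            gene_id=g["gene_id"], transcript_id=tid,
            chrom=chrom, strand=strand,
            span=GenomeInterval(chrom, s, e, strand=strand, name=tid),
            exons=[GenomeInterval(chrom, a, b) for a, b in g["exons"]]))
    return out


# ---------------------------------------------------------------------------
# enhancer plan -> peaks


@dataclass(frozen=True)
class PlannedEnhancer:
    """Designed outcome for one H3K4Me1 region in one stage.

    ``fate`` states what the filtered caller must do with the region:
    ``kept`` (survives with the stated classes), ``filtered_by_length``
    (shorter than the minimum), or ``filtered_by_conservation`` (left on
    background conservation).
    """

    chrom: str
    start: int
    end: int
    stage: str
    classes: frozenset[str]
    fate: str = "kept"

    def region(self) -> GenomeInterval:
        return GenomeInterval(self.chrom, self.start, self.end,
                              name=f"{self.stage}_{self.chrom}_{self.start}")


def _validate_plan(plan: Sequence[PlannedEnhancer], params: Params) -> None:
    for p in plan:
        unknown = p.classes - set(CLASSES)
        if unknown:
            raise ValidationError(f"plan {p}: unknown classes {sorted(unknown)}")
        if "putative" not in p.classes:
            raise ValidationError(
                f"plan {p}: classes without putative are contradictory")
        if p.fate not in ("kept", "filtered_by_length",
                          "filtered_by_conservation"):
            raise ValidationError(f"plan {p}: unknown fate {p.fate!r}")
        if p.fate == "filtered_by_length" and p.end - p.start >= params.enh_min_len:
            raise ValidationError(
                f"plan {p}: region too long to be filtered by length")
        if p.fate == "kept" and p.end - p.start < params.enh_min_len:
            raise ValidationError(f"plan {p}: kept region shorter than minimum")


def make_peaks(plan: Sequence[PlannedEnhancer],
               params: Params | None = None) -> dict[str, list[PeakSet]]:
    """Solve the plan for per-stage peak sets.

    Every planned region becomes an H3K4Me1 peak.  A short internal
    sub-interval of the region is emitted as an H3K27Ac (active) or
    H3K27Me3 (poised) peak; a region *not* promoter-excluded receives an
    overlapping H3K4Me3 peak.
    """
    params = params or Params()
    _validate_plan(plan, params)
    by_stage: dict[str, dict[str, list[GenomeInterval]]] = {}
    for p in plan:
        marks = by_stage.setdefault(p.stage, {m: [] for m in
                                              ("H3K4Me1", "H3K4Me3",
                                               "H3K27Ac", "H3K27Me3")})
        region = p.region()
        marks["H3K4Me1"].append(region)
        mid = (p.start + p.end) // 2
        sub = GenomeInterval(p.chrom, max(p.start, mid - 25),
                             min(p.end, mid + 25))
        if "active" in p.classes:
            marks["H3K27Ac"].append(sub)
        if "poised" in p.classes:
            marks["H3K27Me3"].append(sub)
        if "promoter_excluded" not in p.classes:
            marks["H3K4Me3"].append(sub)
    return {stage: [PeakSet(mark, stage, regions)
                    for mark, regions in marks.items()]
            for stage, marks in by_stage.items()}


def make_reference_crms(plan: Sequence[PlannedEnhancer],
                        sizes: ChromSizes, n_decoys: int = 3,
                        seed: int = 0) -> tuple[list[GenomeInterval], list[bool]]:
    """Reference regions with known overlap truth.

    One reference region is centred on each *kept* planned enhancer
    (overlap truth True); ``n_decoys`` regions are dropped into space at
    least 1 kb away from every planned region (truth False).
    """
    rng = np.random.default_rng(seed)
    refs, truth = [], []
    kept = [p for p in plan if p.fate == "kept"]
    for p in kept:
        mid = (p.start + p.end) // 2
        refs.append(GenomeInterval(p.chrom, max(0, mid - 100), mid + 100))
        truth.append(True)
    avoid = [GenomeInterval(p.chrom, max(0, p.start - 1000), p.end + 1000)
             for p in plan]
    chroms = sorted(sizes)
    made = 0
    while made < n_decoys:
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(sizes[chrom] - 200))
        cand = GenomeInterval(chrom, start, start + 200)
        if any(cand.overlaps(a) for a in avoid) or \
                any(cand.overlaps(r) for r in refs):
            continue
        refs.append(cand)
        truth.append(False)
        made += 1
    return refs, truth


# ---------------------------------------------------------------------------
# the coherent bundle


@dataclass
class TruthManifest:
    """Designed ground truth of one fixture bundle (JSON-serialisable)."""

    seed: int
    chrom_sizes: dict[str, int]
    planted_sites: list[PlantedSite]
    enhancer_plan: list[PlannedEnhancer]
    reference_overlap_truth: list[bool]
    conserved_high: float
    conserved_background: float

    def to_json(self) -> str:
        d = asdict(self)
        for p in d["enhancer_plan"]:
            p["classes"] = sorted(p["classes"])
        return json.dumps(d, indent=1, sort_keys=True)


@dataclass
class FixtureBundle:
    genome: dict[str, str]
    sizes: ChromSizes
    catalog: list[WeightMatrix]
    track: ConservationTrack
    gene_models: list[GeneModel]
    peaks_by_stage: dict[str, list[PeakSet]]
    reference_crms: list[GenomeInterval]
    aliases: list[tuple[str, str, str]]  # gene_id, namespace, alias
    manifest: TruthManifest


def make_bundle(seed: int, chrom_sizes: Mapping[str, int] | None = None,
                params: Params | None = None,
                high: float = 0.97, background: float = 0.2) -> FixtureBundle:
    """One coherent, fully designed test genome.

    Two chromosomes carry: three genes (one minus-strand) whose exons drive
    masking and whose TSSs define promoters; planted consensus sites in the
    three conservation classes, on both strands, inside promoters, introns
    and an exon (the designed negative for masking); six planned enhancer
    regions across two stages covering every class combination plus one
    length-filtered and one conservation-filtered negative; reference
    regions centred on kept enhancers plus decoys.
    """
    params = params or Params()
    sizes = ChromSizes(chrom_sizes or {"chr2L": 40_000, "chr3R": 30_000})
    catalog = demo_catalog(params.pseudocount)
    genome = make_genome(seed, sizes)

    gene_models = make_gene_models([
        dict(gene_id="g1", chrom="chr2L", strand="+", span=(5_000, 8_000),
             exons=[(5_000, 5_600), (7_200, 8_000)]),
        dict(gene_id="g2", chrom="chr2L", strand="-", span=(20_000, 24_000),
             exons=[(20_000, 21_000), (23_000, 24_000)]),
        dict(gene_id="g3", chrom="chr3R", strand="+", span=(10_000, 12_500),
             exons=[(10_000, 10_800), (11_900, 12_500)]),
    ])
    aliases = [("g1", "symbol", "alpha-target"), ("g1", "CG", "CG0001"),
               ("g2", "symbol", "beta-target"), ("g2", "CG", "CG0002"),
               ("g3", "symbol", "gamma-target"), ("g3", "CG", "CG0003")]

    placements = [
        # promoter sites (upstream of each TSS), conserved at both tiers
        Placement("chr2L", 4_000, "M001", "+", cons_class="maximum"),
        Placement("chr2L", 4_500, "M002", "-", cons_class="moderate"),
        Placement("chr2L", 24_500, "M001", "+", cons_class="maximum"),
        Placement("chr3R", 8_500, "M003", "+", cons_class="moderate"),
        # intronic site, weakly conserved
        Placement("chr2L", 6_000, "M003", "+", cons_class="none"),
        # intergenic minus-strand site
        Placement("chr3R", 20_000, "M002", "-", cons_class="maximum"),
        # designed negative: inside g1 exon 1, masked out of every scan
        Placement("chr2L", 5_100, "M001", "+", cons_class="maximum"),
    ]
    genome, planted = plant_sites(genome, catalog, placements)
    genome = scrub_spurious_consensus(
        genome, catalog,
        [GenomeInterval(s.chrom, s.start, s.end) for s in planted])

    plan = [
        PlannedEnhancer("chr2L", 14_000, 15_000, "E8-12h",
                        frozenset({"putative", "promoter_excluded",
                                   "active"})),
        PlannedEnhancer("chr2L", 16_000, 17_200, "E8-12h",
                        frozenset({"putative", "promoter_excluded",
                                   "poised"})),
        PlannedEnhancer("chr2L", 30_000, 30_900, "E8-12h",
                        frozenset({"putative"})),  # touches a K4me3 promoter peak
        PlannedEnhancer("chr3R", 2_000, 3_000, "L3",
                        frozenset({"putative", "promoter_excluded",
                                   "active", "poised"})),
        PlannedEnhancer("chr3R", 15_000, 15_150, "L3",
                        frozenset({"putative", "promoter_excluded"}),
                        fate="filtered_by_length"),
        PlannedEnhancer("chr3R", 22_000, 23_000, "L3",
                        frozenset({"putative", "promoter_excluded"}),
                        fate="filtered_by_conservation"),
    ]
    peaks = make_peaks(plan, params)
    refs, truth = make_reference_crms(plan, sizes, n_decoys=3, seed=seed + 1)

    blocks: list[tuple[GenomeInterval, float]] = []
    for s in planted:
        if s.cons_class == "maximum":
            blocks.append((GenomeInterval(s.chrom, s.start, s.end), 1.0))
        elif s.cons_class == "moderate":
            blocks.append((GenomeInterval(s.chrom, s.start, s.end),
                           params.site_cons_moderate))
    for p in plan:
        if p.fate != "filtered_by_conservation":
            blocks.append((p.region(), high))
    track = make_conservation(sizes, blocks, background=background,
                              seed=seed + 2)

    manifest = TruthManifest(
        seed=seed, chrom_sizes=dict(sizes), planted_sites=planted,
        enhancer_plan=plan, reference_overlap_truth=truth,
        conserved_high=high, conserved_background=background)
    return FixtureBundle(genome=genome, sizes=sizes, catalog=catalog,
                         track=track, gene_models=gene_models,
                         peaks_by_stage=peaks, reference_crms=refs,
                         aliases=aliases, manifest=manifest)
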