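"""Matrix normalisation, similarity scoring and both-strand scanning."""

import math

import numpy as np
import pytest

from regscan.errors import ValidationError
from regscan.intervals import GenomeInterval
from regscan.params import Params
from regscan.pwm import (WeightMatrix, normalize, scan_catalog, scan_sequence,
                         scan_with_exon_mask)
from regscan.synthetic import demo_catalog, make_genome


def simple_matrix(counts, **kw):
    return WeightMatrix(id="m", tf_name="tf", source="user",
                        counts=np.array(counts, dtype=float), **kw)


REVCOMP = str.maketrans("ACGT", "TGCA")


def brute_force_scan(sequence, matrix, threshold):
    """Independent window scorer: every window, both strands, via the
    k-mer similarity formula directly."""
    L = len(matrix)
    out = []
    for start in range(len(sequence) - L + 1):
        window = sequence[start:start + L].upper()
        if set(window) - set("ACGT"):
            continue
        for strand in "+-":
            kmer = window if strand == "+" else window.translate(REVCOMP)[::-1]
            s = matrix.similarity(kmer)
            if s >= threshold:
                out.append((start, start + L, strand, round(s, 12)))
    out.sort()
    return out


class TestNormalize:
    def test_forced_arithmetic(self):
        got = normalize(np.array([[3.0, 1.0, 0.0, 0.0]]), 1.0)
        assert np.allclose(got, [[0.5, 0.25, 0.125, 0.125]])

    def test_uniform_row_symmetry(self):
        for q in (0.1, 1.0, 7.0):
            got = normalize(np.ones((3, 4)), q)
            assert np.allclose(got, 0.25)

    def test_rows_sum_to_one(self, rng):
        counts = rng.uniform(0, 50, size=(12, 4))
        assert np.allclose(normalize(counts, 0.5).sum(axis=1), 1.0)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValidationError):
            normalize(np.array([[1.0, -1.0, 0.0, 0.0]]), 1.0)
        with pytest.raises(ValidationError):
            normalize(np.zeros((1, 4)), 0.0)


class TestSimilarity:
    def test_consensus_and_anticonsensus_hit_bounds(self):
        m = simple_matrix([[8, 1, 0, 0], [0, 9, 2, 1], [1, 0, 0, 7]])
        assert m.similarity(m.consensus()) == pytest.approx(1.0)
        anti = "".join("ACGT"[i] for i in m.log_probabilities.argmin(axis=1))
        assert m.similarity(anti) == pytest.approx(0.0)

    def test_length_one_closed_form(self):
        # counts (3,1,0,0), pseudocount 1 -> p = (.5,.25,.125,.125);
        # sim("C") = (log .25 - log .125) / (log .5 - log .125) = 1/2
        m = simple_matrix([[3, 1, 0, 0]])
        assert m.similarity("C") == pytest.approx(
            (math.log(0.25) - math.log(0.125))
            / (math.log(0.5) - math.log(0.125)))
        assert m.similarity("C") == pytest.approx(0.5)

    def test_uniform_matrix_convention(self):
        m = simple_matrix([[1, 1, 1, 1], [2, 2, 2, 2]])
        assert m.similarity("AT") == 1.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            simple_matrix([[1, 1, 1, 1]]).similarity("AA")

    def test_similarity_in_unit_interval_everywhere(self, rng):
        m = simple_matrix(rng.uniform(0, 20, size=(5, 4)))
        kmers = ["".join("ACGT"[i] for i in rng.integers(0, 4, 5))
                 for _ in range(50)]
        sims = [m.similarity(k) for k in kmers]
        assert all(0.0 <= s <= 1.0 for s in sims)
        consensus = m.consensus()
        assert all(s < 1.0 for k, s in zip(kmers, sims) if k != consensus)


class TestScan:
    def test_planted_consensus_recovered(self):
        m = demo_catalog()[0]
        seq = "A" * 100 + m.consensus() + "A" * 100
        hits = scan_sequence("chrA", seq, m, 1.0)
        plus = [h for h in hits if h.strand == "+"]
        assert [(h.region.start, h.similarity) for h in plus] == [(100, 1.0)]

    def test_minus_strand_reported_in_forward_coordinates(self):
        m = demo_catalog()[0]
        rc = m.consensus().translate(REVCOMP)[::-1]
        seq = "A" * 50 + rc + "A" * 50
        hits = scan_sequence("chrA", seq, m, 1.0)
        assert [(h.region.start, h.strand) for h in hits] == [(50, "-")]

    def test_n_windows_skipped(self):
        m = demo_catalog()[0]
        seq = "A" * 20 + m.consensus()[:-1] + "N" + "A" * 20
        assert scan_sequence("chrA", seq, m, 0.9) == []

    def test_masked_windows_skipped(self):
        m = demo_catalog()[0]
        seq = "A" * 100 + m.consensus() + "A" * 100
        mask = [GenomeInterval("chrA", 105, 106)]
        assert all(h.region.start != 100
                   for h in scan_sequence("chrA", seq, m, 1.0, mask))

    def test_matrix_longer_than_sequence_is_empty(self):
        m = demo_catalog()[0]
        assert scan_sequence("chrA", "ACGT", m, 0.0) == []

    def test_matches_brute_force_oracle(self):
        genome = make_genome(11, {"chrA": 3_000})
        for m in demo_catalog():
            got = [(h.region.start, h.region.end, h.strand,
                    round(h.similarity, 12))
                   for h in scan_sequence("chrA", genome["chrA"], m, 0.80)]
            assert sorted(got) == brute_force_scan(genome["chrA"], m, 0.80)

    def test_threshold_monotonicity(self):
        genome = make_genome(12, {"chrA": 5_000})
        m = demo_catalog()[1]
        keys = lambda hs: {(h.region.start, h.strand) for h in hs}
        prev = None
        for t in (0.7, 0.8, 0.9, 1.0):
            cur = keys(scan_sequence("chrA", genome["chrA"], m, t))
            if prev is not None:
                assert cur <= prev
            prev = cur

    def test_strand_symmetry(self):
        genome = make_genome(13, {"chrA": 2_000})
        seq = genome["chrA"]
        m = demo_catalog()[0]
        fwd = scan_sequence("chrA", seq, m, 0.8)
        rev = scan_sequence("chrA", seq.translate(REVCOMP)[::-1], m, 0.8)
        n = len(seq)
        flipped = {(n - h.region.end, "+-"["+-".index(h.strand) ^ 1],
                    round(h.similarity, 9)) for h in rev}
        assert {(h.region.start, h.strand, round(h.similarity, 9))
                for h in fwd} == flipped


class TestExonMaskedScan:
    def test_compositional_with_precomputed_mask(self, bundle):
        params = Params()
        got = scan_with_exon_mask(bundle.genome, bundle.gene_models,
                                  bundle.catalog, params)
        exons = []
        for gm in bundle.gene_models:
            exons.extend(gm.exons)
        manual = []
        for chrom in sorted(bundle.genome):
            manual.extend(scan_catalog(
                chrom, bundle.genome[chrom], bundle.catalog,
                params.similarity_threshold,
                [e for e in exons if e.chrom == chrom]))
        assert got == manual

    def test_exonic_plant_masked_intronic_kept(self, bundle):
        hits = scan_with_exon_mask(bundle.genome, bundle.gene_models,
                                   bundle.catalog, Params())
        starts = {(h.region.chrom, h.region.start) for h in hits}
        assert ("chr2L", 5_100) not in starts  # planted inside g1 exon
        assert ("chr2L", 6_000) in starts      # planted in g1 intron

    def test_unknown_chromosome_rejected(self, bundle):
        from regscan.io.annotation import GeneModel
        ghost = GeneModel(gene_id="gx", transcript_id="gx.t1", chrom="chrZZ",
                          strand="+",
                          span=GenomeInterval("chrZZ", 0, 100, strand="+"),
                          exons=[GenomeInterval("chrZZ", 0, 50)])
        with pytest.raises(ValidationError):
            scan_with_exon_mask(bundle.genome, [ghost], bundle.catalog,
                                Params())
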