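# Methods

## Scope and coordinate conventions

All internal coordinates are 0-based half-open on named chromosomes;
conversion to the 1-based closed convention of GFF and genome browsers
happens only in I/O code and at the command line (which accepts
browser-style `chrom:start-end`). Interval-set algebra (merge, intersect,
subtract, complement) is exact at base resolution, implemented as
O(n log n) sort-sweeps and tested against per-base boolean-array oracles.
`merge` joins abutting intervals (`end == start`) by default — "coincident"
regions sharing a boundary collapse to one region — with a flag to require
strict overlap instead. Overlap everywhere means ≥ 1 shared base; no
minimum-fraction semantics are offered. `subtract` deliberately does *not*
merge its minuend: each input interval is cut independently and fragments
keep the parent's strand and name, which is how enhancer class labels
survive exon masking.

## Binding-site model

A weight matrix stores raw counts (JASPAR raw-PFM and TRANSFAC dialects are
read via Bio.motifs; several matrices may share one TF name and are grouped
for reporting). Probabilities use an additive per-cell pseudocount
(default 1.0); the pseudocount is a free parameter because source catalogs
do not prescribe one, and any positive value keeps log-scores finite.
Window scores are sums of log-probabilities, reported as min–max-normalised
similarity: 0 at the anti-consensus, 1 at the consensus, the construction
used by the MatInspector family of scanners. This relative scale is what
makes one cutoff meaningful across matrices of different length and
information content; the default cutoff is 0.85.

Scanning evaluates every window on both strands. Minus-strand windows are
scored by scanning the reverse-complemented matrix forward (provably
equivalent to scoring the reverse-complemented window, and the score range
is reversal-invariant) and are reported at forward coordinates. Windows
containing an `N` or any masked base are skipped whole — no partial
scoring — which keeps results deterministic and order-independent. All
super-threshold hits are kept, including overlapping hits and both-strand
duplicates; any best-hit reduction can be layered downstream without loss.

## Conservation

The conservation track emulates a phastCons posterior: one value in [0, 1]
per covered base, with an explicit missing marker at the storage level.
Policy lives in the scoring layer: by default a missing base counts as 0.0
(in a phastCons-style track, unaligned sequence is evidence of
non-conservation, and this choice is conservative for the strict tiers),
with an `ignore` switch that averages covered bases only. Site tiers are
*none* (everything, annotated), *moderate* (mean ≥ 0.95) and *maximum*
(mean = 1.0); enhancer regions use a single mean ≥ 0.5 rule. All cutoffs
use ≥ semantics with a 1e-9 tolerance so that a window of identical
boundary scores (e.g. ten bases at exactly 0.95) is kept despite
floating-point summation.

## Enhancer calling

Within one stage, every H3K4Me1 region becomes a putative enhancer call;
promoter exclusion, activity (H3K27Ac) and poising (H3K27Me3) are three
independent overlap tests against the same stage's other mark sets —
active and poised are not mutually exclusive. Promoter exclusion removes
whole H3K4Me1 regions that touch H3K4Me3 rather than trimming them: the
near-identical average sizes of the with- and without-promoter sets under
this protocol are consistent with whole-region exclusion, not
base-subtraction. Exon masking, by contrast, is base-level subtraction,
because the sub-200 bp artifacts the length filter removes are exactly the
fragments such cutting produces. The filter order is combine →
exon-subtract → length → conservation; the order of the last two is not
uniquely determined by the protocol narrative, and since both are pure
per-fragment predicates the surviving set is the same either way — only
the attribution of *why* a fragment died can differ. Summary products are
a signature matrix (reference regions × (stage, class) overlap counts) and
a per-stage coverage table of H3K4Me1 and its intersections with each
second mark, before and after exon removal.

## Enrichment

The statistic is a one-sided hypergeometric upper tail on gene counts:
genes carry a TF group or not, depending on whether at least one group hit
lies fully inside the promoter window (full containment avoids
double-counting boundary sites). Promoters are the 2,000 nt upstream of
the TSS, strand-aware, clipped at chromosome edges; the TSS is derived
from the transcript span and strand. Gene aliases resolve
case-insensitively across FlyBase/RefSeq/Entrez/symbol/CG-style
namespaces, with near-miss suggestions and hard errors on ambiguity.
Rankings are on raw p-values (ties broken by larger overlap then model
id); Benjamini–Hochberg adjustment is available behind a flag. The
hypergeometric choice is the canonical test for this 2×2 contingency; no
claim is made that it reproduces p-values produced by other tools whose
statistic (e.g. site-count-based) is not specified.

## Comparative promoter maps

Orthology is supplied as an explicit species → gene table rather than
computed, keeping the module free of alignment machinery. Promoters are
extracted per species, reverse-complemented on minus strands so all
sequences read toward the TSS, and scanned independently — cross-species
evidence is the presence of sites in each species' own map, not
alignment-anchored conservation. Coordinates are TSS-anchored: with window
*w* the TSS sits at relative position *w*, and truncated promoters keep
the anchor via an offset. Composite windows (≤ `max_span` containing ≥ 1
hit from each of two motif groups, merged when overlapping) automate the
visual "two-family module" reading of such maps. The scan threshold
defaults to the genome-wide similarity cutoff.

## Evaluation

Reference regions are merged before counting so overlapping annotations
cannot be double-confirmed. The randomization null re-places regions of
the observed lengths uniformly at random in allowed (non-exonic) space,
preserving count and lengths but not spacing — the simplest defensible
null for "do calls hit references more often than chance" — and placements
are independent, so placed regions may overlap each other just as real
calls may. The estimator is add-one (p is never 0; the smallest
reportable value is 1/(n_perm + 1)). Because both the hypergeometric and
the permutation p-values are discrete, they are *superuniform* under the
null, and a raw Kolmogorov–Smirnov test against U(0, 1) would reject by
construction; calibration tests therefore apply the standard randomized
probability-integral transform (for the permutation case, the randomized
tie-broken p-value, which is exactly uniform under the null for the same
statistic). The reported estimators are unchanged. Recovery curves report
prediction counts and recovered-reference counts along rising conservation
thresholds; the ratio is ∞ when nothing is recovered.

## Synthetic fixtures

The generator is outcome-first: fixture plans state intended results —
which planted sites survive which conservation tier, which designed
enhancer regions carry which class labels, which regions the length or
conservation filter must remove, which reference regions overlap calls —
and the generator solves for inputs realising them. Background sequence is
i.i.d. with GC 0.43 (fruit-fly-like euchromatin); sites are planted as
matrix consensi (strand-aware); conservation is background 0.2 with
elevated blocks (1.0 over "maximum" sites, 0.95 over "moderate" sites,
0.97 over surviving enhancers), optionally jittered, with insertable
missing stretches. Because random background occasionally contains a
chance exact consensus, the generator scrubs such windows (one base flipped
outside every planted interval, rescanning until clean) so
"scan recovers exactly the manifest" holds for every seed, not just lucky
ones. The default bundle is two chromosomes of 40 kb and 30 kb, three
genes (one minus-strand), three sharp synthetic TF models, seven planted
sites (including one inside an exon as a designed masking negative), six
planned enhancer regions over two stages, and reference regions centred on
kept enhancers plus decoys placed ≥ 1 kb from any planned region.

What the fixtures do *not* emulate: ChIP-seq read noise and peak-calling
variability, realistic motif degeneracy and genomic repeat structure,
alignment gaps and assembly errors behind real conservation tracks, and
genome-scale catalog sizes. Passing tests therefore demonstrate
correctness of the algorithms and their contracts, not predictive accuracy
on real epigenomes.

## Problem sizes and defaults

Default thresholds: similarity 0.85; site conservation tiers 0.95 and 1.0;
enhancer conservation 0.5; minimum enhancer length 200 bp; promoter window
2,000 nt; gene-free minimum 50 kb (the acceptance script uses 5 kb on the
70 kb fixture genome, the same scale ratio); pseudocount 1.0. Test and
acceptance workloads are sized for interactive runs: 10 kb scanner-oracle
comparisons, 100 kb interval-algebra cases, 100 randomized monotonicity
fixtures, 500-draw calibration checks, 2,000-permutation enumeration
comparisons. The permutation placement loop is pure Python and linear in
n_perm × regions; genome-scale use would vectorise it, which is out of
scope here.

## Known limitations

- The scanner is a zeroth-order model; dinucleotide dependence and
  variable-length motifs are not represented.
- `overlaps_any` and the confirmation/recovery counters are linear scans,
  adequate at fixture scale but not for millions of intervals.
- The missing-as-zero conservation rule is one of two defensible choices;
  both are exposed, and results near a tier boundary can differ between
  them.
- Gene-free region analysis treats transcript spans as the only
  annotation; unannotated non-transcript features are invisible to it.
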