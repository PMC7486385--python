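# Methods

## Coordinate and adjacency conventions

All coordinates, in memory and on disk, are BED-style 0-based half-open
`[start, end)`. 1-based inputs are never auto-detected; a fully disjoint
chromosome namespace between two inputs (`chr1` vs `1`) is a hard error with
an explicit renaming map as the fix, because silently dropping whole
chromosomes is the characteristic failure mode of genome-interval joins.

Two adjacency rules coexist deliberately. Gap-based merging
(`merge_within`, stitching) treats bookended intervals (gap exactly 0) as
mergeable, since a 0 bp separation satisfies "gap ≤ d" for every d ≥ 0.
Overlap-based operations (base-pair intersection, the dual-mark union, SE
combination) require at least one shared base, so bookended intervals do
not connect. Both match the dominant behaviour of the field's interval
tooling.

## Domain calling

**Replicate consensus** is the base-pair intersection of replicate peak
calls: a base survives iff every replicate called it, and the surviving
bases are reported as maximal sub-intervals. Intersection is associative,
so folding more than two replicates is order-independent (asserted by
test). Peak-level alternatives (reciprocal-overlap matching) retain whole
peaks and hence broader, noisier breadths; the base-pair rule is the
stricter and simpler contract.

**Breadth ranking.** Consensus peaks are sorted by breadth descending, ties
broken by coordinate so ranks are stable. The top-fraction cut keeps
n = ⌈f·N⌉ peaks *plus every peak tying the boundary breadth*. The tie rule
makes the kept set a deterministic function of the breadth multiset,
independent of sort stability; with continuous real-data breadths it almost
never fires, but it removes the one source of platform-dependent output.
Defaults: f = 0.02 for the dual-mark analysis, 0.05 for single-mark
(H3K4Me3-style) domains, 0.01 available where a smaller list is wanted —
a ranking cutoff rather than an absolute bp threshold, because rank
fractions transfer across datasets with different peak-size scales.

**Domain construction.** Top-tier peaks of the two marks are joined into an
overlap graph (edge = ≥ 1 shared base); every connected component containing
at least one peak of each mark becomes one HCD whose span is the component's
union. For intervals, connected components are exactly the strict-overlap
chains in coordinate order, so a single sweep implements the graph
definition (verified against a union-find oracle). Components supported by
a single mark are discarded. Domain IDs are `HCD_<chrom>_<start>` so joins
across runs are reproducible. Single-mark domains are simply the kept peaks
promoted to domains — no cross-peak merging, matching the intent of
breadth-only stratification of one mark.

## Super-enhancer calling

The comparator follows the published ROSE geometry with the settings the
HCD comparison uses: a ±500 bp TSS exclusion zone and 12.5 kb stitching.

* **TSS exclusion** removes candidates *fully contained* in
  `[tss − 500, tss + 500]` (an any-overlap mode exists but is off by
  default, matching the reference implementation's containment behaviour).
* **Stitching** merges candidates separated by ≤ 12.5 kb; spans equal
  `merge_within` at the same distance, with constituent bookkeeping.
* **Scoring** sums per-million-normalised treatment signal over the
  *constituent enhancers only* (not the stitched gaps), subtracts the
  control scored the same way, and floors at zero. Normalisation divides by
  the track's total signal (Σ value·width, or a supplied library size) ×
  1e6. Scoring constituents rather than whole stitched spans is a declared
  choice — the published description does not pin it down — so absolute
  region counts on real data are sensitive to it.
* **Elbow cutoff.** Scores are clamped at zero, sorted ascending; with
  slope m = (max − min)/N the cutoff position x minimises the number of
  points strictly below the line of slope m through (x, s_x), ties toward
  the smallest x. The implementation evaluates every position (O(N²),
  vectorised; N is the stitched-region count, typically ≤ 10⁴) and is
  tested against an independent double-loop search. Constant score vectors
  are degenerate: the cutoff equals the constant and nothing exceeds it,
  which is logged. Super-enhancers are regions with score strictly above
  the cutoff value. The cutoff index is invariant under uniform positive
  scaling of the scores.

Dual-mark super-enhancers are the union spans of overlap-connected
components containing SEs of both marks — the same connected-union
machinery as the HCD call.

## Gene association and expression comparison

Nearest-gene association uses gap distance (0 for any overlap, including
bookended contact); all equidistant ties are reported in deterministic
(chrom, start, gene_id) order, the convention of the standard
closest-feature tools' defaults. Signed distance is negative when the gene
lies at lower coordinates than the feature. The containment diagnostic
asks whether the nearest gene's TSS lies inside the feature span (the TSS,
not the gene body, is the regulatory anchor; body containment can be
derived from distance 0). `containment_fraction` represents each feature by
its first tie.

Gene categories: `hcd_only`, `se_only`, `both` (set algebra on the two
association gene sets; cardinalities conserve by construction), plus an
"enhancers within introns" control — genes hosting ≥ 1 candidate enhancer
fully inside the gene body and clear of every TSS zone. Without exon
structure, body containment approximates intronic placement; this is a
declared approximation, not a claim about splicing structure.

Expression comparison is a two-tailed two-sample Student's t-test, pooled
variance with df = n₁ + n₂ − 2 by default, Welch as an option. Values are
tested on the scale provided (microarray platforms are typically already
log-scale); a log2(x+1) transform is available but never applied silently.
Multiple probes per gene are aggregated by mean (max optional) at table
load. Zero variance in both samples yields t = 0, p = 1 when means agree
and an error otherwise. No multiple-testing correction is applied: the
comparisons are individually reported pairwise tests. An optional
"expressed only" threshold restricts the gene universe *before* the nearest
search, as one operational reading of "nearest active gene"; the default is
no filter.

## Synthetic landscape

The generator emulates the input structure the pipeline consumes, scaled to
run in seconds: two chromosomes of 16 Mb; 300 genes of 2–8 kb placed left to
right with inter-gene gaps uniform on 50–90 kb; 15 planted "identity" loci
receiving broad peaks at all three marks (log-normal breadth, median 15 kb,
σ = 0.25, truncated to [9, 40] kb) centred on the TSS, the methyl marks
shifted by ≤ 500 bp; the remaining genes receiving one narrow peak per mark
(median 1 kb, σ = 0.35, truncated to [0.3, 5] kb) near the TSS. Replicate 2
jitters each edge of replicate 1 by ≤ 50 bp. Ten further loci (disjoint
from the domain loci) carry clusters of 2–4 enhancer candidates spaced 3 kb
apart at signal density 8.0; every other gene gets one candidate 2–10 kb
from its TSS at density 1.0; the control track is flat at 0.2. Expression
is 8.0 + N(0, 1), +3.0 at planted domain genes (a log2-microarray-like
scale).

Randomness: each stage (genes → peaks → signal → expression) draws from its
own substream seeded by (stage id, run seed). A fixed seed therefore gives
byte-identical outputs, stages can be called independently or via
`simulate_all` with identical results, and adding config fields to a later
stage can never reshuffle an earlier one.

Two choices trade realism for determinism, deliberately. First, the breadth
truncation bounds guarantee every planted consensus peak is broader than
every background peak, so the 5% filter on 300 peaks recovers exactly the
15 planted loci — recovery is a construction guarantee, not a probabilistic
outcome, and the recovery tests cannot flake. Second, the ≥ 8× density
separation with ~20× score separation pins the elbow at the top of the
background curve, so the planted clusters are exactly the called SEs.
Consequently, passing the end-to-end tests demonstrates that the pipeline's
plumbing (consensus, ranking, union, stitching, scoring, cutoff,
association, testing) is correct under clean separation; it does *not*
demonstrate sensitivity/specificity under realistic overlap between the
domain and background breadth distributions, mappability artefacts,
replicate disagreement beyond edge jitter, or copy-number-driven signal.
Real-data counts additionally depend on the upstream peak caller's version
and parameters, which this package consumes as given.

Recovery scoring matches called to planted spans greedily by descending
Jaccard with a 0.5 floor, one-to-one; precision = matched/called (reported
as 0 with a warning when nothing is called), recall = matched/planted.
Greedy matching is within one pair of the optimal assignment on the tested
instances (checked against an augmenting-path maximum matching at small n).

## Problem sizes

The test suite and the acceptance script run the generator at its default
scale (300 genes, ~600 peaks per mark across replicates, 318 enhancer
candidates) and the oracle suites at 500 random interval instances on
10 kb genomes and 200 random score vectors of N ≤ 500 — sizes chosen so a
full from-scratch run completes in a few seconds on one core while still
exercising every code path at non-trivial n.

## Known limitations

* Exon-aware intronic classification, GTF/GFF parsing, BAM read counting
  and liftover are out of scope; gene models come from a minimal TSV/BED6.
* The SE scoring normalisation is a declared reconstruction of the
  reference behaviour; published absolute SE counts are not reproduced
  here and depend on upstream processing.
* The nearest-gene step reports all ties; pipelines that keep exactly one
  gene per feature will differ at equidistant loci.
* The synthetic benchmark certifies correctness under planted separation,
  not statistical power on real chromatin landscapes.
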