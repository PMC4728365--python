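# Methods

This note documents the models, parameter choices and numerical conventions
behind `occupeak`, and what the synthetic-data tests do and do not
demonstrate about real data.

## Coordinates and interval algebra

All coordinates are 0-based half-open (BED convention); 1-based inputs are
out of scope.  Book-ended intervals ([a,b), [b,c)) merge at gap 0, matching
the default behaviour of the common interval tools, and "coincidence"
between two intervals always means at least one shared base — the loosest
defensible definition, chosen because tighter minimum-overlap rules are a
parameter (`min_overlap`) rather than a different code path.
Nearest-point ties break toward the smaller genomic coordinate so results
are reproducible across runs and platforms.

## Tag model and fragment shift

A tag is a 36-nt single-end read whose 5' end marks one boundary of a
sonicated chromatin fragment.  Fragments bracket the protein's site, so
forward-strand 5' ends pile up upstream and reverse-strand 5' ends
downstream of it, separated by roughly the fragment length.  The shift *d*
between the two pileups is estimated by maximizing the Pearson correlation
between the forward 5'-end count profile and the reverse profile shifted
left by *s* over *s* in [0, `max_shift`]; cross-products are computed by
FFT and the correlation uses whole-chromosome moments (the error from
ignoring the *s*-base truncation is O(s/L)).  A maximum correlation below
0.1 flags the estimate as unreliable, in which case callers fall back to a
conventional 150 bp.  With the sonication-range fragments (500–1000 bp)
the true shift is ~700 bp, which is why `max_shift` defaults to 1200.

## The three callers

Shared defaults (none dictated by the emulated protocol; all follow the
spirit of the published tools this trio stands in for): read length 36,
window *w* = 300 bp for the poisson and threshold callers, *w* = 20 bp for
the strand-transition caller, Poisson cutoff 1e-5, fold cutoff *E* = 2,
minimum tags *R* = 10, minimum run *m* = 50 bp.  Depth scaling between
lanes is linear in total tag count; duplicate-read filtering is omitted
because the generator emits no PCR duplicates.

**poisson.**  Treatment tags are shifted *d*/2 toward 3'; windows of width
*w* step *w*/2.  A window with count *c* is significant when
P(X ≥ c; lambda_local) < cutoff, with
lambda_local = max(lambda_genome, lambda_5kb, lambda_10kb) computed from
control tag counts centred on the window and scaled by the treatment/control
depth ratio.  The 1 kb local window used by some callers is omitted: at
desk-scale control depth a 1 kb window holds so few control tags that its
rate estimate is mostly noise.  Control tags are counted unshifted.
Overlapping significant windows merge; the score is the best window's
−log10 p and the summit the maximum of the shifted-tag pileup (ties toward
the smaller coordinate).  Because the local lambda rises inside any region
enriched in the control, copy-number gains present in both lanes are not
called — this is tested explicitly.

**strand_transition.**  Net counts (forward − reverse 5' ends) are
tabulated in non-overlapping 20 bp windows; a candidate site sits at each
positive-to-negative sign transition, windows without tags carrying no
sign.  A candidate is retained when at least *R* treatment tags lie within
±*w* of it and the fold enrichment over the depth-scaled control in that
span is ≥ *E*; the control count is floored at its genome-wide expectation
for the span so empty control windows do not produce infinite folds.
Candidates closer than 2*w* merge keeping the higher-tag one — 2*w* rather
than *w* because peaks span [t−w, t+w) and transitions between *w* and 2*w*
apart would otherwise yield overlapping peaks, violating the within-caller
disjointness invariant.

**threshold.**  Tags are extended to the fragment length (2*d*) toward 3';
maximal runs of at least *m* bases with coverage ≥ *E* × the genome-mean
coverage become peaks when the depth-scaled treatment/control coverage
ratio over the run is also ≥ *E* (control coverage floored at its genome
mean times the run length).  This is an explicit surrogate for manual track
inspection, not a reconstruction of it: the original manual criteria are
not quantifiable.

## Consensus

Cross-method identity is single-linkage: peaks from any callers overlapping
by ≥1 bp belong to one cluster, transitively.  For intervals this closure
is exactly what a coordinate sweep computes, so clustering is deterministic
and order-independent; a brute-force graph-closure oracle confirms it in
tests.  A cluster's interval is the union span of its members —
conservative for downstream overlap queries, where peaks are treated as
regions of occupancy.  Venn regions are counted per cluster (not per
original peak); tiers are selected by minimum support and nest by
construction.

## Annotation

The six gene-relative categories use strand-aware windows: promoter = 5 kb
upstream of the TSS, downstream = 5 kb past the transcript end, the
±100 kb neighbourhoods measured beyond those 5 kb windows, gene desert =
more than 100 kb from any gene.  A peak qualifies for a category when its
full interval overlaps the window by ≥1 bp; because a peak can qualify for
several categories (e.g. straddling a TSS), a fixed precedence —
intragenic first, then promoter, downstream, far-upstream, far-downstream —
makes the labels exclusive and the fractions sum to 1.  TSS distances use
the peak midpoint (summit- or edge-based conventions are equally
defensible; midpoint needs no caller-specific information), signed negative
upstream in the gene's orientation, nearest TSS by absolute distance with
ties toward the smaller coordinate.  The assigned gene is the
nearest-TSS gene among those qualifying for the winning category.
Chromosome density reports Pearson r of count vs length when ≥3
chromosomes are available and both variables vary; a constant count (or
length) is reported as r = 0 — no linear association — rather than NaN.

## Coincidence

Fractions are interval-level in both directions: a peak overlapping two
track intervals counts once, and conversely.  Percent values are reported
to 2 decimal places.  The track's genome fraction (merged coverage /
genome length) supports over/under-representation ratios, e.g. against the
~1.5% of the genome covered by CpG islands.  Between-condition comparisons
are descriptive (fold change and difference of the peak-level fraction);
no significance test is attached, matching the analysis this pipeline
reproduces.

## Motif scanning and p-values

Scores are log-likelihood ratios in bits against the background base
composition, with a pseudocount of 1e-4 per matrix cell.  Scores are
discretized to a 1/1000-bit integer grid at scan time *and* when building
the null distribution, so the dynamic-programming tail probability
P(score ≥ s) for a random background width-mer is exact on the grid —
full 4^w enumeration agrees to ≤1e-9 for widths up to 8 in the tests.  The
minus strand is scanned by scoring the reverse-complement matrix on the
forward sequence, so palindromic instances produce hits on both strands at
the same interval and reverse-complementing the genome mirrors hits
exactly.  Windows containing N are skipped.  The default occurrence cutoff
is p < 1e-4, the published default of the scanner this emulates.

Enrichment units are scannable window start positions on both strands:
N = 2·Σ(chromosome length − width + 1) genome-wide, n the same count
restricted to peak intervals, K and k the occurrence counts.  Overlapping
occurrences of one motif count separately (no greedy masking), keeping the
units consistent and the test deterministic.  BH correction runs across
all motifs tested, with significance at q < 0.05.

## Gene-set enrichment and clustering

The universe is the full gene annotation table.  Terms with no selected
gene are not tested — they cannot be enriched and would only inflate the
correction burden.  The hypergeometric upper tail is evaluated in log
space via the scipy survival function; an exact rational-arithmetic
summation serves as the test oracle.  BH-adjusted values use the step-up
algorithm; significance at q < 0.01 for gene sets.  Binary profiles
(genes × motifs) cluster under Jaccard distance (two all-zero vectors at
distance 0) with the Lance–Williams Ward update applied to those distances
as if Euclidean — a documented approximation, standard for binary
attributes — and lexicographic tie-breaks for a deterministic dendrogram.

## The synthetic-data generator

The generator reproduces the statistical structure the analysis assumes,
not sequencing chemistry.  Per planted site, a Poisson-distributed budget
of fragments (length Uniform(500, 1000) bp — the sonication range of the
emulated protocol — centre jittered Normal(0, 50 bp)) each sheds one 36-nt
tag from a uniformly chosen end, producing the forward-upstream /
reverse-downstream asymmetry the callers exploit.  Background tags are
uniform on both strands; the input control is uniform background; declared
copy-number segments multiply the local background rate in both lanes.
Gene models are non-overlapping with random strands; CpG islands cover
half the TSSs plus random background up to ~1.5% of the genome; mark
tracks cover each site's neighbourhood with a configurable probability.
Motif instances are the PWM consensus written within ±50 bp of a
configurable fraction of sites.  Everything derives from one seed through
named substreams, so the full output set is byte-reproducible.

Two presets define the study conditions.  `sonication` (the default) keeps
the 500–1000 bp fragment range, a deliberately faithful stress case that
pushes the strand shift to ~700 bp.  `strong` is the conventional easy
case — fragments 100–200 bp, ~150 tags per site, 0.2 background tags/kb,
1 control tag/kb — used for the parameter-recovery checks (recall and
precision ≥0.9 per caller against planted sites, ≥1 bp overlap matching).
The strand-transition caller's tag-count gate (±20 bp of the transition)
cannot fire when fragment ends sit 250–500 bp from the site, so the
recovery floor is asserted under the `strong` conditions, where the gate
is meaningful.

What the generator does **not** model: sequencing errors, PCR duplicates,
mappability, GC bias, diploid genotypes, or correlated background.  Passing
recovery tests therefore show the callers implement their stated decision
rules correctly under their own assumptions — not that those rules are
robust to real-data artefacts.

## Problem sizes and tolerances

Default desk-scale conditions are 3 chromosomes × 300 kb, 30 sites,
30 genes; the acceptance study, the recovery tests and the full pipeline
run in seconds at this size, and the generator scales linearly for larger
studies.  Statistical checks use 200 seeded null replicates for the
false-discovery control (observed rate ≤5%) and exact oracles elsewhere:
rational-arithmetic hypergeometric sums (N ≤ 10^4), 4^w enumerations
(w ≤ 8, agreement ≤1e-9), per-base boolean coverage for interval algebra,
and an independent Ward agglomeration for dendrogram heights (≤1e-10).

## Known limitations

* The three callers are simplified stand-ins; they are not bit-faithful to
  the published tools they echo and omit paired-end support, duplicate
  filtering and broad-domain calling.
* Ward on Jaccard distances is not variance-minimizing in a Euclidean
  sense; it is used as a deterministic convention, as is common for binary
  attributes.
* The motif-enrichment sampling unit (scan start positions) differs from
  per-peak or per-base alternatives; ratios between motifs are comparable,
  absolute p-values depend on this choice.
* Genome-scale published counts (tens of thousands of peaks, specific
  enriched-motif tallies) depend on real data, a full genome and external
  databases, and are not reproducible at desk scale; the package instead
  verifies the printed worked-example ratios exactly and all structural
  and statistical properties on synthetic data.
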