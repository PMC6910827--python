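# Methods

## System and signal model

The analysis targets an experimental design in which one donor
chromosome of a distinct haplotype is transferred into a diploid
acceptor line (microcell-mediated chromosome transfer), producing a
trisomic — occasionally tetrasomic — clone. Passage through a
micronucleus can shatter the transferred homolog or rearrange it
replicatively; the endogenous homolog pair is untouched. Three signal
layers carry the evidence:

1. **Total copy number**: binned quantal values (~2 at disomy, 3 on an
   intact trisomic chromosome). A deleted transferred fragment reads 2
   on the trisomic chromosome; a duplicated one reads 4.
2. **Allelic ratios**: at SNPs where the parental line is homozygous and
   the transferred homolog carries the other allele, the B-allele
   frequency (BAF) is 1/3 or 2/3 at trisomic baseline and moves in
   genotype-specific directions under loss or gain of either homolog.
3. **Junction sequence**: assembled breakpoint contigs whose orientation
   classes, microhomology, and insertions discriminate end-joining
   repair of shattered fragments from replicative template switching.

## Copy-number calling

Quantal values on the aneuploid chromosome are corrected by subtracting
1 (2 for a tetrasomy, via `aneuploid_correction`), so every chromosome
is judged against the same disomic-equivalent thresholds: strict
quantal < 1.5 for loss and > 2.5 for gain; segments in between are
neutral and never emitted. Runs of ≥ 2 consecutive same-state calls on
one chromosome are merged when their summed segment lengths exceed 90%
of the run's total span (first start to last end, gaps counting against
coverage, strictly greater). Merging is greedy left-to-right, taking
the longest qualifying extension, repeated to a fixpoint; the merged
quantal is the length-weighted mean. Interpretation choices made here:
"similar quantal values" is operationalized as state identity
(loss-with-loss, gain-with-gain), and span coverage counts segment
bases only. A consequence worth knowing: a neutral island smaller than
10% of the span between two large same-state calls is absorbed by the
rule — tests therefore compare pipeline output against the *rule
applied to exact truth*, not raw truth intervals.

Calls must exceed 100 kb (strict). Uniqueness (*de novo* status) is
decided by reciprocal overlap — min of the two mutual coverage
fractions, the dominant CNV-literature convention — strictly below 0.70
against every call of every other clone from the same parental line and
of the parental line itself; a call is never compared against its own
clone's calls.

## Haplotype assignment

Phase-informative SNPs are discovered by comparing the parental line
(BAF < 0.05 or > 0.95, homozygous) with an *unrearranged* aneuploid
sample whose BAF lies within ±0.12 of the aneuploid heterozygote
baseline (1/3 or 2/3 for trisomy; computed from allele counts in
general, so tetrasomic baselines need no special casing). Discovery
deliberately uses the unrearranged baseline: inside a CNA of the
rearranged clone, the BAF shift *is* the downstream signal, and
selecting on it would discard exactly the informative sites.

Within a CNA, each informative SNP votes. For a loss: BAF at or beyond
the 0.15/0.85 shift bounds on the parental-homozygote side votes
*transferred* (AAB→AA); BAF within ±0.08 of 0.5 votes *endogenous*
(AAB→AB). For a gain: BAF within ±0.08 of 0.5 votes *transferred*
(AAB→AABB); within ±0.08 of 1/4 or 3/4 votes *endogenous*
(AAB→AAAB/ABBB), the nearer target winning. The verdict needs at least
3 votes and a ≥ 2/3 majority; otherwise the call is *ambiguous* — the
aggregation degrades to "no call" rather than guessing, since the
per-interval decision rule behind curated calls is not otherwise
specified. Junctions are assigned from discordant read-pair allele
counts pooled over the junction's informative SNPs: a one-sided exact
binomial against p = 0.5 at α = 0.05 with ≥ 3 pairs; the exact test
replaces an informal unanimity criterion so small counts are handled
defensibly.

The A/B labeling is arbitrary: swapping labels flips every BAF to
1 − BAF, and all windows are symmetric, so verdicts are invariant
(property-tested).

## Junction forensics

Breakends carry a side: *tail* if the retained sequence runs toward
lower coordinates, *head* toward higher. On disk, BEDPE strand "+" maps
to tail and "−" to head, which makes a simple deletion a tail-head
junction, a tandem duplication head-tail, and an inversion one
head-head plus one tail-tail. Breakends are canonically ordered by
(chrom, pos, side) and the orientation label read off as
side(lower)–side(higher).

Microhomology is defined as junction-shift ambiguity: the number of
equivalent exact placements of the junction minus one. It is computed
from maximal anchored matches of the contig against breakend-centered
reference flanks (each flank's first half retained sequence, second
half the continuation past the breakend): the contig's left anchor is
its longest prefix equal to a suffix of the approach, extended across
the breakend; mirrored on the right. Overlapping extended anchors give
microhomology, a gap gives the insertion; when both a homology split
and an insertion split would be representable, the maximal-anchor rule
resolves it toward the smaller insertion. Matching is exact (mismatch
tolerance 0 by default); anchors below `min_anchor` (10 bp) flag the
contig unclassifiable. An insertion of ≥ 20 bp found verbatim (or
reverse-complemented) in the reference is templated, reported with its
source locus; ties go to the first locus by coordinate and are flagged.

The orientation spectrum counts junctions spanning > 10 kb (strict;
translocations always count) and is tested against uniform 25% per
class with the Pearson statistic, df = 3; for totals below 20 the
p-value is computed by full enumeration of the multinomial outcome
space, otherwise by the chi-square tail. Pooling across clones sums the
counts (a combined dataset, not combined p-values). The per-clone
hallmark report assembles junction counts by chromosome, orientation
classes present, copy-number oscillation statistics (transitions and
distinct states — more than two states being the replicative
signature), and the feature spectrum; it deliberately issues no binary
chromothripsis verdict.

## Enrichment statistics

Each observed *de novo* CNA is reassigned, independently per
permutation, to a chromosome with probability proportional to
length × copy number (the clone's aneuploid chromosome at 3 or 4, all
others at 2; `length_only` available for sensitivity). The statistic is
the count landing on the clone's own aneuploid chromosome; the
empirical p uses the add-one estimator so it is never zero. CNAs are
resampled as chromosome labels, not length-preserving placements — the
toy chromosomes dwarf every CNA, and a length-aware mode would change
nothing at these scales. Because the per-CNA landing indicators are
independent Bernoulli variables, the exact tail is Poisson-binomial;
`exact_enrichment_oracle` computes it by convolution and anchors the
permutation engine in tests (e.g. two equal chromosomes, one trisomic,
one observed CNA: p = 3/5 exactly).

Sizes of CNAs on the transferred versus other chromosomes are compared
with a two-sided Wilcoxon rank-sum test (the groups are unpaired),
exact enumeration when both groups have ≤ 10 untied observations,
normal approximation with tie correction otherwise; a fully tied
comparison reports p = 1.

## The simulator: what it emulates, and what it does not

`GenomeSpec` defaults: three 10 Mb chromosomes, SNPs every 5 kb, 30% of
SNPs informative on the trisomic chromosome (`chr2`), one transferred
copy. These give ≥ 10 informative SNPs per 100 kb CNA while keeping
every test desk-scale.

**Shattering** cuts the transferred homolog at k random breakpoints
(default minimum fragment 200 kb — real chromothripsis fragments span
tens of kb to Mb, and this keeps every true CNA above the 100 kb floor
and the 50 kb bin), deletes each fragment independently with the given
probability, and reassembles survivors in uniformly random order with
independent 50% inversion. Telomeric fragments, when retained, stay
pinned at the derived ends in original orientation, since no flanking
sequence exists beyond a chromosome end to form a junction against.
Restored original adjacencies produce no junction record.

**Chromoanasynthesis** plants tandem duplications/triplications of
well-separated segments (with ≥ 2 switches, one duplication and one
triplication are forced so the profile shows more than two states) and
gives the new junctions microhomology of 1–15 bp or templated
insertions of 50–200 bp copied from the transferred homolog.

**Feature planting** edits the synthetic reference so the
junction-adjacent bases on both reference sides are identical for
exactly the planted microhomology length, and boundary bases mismatch,
making the planted length the unique ground truth; insertion ends are
likewise guarded. Junctions that share a breakpoint with another
junction (possible under shattering when both neighbors of a cut
survive) are left unedited and their true lengths *measured* from the
final reference, so truth is consistent by construction in every case.
A dedicated `simulate_junction_corpus` generates isolated
deletion/duplication/inversion junctions with known orientation classes
for forensics benchmarks.

**Rendering.** SNP tables: BAF is the exact allele fraction of the
local copy configuration plus clipped Gaussian noise; LRR is
log2(total/2) plus noise; parental (disomic) and unrearranged-baseline
(trisomic) samples are rendered alongside the clone. Quantal segments:
truth boundaries snapped to the nearest bin edge (error ≤ half a bin),
value = true total copies plus noise. Junction records: contig =
retained approach + insertion + retained departure, flanks 300 bp by
default, always laid out from the canonical first breakend. Read
pairs: Poisson(coverage) discordant pairs per informative SNP near a
junction, each carrying the transferred allele mislabeled with the
given error rate; concordant pairs drawn per copy present.

A separate phasing panel (`simulate_cna_phasing_panel`) plants
deletions and duplications on the transferred *and* endogenous homologs
in equal numbers — the rearrangement simulators put every event on the
transferred homolog by construction, which exercises only one verdict.
The panel genome uses SNPs every 4 kb with 40% informative so that 100
CNAs each cover ≥ 5 informative SNPs, the evidence level at which the
accuracy guarantees are stated.

**Not emulated**: read-level data (FASTQ/BAM), sequencing error beyond
allele mislabeling, GC and mappability artifacts, segmentation noise
(segments are rendered at truth boundaries ± binning), mosaicism,
breakage-fusion-bridge cycles, and the donor-genome background. Passing
tests therefore demonstrate correctness of the calling, assignment,
forensics and statistics *given* well-formed segment/SNP/junction
inputs — not robustness to upstream artifacts those tools must handle.

## Numerical and testing choices

* Coordinates are 0-based half-open internally and on disk (BED/BEDPE);
  reports print 1-based inclusive. SNP array conventions vary, so the
  package fixes one rather than guessing.
* All thresholds are strict inequalities, read literally from their
  definitions ("< 1.5", "> 2.5", "> 100 kb", "> 90%", "< 70%").
* Degenerate inputs have defined behavior: empty spectra raise for the
  multinomial test, zero informative SNPs yield ambiguous with
  n_total = 0, all-fragment-deletion shattering retries then raises,
  `informative_fraction = 0` is rejected at construction (phasing would
  be untestable).
* The permutation engine draws in blocks bounded at ~10⁶ Bernoulli
  variables to cap memory; p-values are deterministic given the config
  seed.
* Type-I calibration of the permutation test is checked against its own
  null on 200 datasets with randomized 5-chromosome genomes and 100–300
  CNAs each. The dataset sizes matter: the statistic is discrete, so
  its empirical p-values are intrinsically conservative, and with few
  CNAs per dataset the attainable p grid is coarse enough that a
  uniformity test detects the discreteness itself. At the chosen scale
  the grid is fine and the Kolmogorov–Smirnov check is a meaningful
  test of calibration rather than of granularity.
* Problem sizes in tests and the acceptance script (10 Mb chromosomes,
  k = 20 breakpoints, 100-CNA panels, 500-junction corpus, 10⁵–10⁶
  permutations) were chosen as the smallest scales at which every
  property is exercised with comfortable statistical margins.

## Known limitations

* Microhomology with simultaneous non-templated insertion at one
  junction is not planted by default (truth would be ambiguous); the
  classifier itself reports whichever the maximal-anchor rule supports.
* The exact multinomial enumeration is practical only for small totals
  (default threshold 20; the outcome space grows as C(n+3, 3)).
* `find_phase_informative_snps` requires a baseline aneuploid sample;
  using the rearranged clone as its own baseline silently drops
  informative SNPs inside CNAs (documented in the function).
* The permutation null treats CNAs as exchangeable points; length- and
  gene-density-stratified nulls are out of scope.
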