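# Methods

msatkit implements the standard development path for microsatellite markers
in a non-model organism: find perfect short sequence repeats (SSRs) in
shotgun reads, screen the candidate loci whose primers behave like
single-copy sequence, turn raw capillary fragment sizes into discrete allele
bins, and characterize each scorable locus with the usual population-genetic
statistics. A set of ground-truthed simulators reproduces the statistical
structure of each stage's input so the whole pipeline is testable end to end
without any sequencing data.

## Repeat discovery

A motif is a primitive DNA word of length 2–6 (its length is the "kmer":
dimer … hexamer); primitivity means the word is not a whole-number repetition
of a shorter word, so `ATAT` is not a motif — it is two units of `AT`. Motif
classes are named by the canonical representative: the lexicographically
smallest string among all cyclic rotations of the motif and of its reverse
complement. This makes naming phase- and strand-invariant (`TG`, `GT`, `CA`
and `AC` are all "AC"), which is what one needs to tabulate repeat
composition across reads sequenced from either strand.

The scanner reports every maximal perfect run: position `j` is compared with
position `j − k`; a maximal stretch of `L` consecutive matches spans `L + k`
bases and hence `⌊(L+k)/k⌋` whole units. A run is emitted when the unit
count reaches the per-kmer minimum and its leading k-mer is primitive — the
primitivity requirement is also what prevents an `(AC)×8` run from being
re-reported as a reducible 4- or 6-mer. `N` breaks a run; there is no
IUPAC-ambiguity matching and no tolerance for interruptions (imperfect and
compound repeats are deliberately out of scope). When calls at different
kmers cover the identical interval only the smallest kmer is kept.

Default minimum units are {2: 8, 3: 6, 4: 4, 5: 4, 6: 4}. These are an
explicit, overridable assumption (`RunConfig.min_units`): marker-development
pipelines in this field use thresholds of roughly this size so that a repeat
is long enough to be polymorphic but short enough to be common, and the
defaults sit in that conventional range. The scanner is verified against an
exhaustive oracle that tests every (start, kmer, units) triple on random
reads, and against planted repeats with exact coordinates.

## PAL screening

A potentially amplifiable locus (PAL) is an SSR with a designed primer pair.
The occurrence count of each primer in the raw read pool is a cheap proxy
for copy number: a count below `min_count` (default 2) suggests the primer
sequence carries sequencing error; a count above the genome coverage
suggests the primer region is repeated in the genome and would co-amplify
several loci. Counting is exact-match, both orientations, overlapping
occurrences included, over all reads pooled — the most reproducible reading
of an occurrence count (mismatch-tolerant counting would need an error model
the data cannot support). A reverse-complement-palindromic primer is counted
once per position.

Genome coverage is estimated from read depths over a panel of single-copy
gene fragments: the median depth per gene, then the grand median over genes
(reported with the min and max of the per-gene medians). Medians rather than
means keep mapping pile-ups from inflating the estimate. The upper filter
bound defaults to the grand median rounded half-up. Both filter bounds are
inclusive: a locus is kept iff both primers occur between `min_count` and
`max_count` times. Genes with zero depth everywhere are treated as uncovered
and excluded from both the gene count and the grand median.

## Allele binning

Capillary electrophoresis reports fragment sizes as fractional base pairs
while true alleles differ by whole repeat units. Visual histogram binning is
replaced by an explicit rule so the decision is reproducible: sizes are
sorted and clustered single-linkage, a new bin starting whenever the gap
exceeds `gap_factor × motif_len` (default gap_factor 0.5, i.e. half a repeat
unit). The bin label is the round-half-up of the bin's median size; labels
are integers because reported allele ranges are integers.

"Bins could not be clearly assigned" is quantified by the ambiguity score:
the number of adjacent bin pairs whose label spacing is not a positive whole
multiple of the repeat unit, plus the number of bins whose internal spread
exceeds `motif_len − 1`, divided by the number of bins. A locus whose score
exceeds `ambiguity_threshold` (default 0.25, a tool choice) is excluded from
characterization — the algorithmic analogue of dropping a locus whose size
histogram is a smear. Genotype assignment maps each peak to the bin
containing it (bins are padded by half the gap threshold, clipped at the
midpoint to the neighbouring bin); a single peak is a homozygote (the
fragment-analysis convention — note this convention interacts with null
alleles, since a true null heterozygote also presents one peak), and a peak
outside all bins voids the call and is tallied.

One numerical caveat, found while validating the round-trip: exact recovery
of simulated genotypes is a theorem only when every jittered size stays
within 0.5 bp of its label (jitter ≤ motif_len/8 for a tetramer). At larger
jitter — still below the quarter-unit separation needed for clean
clustering — a sparsely populated bin's median can legitimately round to a
neighbouring integer. The round-trip tests therefore run at motif_len/8,
where recovery is guaranteed for every seed rather than merely likely.

## Locus characterization

All statistics are computed from complete genotypes only (missing calls
excluded from numerator and denominator alike).

* **Observed heterozygosity** Ho: fraction of genotyped individuals with two
  distinct alleles.
* **Expected heterozygosity** He: Nei's unbiased estimator
  `2n/(2n−1) · (1 − Σ p_i²)`, which equals the probability that two allele
  copies drawn without replacement from the sample differ (verified by
  exhaustive pair enumeration to 1e−12). The uncorrected `1 − Σ p_i²` is
  available behind a flag.
* **Hardy–Weinberg test**: Pearson chi-square of genotype-class counts
  against HWE expectations (`n p_i²` and `2n p_i p_j`), with a Monte-Carlo
  null built from B (default 1999) random re-pairings of the pooled allele
  copies; `p = (1 + #{permuted ≥ observed})/(B + 1)`, bit-reproducible for a
  fixed seed. Monomorphic loci return p = 1 by convention and join the
  multiple-testing adjustment only on request.
* **Multiple-testing adjustment** across loci: Holm step-down by default,
  Benjamini–Hochberg step-up available; the method is recorded in output
  metadata.
* **Null-allele frequency** (Brookfield estimator 1):
  `r = max(0, (He − Ho)/(1 + He))`, zero whenever Ho ≥ He. Rounding to the
  reporting precision happens only at write time.
* **Allelic richness** by rarefaction: `Σ_i [1 − C(N−N_i, g)/C(N, g)]`,
  computed via log-gamma. `g` defaults to twice the smallest per-locus
  complete sample size in the data set, the usual standardization when loci
  differ in missingness. Identities `A(N) = allele count` and `A(1) = 1`
  hold exactly and the general case is checked against exhaustive subsample
  enumeration.
* **Genotyping error rate**: fraction of individuals, among those complete
  in two replicate genotyping rounds, whose unordered allele pairs differ.
  The unit is the genotype, not the allele.

### Known limitation: Brookfield bias at high null frequency

Under the dropout model the simulator implements (null/null → missing,
null/visible → apparent homozygote, statistics on scored individuals), the
apparent allele frequencies equal the visible ones, so He estimates the
visible-allele heterozygosity H while Ho estimates `(1−r)H/(1+r)`. The
Brookfield estimate then has expectation

    E[r̂] = 2rH / ((1 + r)(1 + H)),

i.e. it is downward-biased, mildly for r ≤ 0.1 (≈ 0.086 at r = 0.1,
H = 0.9) and substantially at high null frequency (≈ 0.158 at r = 0.2,
≈ 0.219 at r = 0.3). Simulations reproduce the closed form to three
decimals. The consistent estimator under this exclusion model would be
Chakraborty's `(He − Ho)/(He + Ho)`, but Brookfield 1 is the estimator the
reported values derive from, so it is what the toolkit computes; the
recovery test documents the bias by failing at r ≥ 0.2 rather than hiding
it. Estimates of high null-allele frequencies should be read as
conservative lower bounds.

## Simulators

`simulate_reads` plants perfect repeats and primer sites in i.i.d.-uniform
background reads; any background draw that accidentally contains a primer
(either strand) or a repeat passing the configured thresholds is rejected
and re-drawn, and a planted read is re-drawn until it contains exactly the
planted feature. Truth records carry exact coordinates and copy numbers, so
downstream count assertions are exact, not probabilistic. `simulate_genotypes`
draws two allele copies per individual from visible frequencies scaled by
`(1 − null_freq)` plus a null allele, applies the dropout rules above, an
independent missingness rate, and an optional replicate round whose miscalls
(probability `miscall_rate`) always change the unordered pair, so the
replicate discordance estimates the miscall rate directly.
`simulate_peaks` emits each allele as label + Uniform(−jitter, +jitter),
one peak for homozygotes.

What the simulators deliberately do not model: sequencing error within
planted features, PCR stutter, dye-dependent size shifts, allele dropout
correlated with fragment length, and linkage between loci. Passing tests
therefore demonstrate algorithmic correctness under the stated statistical
model, not robustness to every artefact of real capillary data.

One master seed drives a named random stream per component
(SeedSequence keyed by seed and stream name), so outputs are byte-identical
across runs and adding a new stream never perturbs existing ones. Every
output file starts with a comment header recording the tool version, a
configuration hash and the seed.

## Problem sizes used in the test battery

Oracle equivalence of the scanner runs on 1,000 random reads of up to
200 bp; HWE p-value uniformity uses 500 simulated loci of 50 individuals at
B = 199 permutations (Kolmogorov–Smirnov at α = 0.01); Brookfield recovery
averages 200 replicate loci of 200 individuals per null frequency;
error-rate recovery uses 500 individuals. These sizes keep each
distributional check's own Monte-Carlo error well below the tolerance it
asserts.
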