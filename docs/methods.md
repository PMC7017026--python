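# Methods

## Model of the signal

On an inbred recipient background, every true variant call is expected to be
homozygous (reference or alternate). A donor-derived segment retained
through backcrossing is present in one copy, so across it the caller reports
a dense run of *heterozygous non-reference* SNPs. The scan treats
chromosome-wide heterozygous-SNP density as the test signal and makes no use
of read-level evidence: alignment and variant calling are upstream of this
package, which starts from a single-sample VCF.

A real introgressed region is not uniformly heterozygous. Successive rounds
of backcross recombination leave a mosaic: heterozygous blocks interleaved
with blocks returned to recipient homozygosity, and — because inbred-strain
haplotypes share identity-by-descent tracts — multi-megabase stretches
inside heterozygous blocks that carry no variants at all. The segment caller
is therefore a run-bridging scheme rather than a changepoint model.

## Discovery procedure and parameters

1. **Quality filter.** Remove calls that failed the caller's internal status
   check (FILTER ≠ PASS) or have per-site mapping quality below
   `mq_threshold` (default **200**, strict less-than; missing scores never
   pass). The filter is monotone in the threshold. Note that different
   callers expose differently named per-site scores (mapping quality,
   base-quality aggregates); this package treats INFO/MQ as *the* per-site
   score and leaves the choice of which caller field to export there to the
   user.
2. **Zygosity selection.** Keep heterozygous calls only; homozygous and
   missing genotypes are uninformative for introgression on an inbred
   background.
3. **Windowed density.** Count calls in non-overlapping windows of
   `window_size` (default **1 Mb**) on a fixed grid anchored at bp 1, last
   partial window included. Window counts conserve the number of input
   calls per chromosome.
4. **Segment calling.** Windows with at least `min_snps_per_window`
   (default **5**) calls are dense; maximal runs of dense windows are
   segments, allowing up to `max_gap_windows` (default **5**) consecutive
   below-threshold windows inside a run. Segment boundaries are then
   trimmed to the first/last supporting SNP, giving sub-window resolution.
   Runs spanning fewer than `min_segment_windows` (default **3**) windows
   are classified `artifact_candidate` and reported with their mean mapping
   quality for triage; the rest are `introgressed`.
5. **Devoid gaps.** Inside a segment, maximal call-free intervals of width
   ≥ `min_gap_bp` (default 1 Mb) are reported widest-first.

Parameter rationale. `min_snps_per_window = 5` separates true-segment
windows (hundreds of calls at the default simulated density) from
error-scale clusters (1–5 sites) by a wide margin on both sides.
`max_gap_windows = 5` is chosen so that a backcross mosaic stays one
segment: reference-homozygous blocks of a few Mb and devoid stretches up to
~5 Mb produce at most five consecutive empty windows and must not split the
region, while genuinely separate clusters tens of Mb apart still do.
`min_segment_windows = 3` declares anything shorter than ~3 Mb a triage
candidate rather than a region. All three are exposed in `ScanParams` and
on the CLI; none is fitted from data.

## Synthetic-data generator

The generator emulates the *call set* of one congenic individual, not reads
or alignments. Its default truth plants:

* a mosaic on chromosome 13 spanning **38.2–75.7 Mb**: four heterozygous
  blocks separated by three reference-homozygous blocks of 1–1.5 Mb;
* one **4.5 Mb** variant-devoid gap (49.55–54.05 Mb, centered on 51.8 Mb)
  inside the second heterozygous block;
* a **private-site region at 60–70 Mb** whose alleles no panel strain
  carries;
* artifact clusters (Poisson, default 20 per genome, 1–5 sites within
  500 bp) placed uniformly outside heterozygous blocks, emulating
  sequence-context errors and colony drift;
* a simulated genome of chromosomes 1, 4 and 13 at mm10 lengths — enough
  territory for artifact scatter without simulating all autosomes.

Positions inside heterozygous blocks are a homogeneous Poisson process at
`het_site_rate` (default **1000 sites/Mb**, the order of SNP density between
divergent inbred mouse haplotypes; the density is not identifiable from the
package's own use cases, so it is set once here and documented). Mapping
qualities come from a two-component model — true sites N(700, 120²),
artifact sites N(150, 80²), clipped to [0, 1000] and rounded — with
status-pass probabilities 0.98 and 0.5. This makes the default filter
meaningful: essentially all true sites survive; most artifact sites do not.

The 36-strain panel covers every introgression-origin site: each strain
carries each non-private allele with a per-strain sharing probability
(defaults: BALB/cJ 0.85, C57BL/6NJ 0.02, wild-derived strains 0.15, other
classical strains 0.35–0.65), reflecting that classical-strain haplotypes
are widely shared while the two B6 substrains are outliers in a region
divergent from the B6 reference. A site's truth label is the *realized*
panel state (private iff no strain drew the allele), so downstream
classification can be tested for exact agreement.

Phenotype cohorts draw sex per animal (defaults: p(female) = 0.725 for
non-carriers versus 0.30 for carriers of the protective region, 150 animals
per genotype — colony-scale numbers) and a gonad category from
{O, Ot, ot, oT, T} per genotype, with no normal testes in either genotype
by default. qPCR tables put the planted expression ratio into the target
gene's Ct: Ct_target = Ct_ref_mean + offset − log2(expression) + noise; the
last group listed is the calibrator.

What the generator does *not* model: read-level error structure, linkage
between neighboring sites, real recombination maps or pedigrees, copy-number
artifacts, qPCR efficiency deviations from 2.0. Passing recovery tests
therefore demonstrate the correctness of the analysis logic under the
stated sampling model, not robustness to every real-data pathology.

## Randomness and determinism

Every generator derives its own named stream from one integer seed
(`numpy` `SeedSequence` spawn keys), so each output is reproducible
independently. Identical config + seed gives byte-identical files; pipeline
manifests record parameters, package version and input SHA-256 checksums
and deliberately contain no timestamps or absolute paths.

## Exact tests

`fisher_exact` implements the point-probability two-sided convention: the
p-value is the total conditional probability (margins fixed) of tables
whose probability does not exceed the observed table's. For 2×2 this is the
classical Fisher test (hypergeometric summation over the free cell); for
R×C it is the Freeman–Halton extension by full enumeration, capped at grand
total 200 (beyond that `monte_carlo_exact` samples margin-fixed tables via
`scipy.stats.random_table` and applies the same criterion with an add-one
correction and a Clopper–Pearson interval). Probability ties — exact in the
underlying rationals — are resolved in integer arithmetic (comparing
products of cell factorials), never by floating-point grace factors, so
p-values are invariant under row/column permutation to the last bit. The
test suite checks the implementation against an independent exact-rational
enumeration oracle, against scipy's 2×2 implementation, and against R's
`fisher.test` for R×C tables.

Gonad-category comparisons are tested as full 2×C tables rather than
collapsed 2×2 dichotomies, since the biology of partial sex reversal is
ordinal-categorical. Cell counts at colony scale (total 300) exceed the
enumeration cap, so the pipeline's consolidated report uses the Monte-Carlo
mode there and says so in its output.

A note on test size: Fisher's conditional test is discrete and therefore
conservative at small sample sizes. A design calculation (exact summation
over binomial nulls) gives unconditional size 0.031 at n = 50/group and
0.045 at n = 300/group with a balanced sex ratio; the null-calibration
check in the test suite accordingly simulates cohorts of 300 per genotype
at p(female) = 0.5, where the test's size is close to nominal.

`welch_t` delegates to `scipy.stats.ttest_ind(equal_var=False)` and handles
the degenerate both-variances-zero case explicitly (p = 1 for equal means,
p = 0 otherwise). `ddct_fold_change` averages ΔCt on the cycle scale before
exponentiating (the standard Livak–Schmittgen procedure), returns
per-sample relative quantities 2^(−ΔΔCt) for plotting and t-tests, and is
an exact inverse of the qPCR generator in the zero-noise limit. No
multiple-testing correction is applied; the report lists raw p-values.

## Marker genotyping

Region genotype is derived from a panel of diagnostic SNPs (default nine
loci spread across the region): all informative markers heterozygous →
`var/+`, all homozygous-alternate → `var/var`, all homozygous-reference →
`+/+`. Any mixed pattern is reported as `discordant` — a possible
recombinant — and deliberately never resolved by majority vote, because a
wrong automatic resolution would silently misgenotype recombinant animals.

## Numerical and degenerate-input choices

* Coordinates: 1-based inclusive internally (VCF convention); BED output and
  planted-truth intervals 0-based half-open; conversions only at format
  boundaries, asserted by round-trip tests.
* Missing mapping quality: retained on read (flagged, logged), removed by
  the quality filter.
* Segment ties (equal length) resolve to the lower start; strain-similarity
  ties resolve alphabetically; densest-span ties resolve to the smallest
  start.
* An empty call set or a VCF with zero heterozygous calls yields an empty
  segment set and a success exit with a warning, not an error.
* A single-SNP artifact cluster yields a degenerate one-bp segment
  (start = end), kept so its call appears in triage reports.

## Problem sizes used in the shipped experiments

The recovery experiments run at the generator's default scale — a ~470 Mb
three-chromosome genome, ~37,500 heterozygous sites, a 36 × ~33,000 panel —
which gives sub-second single runs; replicated checks use 100 seeds
(segment recovery, artifact triage, fold-change recovery), 2,000 cohorts
(test size) and exhaustive small-table sweeps (46,375 2×2 tables plus 2×4
tables enumerated exhaustively to total 8 and sampled to total 30).

## Known limitations

* Density segmentation with fixed thresholds, not an HMM/changepoint model;
  boundary precision is limited by local SNP density at the segment ends.
* Provenance is per-site sharing, not haplotype matching: a strain can rank
  first in allele sharing without being the actual donor, and phylogenetic
  inference among strains is out of scope.
* The enumeration cap (total ≤ 200) for R×C exact tests is conservative;
  very unbalanced margins below the cap can still be slow.
* Single-sample VCFs only; indels, structural variants and multi-sample
  designs are out of scope, as are copy-number signals from read depth.
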