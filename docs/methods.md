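# Methods

This note records the models, parameter choices and numerical conventions
behind `ampccs`, and what the synthetic-data tests do and do not
demonstrate about real sequencing data.

## Problem setting

Each sample is a 1–5 kb PCR amplicon tagged during amplification with a
unique pair of 16-nt barcodes (forward at the 5′ end, reverse-complemented
reverse barcode at the 3′ end), pooled with hundreds of other samples into
a single single-molecule sequencing library. Sequencing reads each
circularized molecule several times; the per-pass error rate is high
(10–15 %, overwhelmingly 1-nt indels) but multi-pass consensus (CCS)
reads suppress random error to the sub-percent level. Every CCS read spans
its whole amplicon, so read-level analysis suffices: the causative
mutation of a mutant appears in essentially every read of its bin, SNP
phase is read directly off each molecule, and heteroduplex
(strand-exchange) tracts appear as contiguous runs of donor alleles.

## Demultiplexing

A read is assigned to pair F×R when the forward barcode matches at ≥ 12 of
its 16 positions near the 5′ terminus and the reverse barcode likewise at
the 3′ terminus (equivalently at the 5′ end of the reverse-complemented
read), in at least one read orientation. Candidate offsets come from two
sources: exact hits of any of the five 12-nt barcode windows within the
terminal span, and a direct scan of every offset in the span. The direct
scan makes the prescreen complete — any qualifying placement is found even
if every 12-mer window is disrupted — so the window stage is purely an
acceleration. Parameters:

* `min_matches` = 12 of 16. The binomial chance of a random 16-mer
  matching a given barcode at ≥ 12 positions is ≈ 6 × 10⁻⁵ per offset;
  with well-separated barcode sets (pairwise Hamming ≥ 8, enforced by the
  synthetic barcode generator) cross-talk between barcodes is impossible
  at this threshold (a read within 4 mismatches of one barcode is ≥ 4 away
  from every other).
* `search_span` = 50 nt from each terminus. Barcodes sit at the termini by
  construction; bounding the search prevents spurious internal hits on
  long amplicons. The bound leaves room for a few junk bases ahead of the
  barcode, which are trimmed away with it.
* Reads qualifying for two or more pairs are binned as
  unassigned/ambiguous rather than given to the best match: a conservative
  choice that protects downstream variant calls from cross-sample
  contamination. With distance-separated barcode sets this path is
  essentially never taken.

Trimming removes everything up to and including each matched barcode
placement and orientation-normalizes the insert (forward barcode 5′).

## Alignment

Trimmed inserts are aligned end-to-end by affine-gap dynamic programming
in the "fitting" regime: the read is consumed entirely; reference overhang
at either end is free. This differs from a strictly global alignment only
when trimming leaves terminal slack, which must not be forced into the
alignment as spurious indels. Scoring defaults: match +2, mismatch −4,
gap open −6, gap extend −1, with a gap of length k costing
`open + (k−1)·extend`. Both the read and its reverse complement are
scored; the better strand is kept (ties to +).

The DP is computed row-wise with numpy; the within-row (deletion) state is
resolved by a prefix-scan identity that is exact whenever
`gap_open ≤ gap_extend`, which the scoring-scheme invariant guarantees.
Traceback tie-breaking is fixed (diagonal ≻ deletion ≻ insertion, leftmost
optimal end column), so CIGARs are reproducible; indel placement inside a
repeat is therefore a deterministic convention, and tests that compare
indel positions do so by sequence equivalence, not coordinates. The
optional `band` parameter is a contract check on the optimal path's
diagonal excursion — the implementation always computes the unbanded
optimum and raises (never silently truncates) if the path leaves the band.

`=`/`X` are kept distinct internally; SAM output collapses them to `M`
for tool compatibility.

## Variant calling and mutation classes

Pileup columns tally A/C/G/T/N, deleted columns, and insertion events
anchored to the preceding reference position; column depth equals the sum
of base and deletion tallies by construction. Calling is threshold-based
— appropriate for amplicon bins where the residual consensus error
(~0.2 %) is far below any real allele fraction of interest:

* report an alternate allele at fraction ≥ 0.10 **and** count ≥ 5;
* homozygous-alt at fraction ≥ 0.90, else heterozygous (the reference
  allele then also passes the reporting floor in practice);
* adjacent deletion-qualifying columns merge into one deletion call whose
  support is the minimum per-column deletion count;
* insertion alleles are compared as exact sequences.

The 0.10 floor is calibrated so that the smallest heterozygous minor
fraction in the benchmark allele tables (8 of 73, ≈ 0.11) is reported
while consensus noise (≲ 0.01) is not. One benchmark cell (3 a + 70 G,
minor fraction ≈ 0.04) falls below the floor and is called
homozygous-alt; whether the original analysis treated it as heterozygous
is unknowable from the printed tallies, and the thresholds are exposed as
flags.

The causative mutation of a mutant bin is any call with fraction ≥ 0.80
("a real mutation in virtually every read"). Classes: single base
substitution; 1-bp indel; 2–5-bp deletion; large (≥ 6 bp) deletion;
complex when two or more causative calls cluster within 10 nt or mix
types. The 10-nt window is this package's operational definition of
"complex"; it is a reporting category, not a mechanistic claim.

## Error landscape

Pooling reads across many independent mutant bins, the per-position
base-substitution error frequency is (non-reference base calls)/(aligned
bases), with each sample's reads excluded at that sample's own causative
position(s) — per-sample exclusion, not global masking, so positions
mutant in one sample still accumulate evidence from every other sample.
Deleted columns are excluded from both numerator and denominator:
the quantity is a substitution error rate. `compare_landscapes` pairs two
landscapes position-wise and reports their Pearson correlation — the
between-library reproducibility check; on simulated data the correlation
is driven by planted position-specific rate variation (e.g. homopolymer
inflation), since i.i.d. noise alone is uncorrelated by construction.

## Phasing and crossover inference

Allele vectors are read off aligned reads at panel sites; deleted or
uncovered sites are missing, and reads with any missing site are dropped
before grouping (partial-haplotype rescue is out of scope). Groups below
`min_count` = 3 reads or `min_fraction` = 0.02 are set aside as noise —
calibrated between the smallest real haplotype group in the benchmark
tables (11 of 121 reads, ≈ 9 %) and the singleton vectors that ~0.2 %
per-site consensus errors generate. Possible haplotypes are enumerated as
the Cartesian product over per-site allele sets (2^k for k heterozygous
biallelic sites).

Crossover inference takes the two most abundant groups as parents (count
ties broken lexicographically). Each minority haplotype's alleles at
parent-informative sites are assigned to parent 1 or 2; one switch along
panel order marks a simple crossover, reported as the interval between
the flanking informative sites — the data cannot localize a breakpoint
between adjacent SNPs any further, so a point estimate would overstate
precision. Two minority haplotypes with mirrored assignments and a common
breakpoint are flagged reciprocal. Alleles matching neither parent are
reported as unexplained rather than raising.

## Strand-exchange tracts

Against a panel annotated with recipient and donor alleles, each read's
sites are classified recipient/donor/error/missing. Maximal donor runs of
≥ `min_run` = 2 sites are tracts; isolated donor singletons are
reclassified as putative errors (an isolated discordant SNP is far more
likely a sequencing error than a one-SNP conversion tract) but remain
distinguishable from neither-parent errors in the per-site tallies. The
population-level exchange interval is the longest run of sites whose
donor fraction reaches `donor_fraction_threshold` = 0.10 — an explicit
operationalization of what is otherwise a visual boxing of the exchanged
region.

## Synthetic data generator

The generator replaces the instrument for all testing.

* **Single-pass model**: each template base is hit independently at
  `single_pass_rate` = 0.12 (the middle of the 10–15 % single-pass range);
  a hit is a 1-nt indel with probability `indel_fraction` = 0.92
  (insertions and deletions equally likely), else a substitution uniform
  over the three alternatives. An optional homopolymer multiplier
  inflates indel probability inside runs ≥ 4 nt (off by default),
  mirroring the empirical association of error hot spots with long
  mononucleotide runs.
* **Consensus policy**: ≥ 3 passes with ≥ 2 of one strand and ≥ 1 of the
  complement; fewer passes are rejected, as two-pass consensus quality is
  poor. Strands alternate pass-to-pass as they do on a circular template.
* **Consensus algorithm**: the median-length subread seeds a draft; all
  subreads are aligned to the draft semi-globally and each column is
  resolved by majority (ties keep the draft base; strict gap majorities
  drop the column; insertions carried by a strict majority of subreads
  are emitted). The vote is iterated up to three rounds, realigning
  against the polished draft. The voting alignment uses gap-friendly
  scoring (match +2, mismatch −5, gap −3/−3): with indel-dominated
  single-pass errors a 1-nt gap must cost less than a mismatch, or draft
  indels get absorbed as mismatch runs and the votes misregister. This
  draft-plus-vote construction is an emulation — the real instrument's
  consensus caller is proprietary — and is adequate here because
  downstream stages consume only the consensus base calls: at 5 passes it
  leaves ~2 % residual error (mostly indels in repeats), well below the
  single-pass rate but above a production POA-based caller.
* **Residual mode**: most pipeline scenarios bypass the multi-pass
  machinery and emit consensus-level reads directly with substitution-only
  noise (default 0.2 % per base, matching the observed consensus-level
  substitution noise; scenario-specific values are stated per scenario).
  Real consensus reads also carry residual indels, PCR errors and
  chimeras, which this mode does not model — passing tests demonstrate
  correct pipeline behavior under the stated noise model, not robustness
  to every artifact of real libraries.
* **Allocation and determinism**: template mixtures are allocated by
  largest remainder (a 73:17 plan over 90 reads yields exactly 73 and 17,
  as in a reconstructed dataset, not a multinomial draw); each run uses a
  single seeded RNG stream, so outputs are byte-identical across runs.

Benchmark scenarios (`ampccs.scenarios`) embed the published DLBCL
MYD88/EZH2 allele tallies and haplotype counts as study conditions. The
reference sequences there are synthetic stand-ins with the SNP sites
planted at fixed offsets, since site-level tallies, phasing and crossover
structure do not depend on the surrounding sequence; they are labelled
synthetic wherever they appear.

## Problem sizes used in tests

Test problem sizes are chosen at desk scale: 2-kb amplicons for the
benchmark phasing scenarios (90–121 reads), a 400-nt amplicon at depth 10
for the 500-trial causative-recovery study, 250–500-nt templates for
consensus calibration, and ≤ 40-nt instances for the 500-case
aligner-vs-brute-force oracle. The mutation-class *proportions* reported
for real mutant collections (e.g. the 92 %/7 %/1 % split) depend on real
biology and are not reproduced; only the classification machinery is
exercised, on mixtures whose composition the generator controls.

## Known limitations

* The consensus emulation's residual error (~2 % at 5 passes) exceeds
  real CCS accuracy; scenarios model consensus reads directly where
  consensus quality itself is not under study.
* Threshold-based calling has no genotype likelihoods and is not
  depth-adaptive; it presumes amplicon-scale depths (≥ ~10 reads).
* Phasing drops reads with missing panel sites rather than partially
  matching them.
* Chimeric reads, adapter read-through, and barcode synthesis errors are
  not modeled or detected.
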