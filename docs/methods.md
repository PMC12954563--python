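# Methods

This note documents the models, numerical conventions and deliberate
design choices behind spetkit, and what the synthetic-data tests do and
do not demonstrate about real data.

## Mappability and eligible regions

Repetitiveness is quantified as the occurrence count of the k-mer
(k = 20) starting at each position, counted over the whole reference.
Counting is **canonical** (a window and its reverse complement share
one class) because hybridisation capture is strand-symmetric; a
single-strand mode exists for comparison.  Windows containing N are
undefined and always break regions, since probes cannot be designed
over Ns.

Eligible regions must satisfy three constraints: length ≥ 200
positions, mean k-mer count strictly < 2, and every position ≤ a
per-position cap (default 4).  The cap is our addition: without it a
single massive repeat spike can be averaged away by long unique flanks.
Only the mean and length criteria are inherent to the approach; how
region boundaries are delimited is genuinely open, and we chose a
deterministic rule — within each maximal cap-respecting run, greedily
take the longest qualifying segment from the current start, else
advance one position.  The rule is implemented twice (prefix-sum scan
and a literal O(n²) loop) and the two are checked for equality in the
tests.

## Exact mapping and transcriptome anchoring

The internal mapper is exact-match seed-and-verify, valid only for
error-free reads; real-read alignment is out of scope and expected to
come from a standard aligner.  A consistent pair placement requires
forward–reverse orientation, positive insert, and insert ≤ mean + 10·sd
(650 bp at the defaults).  The upper bound makes the placement count of
a pair simulated inside an exact c-copy repeat equal c (cross-copy
pairings at implausible inserts are not counted), while a simulated
chimera with mates far apart has no consistent placement and is never
"proper".  "Unique" means exactly one consistent placement; "proper"
means the insert lies within mean ± 4·sd.

Transcriptome-to-genome contiguity uses the simulated pairs' source
coordinates: a pair contributes only when uniquely and properly placed
**and** collinear — the genomic distance between its mates equals the
transcript distance, i.e. both mates share one transcript-to-genome
offset.  Fragment spans are unioned per (transcript, genome sequence,
offset, orientation) group, so an exon–intron junction always separates
regions: a junction-crossing read has no exact full-length placement,
and pairs bridging the intron either exceed the insert bound or fail
collinearity.  The genome simulator guarantees one base of divergence
at each splice boundary (no splice-site micro-homology), without which
an exact mapper could extend a read a few chance-matching bases into an
intron; real aligners soft-clip instead, so this is a property of the
exact-matching substitute, not of the method.

## Panel design

Probe geometry is our convention (probe design is normally outsourced
to the assay vendor): a 40 bp probe immediately 5′ of the target on the
chosen strand, so single-primer extension sequences across the target.
Random sites are drawn uniformly without replacement from eligible
region positions with a minimum pairwise spacing of 1000 bp — spacing
avoids redundant capture; the exact value is not critical and is
exposed.  Panels enforce n_random/n_total ≥ 0.5, subsampling known
sites (seeded, uniform) when they exceed their share; a position in
both lists is kept as known.

## Synthetic data

The generator produces clean, well-behaved data on purpose; every
departure from realism is listed here.

* **Genomes**: i.i.d. uniform bases; repeat families are exact copies
  (so copy-number truth is unambiguous); genes have 1–3 exons of
  300–600 bp separated by introns of 800–1500 bp (long enough that no
  properly paired fragment can bridge one collinearly).  No GC
  structure, no diverged repeats, no nested features.
* **Reads**: error-free, insert ~ Normal(400, 25) truncated at twice
  the read length.  No sequencing errors, no indels, no chimeras
  (chimeric behaviour is unit-tested with hand-built pairs).
* **Capture**: per-probe fragment counts are Poisson(mean · efficiency)
  with mean 20 by default; every read starts exactly at the probe 3′
  end (SPET geometry); each fragment carries a uniform 6 bp UMI and is
  sequenced 1 + Poisson(duplication_rate) times.  Base qualities are
  constant, so the deduplicator's quality-then-id tie-break
  deterministically retains the fragment's first copy, letting
  duplicate flagging be compared to the truth table read-for-read.
  UMI collisions (two fragments, same probe, same UMI) occur at the
  birthday-problem rate and are counted in tests rather than prevented.
* **Cohorts**: population allele frequencies follow Balding–Nichols,
  p_k ~ Beta(p(1−F)/F, (1−p)(1−F)/F) around an ancestral p ~
  Uniform(0.05, 0.95); genotypes are Hardy–Weinberg within populations;
  no linkage.  Depth is negative binomial (mean 40, dispersion 5,
  var = m + m²/r), inside the 18–150× range typical of SPET target
  depth.  Allele depths are binomial with a 0.005 per-read error; GQ is
  the second-best phred-scaled genotype likelihood, capped at 99.
  Non-paralog genotypes are emitted as called correctly (an idealised
  caller); **paralog-collapsed loci** pool the reads of two latent loci
  and re-call genotypes from the pooled allele balance
  (< 0.15 / > 0.85 / else het), which produces exactly the
  excess-heterozygosity and skewed-ratio signature HDplot targets.
  Technical replicates re-draw reads independently and flip genotypes
  at rate 0.01 (uniformly to another class), so expected replicate
  concordance is 1 − e in closed form.
* **Ascertainment emulation**: the "known/array" marker class is
  labelled by conditioning on intermediate minor allele frequency
  (0.35–0.5) in a single discovery population, mirroring how array
  content is selected from a discovery panel.  This conditioning
  reproduces both the elevated MAF/Ho of array markers and a positive
  FST-underestimation ratio; conditioning on pooled MAF across all
  populations turns out to be too weak to bias θ reliably.

Passing tests therefore demonstrate algorithmic correctness and
statistical calibration under these idealised conditions — not
robustness to sequencing error, allele-specific capture bias, indels,
or linkage.

## Filtering conventions

Thresholds follow the defaults listed in the README.  Decisions the
quoted rules leave open:

* Missing site annotations (QD/MQ/MQRankSum) **pass** the hard filter
  — the GATK convention that an uncomputable annotation is
  uninformative — and get an audit flag.
* "At least half the samples had a depth greater than six reads" is
  implemented strictly (DP > 6 in ≥ ⌈n/2⌉ samples), even though the
  genotype rule is DP ≥ 6; the two rules are applied as written.
* The minor-allele support rule sums AD over all non-missing genotypes
  at the locus (a per-sample variant could be exposed later); the
  minor allele is the one with the lower called-allele count, ties
  resolved to the alternate allele.
* HDplot sub-rules combine conjunctively for keeping: a site is
  flagged if it fails H, ratio **or** D.  Ratio and D use read counts
  summed over heterozygous samples at the site; when a site has no
  heterozygote reads they are undefined and only the H rule applies.
* Hard- and HDplot-failing sites are flagged, not deleted, until the
  V0 merge, so every input site is accounted for in the report.
* Sample missingness is evaluated on the post-genotype-filter retained
  SNP loci, before sample removal affects anything else.
* DP thresholds are assumed to refer to deduplicated depth.

## Statistics

* **Hs** follows the Nei–Chesser unbiased estimator per population and
  locus, averaged over populations within a locus and then over loci.
  Whether to average over populations before or jointly is a
  convention; we use per-population-then-mean.
* **θ (W&C)** uses the classic variance components with per-locus
  population sizes from called genotypes only; populations with < 2
  called diploids are dropped from that locus, loci with < 2 usable
  populations or zero total variance are skipped from both sums.
  Ratio of sums across loci, never the mean of per-locus ratios.  The
  bootstrap resamples loci with replacement (seeded, percentile CI).
  Calibration is verified by parameter recovery: at F = 0.10 with 10
  populations × 25 diploids and 2000 loci, |θ̂ − F| ≤ 0.02 per run and
  the 95% CI covers F in ≥ 18/20 seeded replicates.
* **π** excludes sites with < 2 called allele copies from both sums;
  windows with empty denominators report NaN, never 0.  Window rows
  carry their summed numerator and denominator so any aggregation
  reproduces the global value exactly.
* **KING φ** is reported per pair over co-called loci (≥ 100 by
  default).  For a single unrelated pair at 2000 loci the estimator's
  sampling SD is ≈ 0.02, so "unrelated ≈ 0" is checked on the mean
  over all pairs of an unrelated cohort, not per pair.  The duplicate
  threshold is 2^(−3/2) ≈ 0.354.  Flagged pairs are only reported —
  deciding whether a duplicate is a natural clone (and hence retained)
  is curation, supplied to `build_v1` as an explicit removal list.
* **PCA** is an SVD of the centred, unit-variance, mean-imputed dosage
  matrix with a deterministic sign convention (largest-magnitude score
  positive per axis).

## Problem sizes

Tests and the acceptance script run on deliberately small instances
chosen to keep the full suite near a minute while leaving the
statistical checks well-powered: genomes of 30–260 kb, panels of
20–70 probes, cohorts up to 10 populations × 25 diploids × 2000 SNP +
2000 invariant sites, 10 000 read pairs for round-trip checks.  All
generators and estimators scale linearly in sites × samples and have
been run well beyond these sizes.

## Known limitations

* The exact mapper cannot stand in for real-read alignment; it exists
  to reproduce the perfect-read anchoring procedure and to test the
  pipeline.
* Multiallelic SNPs are counted and dropped (as in the filtering
  workflow), never dosage-coded; indels are classified and excluded at
  read time.
* HDplot power depends on depth and cohort size; the ≥ 0.9 sensitivity
  shown at 100 samples and 40× mean depth degrades in small or shallow
  cohorts.
* The VCF writer emits uncompressed text only; bgzip/tabix handling is
  left to the surrounding tooling.
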