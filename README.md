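# spetkit

A toolkit for designing and analysing **SPET (Single Primer Enrichment
Technology) targeted-genotyping panels**, aimed at population-genetic
monitoring of non-model species — forest trees in genetic conservation
units being the motivating case.  It covers the full workflow:
ascertainment-bias-free selection of probe target sites on a reference
genome or transcriptome, probe manifest emission, UMI-based duplicate
removal, per-probe depth QC, a reproducible variant-filtering cascade
with paralog detection, and the diversity/differentiation statistics a
conservation-genetics cohort analysis needs.  A synthetic-data module
generates every input with known truth, so the whole pipeline is
testable on a laptop without any sequencing data.

## What it computes

**Mappability and site selection.** Local repetitiveness is the
occurrence count of the 20-mer starting at each genome position
(canonical, strand-folded).  Regions at least 200 bp long with mean
20-mer count < 2 (and no per-position count above a cap) are eligible
for random target placement.  For transcriptome-only species, eligible
intervals are found by exactly mapping simulated error-free read pairs
(150 bp, insert 400 ± 25) onto a related genome and keeping transcript
intervals collinear with it — repeats and exon–intron junctions drop
out by construction.  Panels enforce **≥ 50% random sites** so that
downstream diversity estimates are not dominated by markers
pre-selected for intermediate frequency.

**Filtering (V0/V1).** SNPs and invariant sites are split and filtered
separately: hard site filters (fail when QD < 2.0, MQ < 40.0 or
MQRankSum < −12.5); HDplot paralog removal with H ≤ 0.6, allele read
ratio in [0.2, 0.8] and D = (A−B)/√(A+B) in [−10, 10]; genotype filters
(DP ≥ 6, GQ ≥ 20, depth > 6 in at least half the samples, locus minor
allele supported by ≥ 3 reads); samples with > 80% missing data
removed; invariant sites kept when DP > 6 in at least half the samples.
The merged V0 minus curated outlier/duplicate samples is V1.

**Statistics.**

- Nei–Chesser unbiased gene diversity, per population and locus:
  `Hs = n/(n−1) · (1 − Σp² − Ho/(2n))`.
- Weir & Cockerham's θ (FST) from the per-locus variance components
  a (among populations), b (between individuals within populations),
  c (within individuals), combined as `θ = Σa / Σ(a+b+c)` over loci,
  with a seeded 1000-replicate locus bootstrap for the 95% CI.
- Nucleotide diversity π the missing-data-robust way:
  `π = Σ D_s / Σ C_s` with `D_s = n_ref·n_alt` and `C_s = C(n,2)` over
  called allele copies, invariant sites included in the denominator.
- KING-robust kinship `φ = (N_Aa,Aa − 2·N_AA,aa)/(N_Aa(i)+N_Aa(j))`
  for duplicate detection (duplicates ≈ 0.5), plus genotype PCA and
  technical-replicate concordance with discordance-class breakdown.
- Species-discriminant markers: sites where two species' allele
  frequencies differ by ≥ 0.9 after DP/GQ/call-rate filtering.

The synthetic cohort generator draws population allele frequencies from
the Balding–Nichols model, whose parameter F is exactly what W&C θ
estimates — giving the estimators a planted truth.

## Worked example

```python
from spetkit import simulate, filters, popgen, cohort
from spetkit.simulate import PopulationModel

model = PopulationModel(n_pops=5, n_per_pop=20, n_loci=1000, F=0.08,
                        missingness=0.05, paralog_fraction=0.05,
                        n_invariant=1000, n_replicates=3, seed=11)
sim = simulate.simulate_population_vcf(model)

res = filters.apply_filter_workflow(sim.table)   # V0 cascade
v0 = res.v0
labels = {s: sim.pop_labels[s] for s in v0.samples}

hs, _ = popgen.expected_heterozygosity(v0, labels)
fst = popgen.wc_fst(v0, labels)
lo, hi = popgen.bootstrap_ci(fst, n_boot=1000, seed=12)
pi = popgen.pi_global(v0)
_, pooled = cohort.replicate_concordance(v0, sim.replicate_pairs)

print(f"retained sites: {v0.n_sites} of {sim.table.n_sites}")
print(f"Hs = {hs:.4f}")
print(f"theta = {fst.theta:.4f}  (95% CI {lo:.4f}-{hi:.4f})")
print(f"pi = {pi:.4f}")
print(f"replicate concordance = {100*pooled.concordance:.2f}%")
```

prints

```
retained sites: 1948 of 2000
Hs = 0.3406
theta = 0.0795  (95% CI 0.0745-0.0844)
pi = 0.1760
replicate concordance = 98.88%
```

The cohort was simulated at F = 0.08; θ̂ recovers it within sampling
noise and the CI covers it.  The 52 sites dropped by the cascade are
dominated by HDplot-flagged paralog-collapsed loci (the model planted
5%).  Replicate concordance reflects the simulated 1% genotype error.

A command-line interface mirrors the library
(`spetkit index|regions|anchor|panel|dedup|filter|stats|qc|discriminant`);
run `spetkit --help` for details.

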