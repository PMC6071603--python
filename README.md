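# balsel-diff

Population differentiation under balancing selection, for multi-population
diploid SNP data.

Genes under long-term balancing selection — the classical HLA loci are the
canonical case — carry an excess of intermediate-frequency variants. Because
the maximum attainable FST at a biallelic site is constrained by its minor
allele frequency (MAF), a SNP set depleted of rare variants looks *more*
differentiated than the genomic background even when selection is actually
homogenising allele frequencies across populations. This package implements
the complete analysis needed to untangle that confounding, plus the forward
simulations that explain why recently diverged populations can show the
opposite pattern:

* **Weir–Cockerham (1984) FST** with explicit variance components `a`
  (among populations), `b` (among individuals within populations) and `c`
  (within individuals), per SNP: `FST = a / (a + b + c)`. Multi-locus
  summaries by both the **ratio of averages** `mean(a) / mean(a+b+c)` (least
  biased; downweights rare variants) and the naive **average of ratios**.
* **Analytic MAF constraint**: the maximum parametric FST,
  `max Var(p) / (p̄(1−p̄))` over deme frequency configurations with a fixed
  pooled MAF `m` (for two demes, `m/(1−m)`), plus the observed MAF–FST
  envelope.
* **MAF-binned comparisons and an LD-aware resampling test**: focal SNPs vs
  genomic controls per MAF bin (two-sided Mann–Whitney), and a matched
  resampling scheme that assembles control sets gene-block by gene-block with
  exactly the focal set's per-bin MAF counts, so linked focal SNPs are
  compared against equally linked controls.
* **Haplotype-level recoding**: two-field HLA allele normalisation
  (`A*01:01:01:02 → A*01:01`), frequency-based ambiguity resolution, and
  one-vs-rest recoding of each gene's multiallelic calls into
  pseudo-biallelic loci that feed the same FST machinery.
* **Overdominance split simulator**: Wright–Fisher daughters of size `N`
  split from an ancestor at the equilibrium `p̂` of heterozygote advantage
  (fitnesses `1−s(1−p̂) : 1 : 1−s·p̂`), under *shared* (same fitnesses) or
  *divergent* (daughter 2's equilibrium shifted by `δ`) overdominance, with
  a matched neutral locus. Reports `ΔFST = FST_neutral − FST_selection`
  over time.
* **Synthetic data generator** producing the full input bundle (VCF, panel,
  region map, annotations, exclusion list, HLA call table) with the
  structure the analysis assumes: rare-variant-rich controls, an
  intermediate-frequency focal class with weaker differentiation, and
  tunable within-gene LD.

## Worked example

Generate the default synthetic study conditions (20 populations × 100
diploids; a focal "HLA-like" class at differentiation 0.04 with an
intermediate-frequency SFS, controls at 0.09 with a rare-dominated SFS) and
compare the two classes:

```python
from balseldiff import (SynthConfig, generate_dataset, per_snp_fst_table,
                        binned_fst_comparison)

ds = generate_dataset(SynthConfig(rng_seed=7))
tab = per_snp_fst_table(ds.genotypes, ds.pop_codes, ds.sites, 20)
focal = tab[tab.region_class == "HLA"]
control = tab[tab.region_class == "control"]
print(focal.fst.median(), control.fst.median())
# 0.0397  0.0253        <- unconditional: focal looks MORE differentiated
print(binned_fst_comparison(focal, control)
      [["maf_lo", "focal_median", "control_median", "pvalue"]])
#  maf_lo  focal_median  control_median   pvalue
#    0.00           NaN          0.0117      NaN
#    0.01        0.0360          0.0785  1.5e-01
#    0.10        0.0359          0.0902  2.8e-15
#    0.20        0.0410          0.0861  8.1e-28
#    0.30        0.0394          0.0950  2.5e-27
#    0.40        0.0402          0.0931  1.1e-10
```

Unconditionally the focal SNPs look more differentiated (median 0.040 vs
0.025) because the controls are dominated by rare variants pinned to near-zero
FST; within MAF bins the ordering reverses — focal SNPs are substantially
*less* differentiated (medians ≈ 0.04 vs ≈ 0.09, Mann–Whitney p < 1e-10 in
every bin above MAF 0.1). The multi-locus ratio of averages shows the same
reversal: 0.041 (focal) vs 0.091 (control), while the naive average of
ratios gives 0.041 vs 0.044.

The split simulator reproduces the divergence-time sign switch:

```bash
balsel-diff simulate --n0 1000 --s 0.1 --feq 0.5 --delta 0.2 \
    --tmax 2000 --reps 5000 --seed 7 --times 50,2000 --out sim.tsv
```

At 50 generations after the split, `dfst` (FST_neutral − FST_selection) is
≈ −0.013: divergent overdominance transiently *drives* differentiation above
the neutral level. By 2N = 2000 generations it is ≈ +0.41: in the long run
balancing selection strongly suppresses differentiation. With a small
equilibrium shift (`--delta 0.1 --s 0.05`) `dfst` is non-negative at all
times.

A command-line interface covers the whole pipeline on real VCF inputs:
`balsel-diff fst`, `pairwise`, `envelope`, `resample-test`, `haplotypes`,
`simulate`, `synth` (see `--help` for each).

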