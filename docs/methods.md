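# Methods

## FST estimation

Per-SNP differentiation uses the Weir & Cockerham (1984) ANOVA estimator for
diploid data. For `r` populations with sample sizes `n_i`, alternate-allele
frequencies `p_i` and observed heterozygote frequencies `h_i`, the estimator
returns the three variance components (`a`: among populations, `b`: among
individuals within populations, `c`: between gametes within individuals) and
`FST = a/(a+b+c)`. The estimator is unbiased, so individual components and
per-SNP FST can be negative; a site is reported as *undefined* (NaN) when
`|a+b+c| < 1e-12` — a floating-point guard for (near-)monomorphic sites —
never as an exception. Populations with no non-missing genotype at a site are
excluded from that site's estimate; sites with fewer than two populated
populations are undefined. The implementation is the algebraic per-locus form
(`n̄`, `n_c`, `p̄`, `s²`, `h̄`); the test suite checks it to 1e-12 against an
independently coded mean-squares (MSP/MSI/MSG) transcription on a thousand
random instances, and against hand-evaluated examples (a fixed difference
gives exactly `a=0.5, b=c=0, FST=1`; a small balanced two-population sample
gives the expected negative estimate `−1/6`).

Multi-locus summaries come in two modes. The **ratio of averages**
`mean(a)/mean(a+b+c)` weights each SNP by its total variance and is the least
biased aggregate; the **average of ratios** (mean per-SNP FST) is pulled
toward zero by rare variants, whose FST is constrained to small values. Both
are exposed because their disagreement is itself diagnostic of SFS
differences between SNP sets. Global analyses use every site polymorphic in
at least one retained population; pairwise analyses re-filter sites for
polymorphism within each pair, and flag pairs sharing a continental group.

Per-population allele frequencies are computed from genotype counts (not
dosages), with missing genotypes dropped per site and individual. The global
MAF is the frequency of the rarer allele in the pooled sample, not a mean of
per-population MAFs. The allele designated as "counted" is the VCF alternate
allele throughout; FST is invariant to this choice (tested).

## The MAF constraint on FST

Parametric FST of a deme configuration is `Var_w(p)/(p̄(1−p̄))`. With the
pooled frequency fixed, this is convex in the frequency vector, so its
maximum over `[0,1]^K` lies at an extreme point of the constrained polytope:
all demes fixed at 0 or 1 except at most one. For equal deme weights (the
default; population samples in the intended datasets are near-equal) this
yields a closed form evaluated stably via deviations from the mean; for
`K = 2` it reduces to `m/(1−m)`. The bound equals 1 exactly when
`K·(1−m)` admits an integral fixed-deme decomposition. Unequal weights fall
back to constrained numerical maximisation (SLSQP, multi-start). Sample
estimates may exceed the parametric bound; the envelope report counts such
exceedances as diagnostics and never clips them.

## MAF bins and the LD-aware resampling test

Default bins: one rare bin `[0, 0.01)` and five bins of width ~0.1 up to 0.5;
bins are left-closed/right-open with the last bin closed (the bin convention
is a package decision; only the edge values are inherited from the analysis
design). Per-bin comparisons use the two-sided Mann–Whitney test: exact when
both sides are ≤ 50 tie-free observations, otherwise the normal approximation
with tie correction.

The resampling test controls for the non-independence of focal SNPs (which
sit in a handful of genes) by building each replicate's control set out of
whole gene blocks: a control SNP is drawn uniformly at random (so genes enter
with probability proportional to their usable SNP count), all of its gene's
SNPs in still-incomplete MAF bins enter the set (a random subset when the
remaining quota is smaller), the gene is retired, and drawing continues until
every bin holds exactly the focal set's count. Genes are used at most once
per replicate; replicates are independent; exhausting the pool before a bin
fills raises an error naming the bin. Per-bin count equality is asserted on
every replicate.

**Calibration caveat.** Because the matched set reproduces the focal MAF
composition exactly, the rank-sum statistic has smaller variance than the
Mann–Whitney null assumes whenever the FST distribution varies across MAF
bins; the test is then conservative (observed type-I fractions well below
alpha on rare-rich pools). On a null fixture where FST is approximately
independent of MAF — a single SNP class with an intermediate-frequency SFS
and one concentration parameter — the type-I fraction is correctly
calibrated (within 3 binomial SEs of alpha at 1000 independent null draws,
each with a freshly drawn focal gene set). Calibration must be judged on
independent draws: with one fixed focal set the replicate outcomes are
strongly correlated and their significant fraction is not a type-I rate.

## Haplotype-level analysis

HLA allele names are truncated to two fields (protein-level resolution);
truncation is idempotent and malformed names are rejected. Ambiguous calls
(candidate lists) are resolved to the candidate with the highest pooled
frequency, iterating the frequency table until the assignment stabilises,
with lexicographic tie-breaks — fully deterministic. (An alternative used in
parts of the literature resolves ambiguity by minimising population
differentiation; the pooled-frequency rule is implemented because it is
deterministic and does not bias the differentiation estimate downward.)
Each gene is then recoded one-vs-rest: one pseudo-biallelic locus per
distinct two-field allele, genotype = count of the focal allele. Within a
gene, each typed sample's counts across loci sum to exactly 2 (asserted);
untyped samples are dropped per gene, never imputed. Pseudo-loci feed the
identical Weir–Cockerham code path as SNPs. Because no haplotype reaches
high frequency, haplotype-vs-SNP comparisons use a finer bin scheme confined
to `[0, 0.2]` (edges 0, 0.02, 0.04, 0.08, 0.12, 0.16, 0.2; configurable).

## Input handling

Inputs are a VCF (plain or gzipped, parsed with cyvcf2), a sample panel TSV
(sample, population, continental group, admixed flag), a region map TSV of
1-based fully closed intervals labelled HLA/periHLA plus an exclusion-list
TSV, and a functional annotation TSV (consumed as input — e.g. ANNOVAR
output — never recomputed). Samples of admixed populations are excluded.
Site filters: biallelic SNVs only (multi-allelic records dropped, never
decomposed), excluded sites dropped, one functional class retained so focal
and control SNPs are compared within the same category, and each retained
site must be polymorphic (ALT count strictly between 0 and 2×non-missing) in
at least one retained population. The retained set is order-independent;
drop counts are logged per filter with each site attributed to the first
filter it fails (multiallelic → excluded → functional class → monomorphic),
so counts sum to input − retained. Any site outside the HLA and peri-HLA
intervals is a control.

## Overdominance split simulator

Fitnesses are parametrised by the equilibrium frequency and a total selection
strength: `w_AA = 1−s(1−p̂)`, `w_Aa = 1`, `w_aa = 1−s·p̂`, so the interior
equilibrium is exactly `p̂` and the summed homozygote load is `s`. Each
generation applies deterministic viability selection followed by binomial
resampling of `2N` gametes. Both daughters start deterministically at the
ancestral equilibrium (populations are effectively identical at the split;
no extra sampling noise is injected), take size `size_fold × N0` from the
split onward, and daughter 2's equilibrium is shifted by `delta` (divergent
overdominance; `delta = 0` is shared overdominance; the shift is asymmetric,
applied to one daughter). A matched neutral locus starts at the same
frequency in both daughters and drifts independently (unlinked). Per
generation the two-deme parametric FST `(p1−p2)²/(4 p̄ q̄)` is aggregated
across replicate loci by ratio of averages (mean numerator over mean
denominator, with a delta-method Monte-Carlo SE); replicates monomorphic in
both daughters contribute nothing. The per-replicate mean of ratios is
reported alongside since the two aggregations can differ at long times.
`ΔFST = FST_neutral − FST_selection`: positive when selection suppresses
differentiation.

Default scales: `N0 = 1000`, `feq = 0.5`, 2000–5000 replicate loci, times up
to `2N` generations — sizes at which the full experiment runs in seconds
while the Monte-Carlo SE of ΔFST (≈ 4e-4 at t = 50 with 5000 replicates) is
an order of magnitude below the effects of interest (|ΔFST| ≈ 0.003–0.013 at
early times).

## Synthetic study conditions

The generator emulates the structure the analysis assumes, not human
demography. Per-population frequencies follow the Balding–Nichols model:
`p_i ~ Beta(p(1−F)/F, (1−p)(1−F)/F)` around an ancestral frequency `p`,
where `F` is the parametric differentiation. Within-gene LD is induced by a
Gaussian copula that shares a per-gene, per-population quantile across the
gene's SNPs with weight `ld_strength` (0 = independent, 1 = identical
quantiles), leaving every SNP's marginal distribution intact. Genotypes are
HWE binomial draws; sites realized monomorphic in every retained population
are dropped, mimicking variant-calling ascertainment.

Defaults are the study conditions: 20 populations × 100 diploids in four
continental groups; focal class of 7 genes at `F_focal = 0.04` with an
intermediate-frequency SFS (`0.1 + 0.4·Beta(2,2)`); controls at
`F_control = 0.09` (the two multi-locus levels the real-data analysis
reports) with a two-component `1/x` folded SFS — 92 % of draws between
5e-5 and 5e-4 (at or below ~2 expected pooled copies) and the rest between
5e-4 and 0.5. The heavy ultra-rare component is deliberate: under
Balding–Nichols, conditioning on realized polymorphism biases rare variants
toward multi-copy, single-population configurations with genuinely elevated
FST, so reproducing the empirical dominance of near-zero-FST rare variants
in exome data requires most control draws to sit at the singleton scale.
With these defaults the fixture shows the three structural facts the
analysis turns on — the focal/control SFS shift, no parametric exceedance of
the MAF–FST bound, and the reversal between unconditional FST (focal above
control) and MAF-conditional FST (focal below control in every tested bin
above 0.01) — verified across independent seeds. A serial-split variant
generates populations along a balanced binary tree so pairwise FST grows
with divergence time.

What the generator does **not** emulate: migration and isolation-by-distance,
realistic SFS shapes beyond the two-component approximation, linkage decay
within genes (LD is exchangeable, not distance-dependent), inter-gene LD,
and the within-continent structure that drives the real divergent-time
contrast. Passing tests therefore demonstrate correctness of the estimators
and procedures under a controlled frequency model, not demographic realism.

## Known limitations

* Diploid, biallelic data only; no haploid or multiallelic support.
* The hierarchical (continent/population) F-statistics decomposition is out
  of scope; pairwise runs only flag same-continent pairs.
* The resampling test reports raw per-bin p-values; no multiple-testing
  correction (by design).
* The weighted-deme variant of the MAF bound relies on numerical
  maximisation and is validated only for small numbers of demes.
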