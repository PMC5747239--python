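# Methods

This note documents the models, the synthetic-data design, the numerical
choices and the known limitations of `bovimpute`.

## Synthetic population

The generator emulates the statistical structure of a sequenced dairy-cattle
cohort at desk scale. Nothing in the package depends on these exact numbers —
they are the defaults of `BenchmarkConfig` and of the CLI `simulate` command.

**Pedigree.** `simulate_pedigree` builds a closed population with cattle-like
mating: founders split evenly by sex, each generation's dams are all females
of the previous generation, and each dam mates with one of a small number of
sires (default 4) sampled from the previous generation's males. Offspring
sexes alternate within a dam, so the population size is deterministic:
`n_founders + Σ_g n_dams_g × offspring_per_dam`. The default benchmark uses
20 founders and two generations of 40 and 80 animals (140 in total) so that
nested reference panels of 20/60/120 animals coexist with a 20-animal
validation set.

**Founder haplotypes.** `simulate_founder_haplotypes` draws per-site target
alt-allele frequencies from Beta(a, b) with a = b = 0.5; the U-shape
concentrates mass near 0 and 1, so after folding to MAF the lowest
polymorphic class (0, 0.025] holds more sites than any other class — the
signature of sequence (as opposed to chip) data. Haplotypes are generated by
a first-order copying process: each haplotype carries a latent uniform
variate that persists from one site to the next with probability
`copy_rate^(d / mean_spacing)` (d = inter-site distance in bp) and refreshes
otherwise; the allele is the indicator that the latent uniform lies below the
site's target frequency. This matches the target frequencies exactly in
expectation and induces pairwise LD that decays geometrically with physical
distance; `copy_rate = 0` gives independent sites with E[r²] ≈ 1/H. The
default `copy_rate = 0.9` at 2.1 kb mean spacing gives strong local LD that
is largely dissipated beyond a few hundred kb. LD decay in the real breed is
not quantitatively characterised, so this parameter is a tunable emulation,
not a calibration.

**Gene dropping.** Founder haplotypes propagate through the pedigree with
Poisson(L_Mb × cM/Mb ÷ 100) crossovers per meiosis, uniformly placed, on a
uniform 1 cM/Mb map over a single 42 Mb chromosome (the scale of the small
autosome used for imputation validation). No mutation is introduced: all
polymorphism originates in founders, matching the imputation setting where
reference and target share variation. True phase is retained, which is what
licenses handing truth-phased chip genotypes to the imputer (real pipelines
pre-phase with a tool such as Beagle before population-based imputation). If
a pedigree record has one unknown parent, that gamete is drawn from a random
founder.

**Chip ascertainment.** `select_hd_subset` keeps sites with MAF ≥ 0.05 and
picks n sites nearest an even grid of target positions, mimicking commercial
array design (common variants, even bp spacing). The default 400 chip sites
against 20,000 sequence sites preserves the ~1:50 chip-to-sequence density
ratio of an HD chip on a small autosome (12,222 : 642,911).

**Phenotypes.** `simulate_phenotypes` composes a QTL part (n_qtl causal sites
sampled among MAF ≥ 0.05, jointly explaining `qtl_fraction` of the genetic
variance, default 0.5) and a polygenic part (small normal effects on all
sites). Both parts are rescaled to their target sample variances and the
residual is drawn with variance 1 − h², so the phenotypic variance is ~1 and
the realized heritability is close to nominal by construction. The
daughter-derived breeding-value phenotypes of a real evaluation (mean
reliability ~0.95) are not modelled; these synthetic phenotypes stand in for
them in all recovery tests.

What the generator does **not** emulate: genotyping/sequencing error, variant
calling and phasing error (the real upper bound on imputation accuracy),
multi-breed structure, selection, non-uniform recombination, and structural
variation. Passing tests therefore demonstrate correctness of the machinery
and the direction of design effects, not absolute accuracy levels on real
panels.

## Relationship matrices and key ancestors

`additive_relationship` is the standard tabular method (founders a_ii = 1;
a_io = (a_is + a_id)/2; a_oo = 1 + a_sd/2), with unknown parents contributing
zero, so inbreeding accumulates implicitly. `vanraden_G` is VanRaden's first
method, G = ZZ′ / (2Σp_k(1−p_k)), with observed-sample allele frequencies and
monomorphic sites dropped. GRM PCA double-centers the matrix before the
eigendecomposition and fixes signs so the largest-magnitude loading is
positive.

Key-ancestor selection is implemented as a greedy maximisation of the
captured additive variation c(S) = mean_j a_jS (A_SS)⁻¹ a_Sj over the whole
pedigree — the average squared pedigree-predicted contribution of the
selected set to every population member. The published description of the
selection of influential animals is verbal ("capture most of the gene pool,
based on mean pedigree relationship"); the conditional greedy criterion is
this package's concrete, testable choice. It is monotone along the greedy
path, selects a prolific sire first on the obvious fixture, and a ridge of
1e-8 on A_SS guards against singular subsets. Ties break toward the older
generation, then id order.

## Imputer

The Li–Stephens copying model runs per target haplotype on the typed sites
only: switch probability 1 − exp(−ρ·d) per interval (landing uniformly on any
of the H reference haplotypes, including the current one), emission mismatch
probability θ. The forward–backward recursion is scaled at every step, so no
underflow occurs at any panel size used here.

- **θ default 1e-3** — a small allelic mismatch rate absorbing both mutation
  and genotype error.
- **ρ default 4e-6/H per bp** — the population-scaled recombination rate
  4·Ne·r/H with cattle-like Ne ≈ 100 and r = 1 cM/Mb. Dividing by the panel
  size is what keeps copying segments long in large panels; at the default
  chip spacing (~105 kb) this gives per-interval switch probabilities of
  order 1e-3–1e-2.

Untyped sites take the state posterior linearly interpolated in physical
distance between the flanking typed sites (ends extend the nearest typed
posterior); the haploid alt-allele probability is the posterior-weighted
reference allele, diploid genotype probabilities are the convolution of the
two haplotype posteriors, and dosage is p₁ + 2p₂. Targets are assumed
pre-phased; no internal phasing exists.

`call_genotypes` implements the threshold rule of discrete-genotype
conversion: call the most probable genotype when its probability reaches the
threshold, else missing. Since the three probabilities sum to one, any
threshold ≤ 1/3 (including the 0.3 default) always calls. Exact ties resolve
to the smaller genotype code — the tie behaviour of the original conversion
tool is undocumented, so this deterministic rule is a package decision.

`minimac_r2` is the dosage-variance quality measure: r̂² = var(d)/(2p̂(1−p̂))
with p̂ = mean(d)/2, defined as 0 when p̂ ∈ {0, 1}. Population variance (ddof
0) is used so that hard, balanced dosages give exactly 1.

## Accuracy evaluation

Sites eligible for accuracy statistics exclude (i) chip sites and (ii) sites
monomorphic in both the reference and the validation truth — including the
corner case of both being monomorphic for *different* alleles. Genotype
concordance is the per-animal fraction of identical called genotypes, with
missing imputed calls counted as mismatches.

**Centering.** Correlation measures first subtract each site's expected
genotype: the truth by 2p with p estimated in the validation truth (a config
switch allows reference or combined frequencies), the imputed values by
their own per-site mean. Centering each dataset by its own frequency is the
natural "remove the expected genotype" reading and makes the measure behave
correctly under systematic direction flips (an imputation returning 2 − g at
every site scores exactly −1). Zero-variance vectors yield NaN with a
warning, never a silent 0, and NaNs are excluded (and counted) in averages.

**MAF classes.** Thirteen classes with boundaries 0, 0.025, 0.05, 0.075,
0.1, 0.15, 0.2, 0.25, 0.3, 0.35, 0.4, 0.45, 0.5; membership is (lower,
upper], class 0 holds exactly the monomorphic sites and is excluded from
evaluation. Class MAF is computed in the scenario's **reference** panel;
per-class correlations pool all sites of a class into a single
individual × site vector.

**Aggregation.** Cross-validated scenarios average per-animal means within
each fold first, then across folds unweighted, and report the across-fold
range; fold-size imbalance therefore does not re-weight animals (the test
suite pins this with a constructed counter-example against pooled
averaging).

**Scenario schemes.** `key_ancestors(n)` (greedy selection as above),
`random_cv(n, folds)` (disjoint reference chunks when folds·n fits in the
pool, independent draws otherwise — a 10-fold draw of 20 animals from a
~120-animal pool cannot be disjoint), and `nested_reference(sizes,
n_validation)` (one fixed random validation set, strictly nested growing
references).

## Mixed-model association

The null model y = μ + u + e with u ~ N(0, Gσ²_a) is fitted by REML: G is
eigendecomposed once, the restricted likelihood is profiled down to the
heritability ratio h² = σ²_a/(σ²_a+σ²_e), and a bounded scalar optimisation
(plus a 21-point grid guard against boundary-adjacent local optima) finds
the maximum on [1e-6, 1−1e-6]. Estimates within 1e-4 of the bounds are
flagged as boundary fits. The scan then fixes V = Gσ²_a + Iσ²_e (the EMMAX
approximation — no per-variant variance re-estimation, and a single global
null fit rather than leave-one-chromosome-out), decorrelates y, the
intercept and all dosage columns through the eigenbasis, and computes each
variant's GLS effect, its known-variance standard error and a Wald 1-df
chi-square p-value in closed form. Zero-variance (or
intercept-collinear) dosage columns are reported with effect 0, p = 1 and a
flag. With σ²_a = 0 the scan reduces exactly to per-variant OLS, which the
tests verify.

QC keeps sites with MAF > 0.01 **and** missing fraction < 0.1 — the two
standard rules applied jointly. The imputation-quality filter keeps sites
with r² strictly greater than 0.3. The significance threshold is Bonferroni
α/m; the inflation factor is the median of the p-value-implied 1-df
chi-squares over 0.4549 (the null median). QTL summarisation merges
significant sites whose consecutive gaps are ≤ 1 Mb (a package default — no
clustering rule is standard) and reports each region's bounds, site count
and top variant, with ties broken toward the smaller position.

The fat-content phenotype transform is
FC = 200 ((FY_basis + FY/2)/(MY_basis + MY/2) − FY_basis/MY_basis)
with FY_basis = 282.18463 kg and MY_basis = 7080.298 kg; it is strictly
increasing in fat yield and strictly decreasing in milk yield over the
admissible domain (MY_basis + MY/2 > 0).

## Problem sizes and numerical choices

The default benchmark (140 animals, 20,000 sites, 400 chip sites, nested
references 20/60/120, 20 validation animals) runs in a few seconds per
replicate; the ten-replicate trend study and the recovery studies (500
individuals × 2,000–5,000 sites) complete in about two minutes in total.
These sizes were chosen so the full pipeline and its statistical behaviour
are exercised at interactive speed while preserving the study's density
ratios and panel-size contrasts.

Probability triples are validated to sum to 1 within 1e-9; forward–backward
uses per-step normalisation; eigenvalues of G are clipped at 0; the A-matrix
ridge is 1e-8; p-values are clipped away from exact 0 before the λ
computation. All stochastic operations take explicit seeds and the pipeline
derives stage seeds from one master seed via `numpy.random.SeedSequence`.

## Limitations

- The imputer is a single-chromosome, pre-phased-target model: no phasing,
  no chunking, no pedigree-aware (family-based) imputation.
- Only biallelic SNPs are supported end to end (multiallelic records are
  rejected at parse time); BCF, indels and genotype likelihood fields are out
  of scope.
- Synthetic accuracy levels are optimistic relative to real panels (no
  calling or phasing error, closed pedigree); only directions of effects and
  exactness of the statistics transfer.
- The greedy key-ancestor criterion is one defensible formalisation of
  "capture the gene pool"; alternatives (unconditional mean relationship,
  marginal-gain weighting) would rank differently on some pedigrees.
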