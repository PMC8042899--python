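# Methods

This note records the models behind each statistic, the parameter choices
that matter, what the synthetic generator does and does not emulate, and
the numerical conventions — the things a maintainer would otherwise have to
reverse-engineer from the code.

## Data model and conventions

Genotypes live in a `VariantTable`: biallelic SNPs only (multi-allelic and
indel records are dropped at read time), alt-allele dosage 0/1/2 with a
single missing code per diploid call, 1-based inclusive coordinates (VCF
convention; BED output converts to 0-based half-open). No imputation
anywhere: every statistic uses per-site non-missing counts. Chromosome
lengths come from VCF header contigs when present, else the maximum
observed position.

Sliding windows are anchored at position 1 of each chromosome:
`[k·step+1, k·step+size]` for every k whose start lies on the chromosome,
truncated at the end. Windows below a SNP minimum are flagged excluded but
still emitted, so window indices are stable across statistics.

Per-bp quantities (θπ, d_xy) divide by the full window length, i.e.
non-variant positions are treated as monomorphic and accessible — the
convention of VCFtools-style windowed scans. An accessibility mask would
change levels but not contrasts; it is out of scope.

## Diversity statistics

* θπ: per site 2p(1−p)·n/(n−1) (unbiased pairwise diversity at sample size
  n haplotypes), summed over the window. Equivalent to averaging pairwise
  haplotype mismatches, which is exactly how the test oracle computes it.
* Tajima's D: the 1989 normalization computed from the window's S and
  summed pairwise differences. Constants use the window's **modal**
  non-missing haplotype count; sites with other counts still contribute
  their own frequencies. With no missing data this is exact; with
  missingness it is the same approximation the standard tools make. S = 0
  windows are NaN (undefined), never 0.
* F_ST: Weir–Cockerham (1984) a/b/c variance components per site (two
  populations, genotype-level, using observed heterozygosity), combined per
  window as Σa / Σ(a+b+c) — the "weighted" ratio-of-sums convention.
  Negative windowed values are reported as computed, preserving the shape
  of the distribution that the sweep scan Z-transforms. The alternative
  `hudson` estimator is the *definitional* frequency contrast
  (p_A−p_B)² / [p_A(1−p_B)+p_B(1−p_A)], chosen (over the finite-sample-
  corrected variant) so that identical frequency vectors give exactly 0 and
  fixed differences exactly 1; Weir–Cockerham is the default precisely
  because it carries the finite-sample correction.
* LD: on unphased data r² is the squared Pearson correlation of 0/1/2
  dosage columns over samples called at both sites (composite LD); phased
  mode uses D²/(p(1−p)q(1−q)) from haplotype frequencies. Monomorphic
  members of a pair are skipped.

## Introgression statistics

Polarization assigns the ancestral state as the allele fixed in the
outgroup among non-missing calls; sites with a polymorphic or missing
outgroup are excluded from all polarized statistics. Exclusion is the
only implemented behaviour: keeping outgroup-missing sites would mix
polarizations silently, and no windowed statistic here needs them.

D uses population derived-allele frequencies (a pseudo-haploid "count"
mode, rounding each population to its majority allele, exists as the
oracle mode). Significance comes from a weighted delete-one block
jackknife over contiguous 2-Mb coordinate blocks (last block truncated,
empty blocks skipped), block weight = its informative mass Σ(ABBA+BABA),
variance per Busing et al. (1999) — the AdmixTools convention, which
reduces to the classical jackknife at equal weights. Two cautions
established during calibration:

1. **Quartet topology matters.** In the (Wild,(DomCN,SEASA)) scaffold the
   quartet (Wild, DomCN; SEASA) is *not* null without migration — the
   DomCN/SEASA sister branch generates excess ABBA (measured mean D ≈
   +0.02 at fixture scale). The null-calibration test therefore follows
   the original study design: P1 and P2 are two subsamples of the same
   domestic group (exchangeable ⇒ E[D] = 0 exactly) against SEASA as P3.
2. **Blocks need mass.** With ~2 independent 5-kb loci per block the
   jackknife Z is overdispersed (std ≈ 1.26); at ~10 loci per block
   std(Z) = 1.00. Block size should always be chosen to hold many
   independent segments, which the 2-Mb default does on a real genome.

f_d (the window-scale admixture-fraction estimator) replaces P2 and P3 by
the per-site donor proxy p_D = max(p2, p3) in the denominator; windows
with non-positive numerator get f_d = 0 (switchable to NaN), which keeps
region calling well defined. Regions are maximal runs of overlapping or
bookended passing windows (f_d ≥ 0.5 by default) with merged span ≥ 200 kb.

f3(A;B,C) is the unscaled Patterson-style estimator
(p_A−p_B)(p_A−p_C) − h_A/n_A with h_A = p_A(1−p_A)·n_A/(n_A−1), averaged
over sites, jackknifed like D. No heterozygosity normalization: only the
sign and Z enter the inference, and the unscaled form keeps the estimator
linear in per-site terms.

Verification of a candidate region contrasts its d_xy(recipient, donor)
and F_ST against the distribution over all same-size windows: recent gene
flow pulls d_xy down locally, shared ancestral polymorphism does not —
this is the package's substitute for haplotype-painting evidence.

## Sweep scan

Per 40-kb/10-kb window: θπ in each group, Weir–Cockerham F_ST, and (for
plotting only) Tajima's D. Windows with θπ(domestic) = 0 are sidelined as
"fixed in domestic" candidates rather than entering the ratio distribution
— a pseudo-count would distort exactly the top-5% quantile the criterion
uses. Over included windows F_ST is Z-transformed (mean 0, SD 1) and
outliers must reach the empirical `quantile` (default 0.95) of **both**
log2(θπ ratio) and Z(F_ST). Cutoffs are recomputed from the data at hand;
published numeric cutoffs from any one dataset are properties of that
dataset. Fewer than 20 usable windows is a refusal, not a quiet answer.

## Coalescent models and ABC

Scaffold: backward in time DomCN and SEASA merge at T1, their ancestor
merges with Wild at T0 (T1 < T0 enforced by prior rejection); each derived
deme optionally runs at a bottleneck fraction of its size during the older
half of its existence [T1/2, T1]; migration edges connect coexisting
demes, parameterized as 4Nm with the backward per-lineage rate
m = 4Nm/(4·N_source). Mutation: infinite sites at μ = 1.91e-9 per bp per
generation, generation time 1 year — the constants used for this system.
Loci are independent (no intra-locus recombination), matching the
multi-locus summary-statistic workflow the design emulates; msprime is the
simulation engine, with the package's analytic neutrality checks
(E[π] = 4Neμ, E[S] = θ·a1·L, E[D] ≈ 0) as independent oracles.

The eight-model registry covers the gene-flow hypotheses: M1 none, M2
Wild↔DomCN, M3 DomCN↔SEASA, M4 Wild↔SEASA, M5 = M2+M3, M6 = M2+M4, M7 all
three pairs, M8 all pairs but only in the most recent T1/2 generations.
Default priors (reconstructions, config-swappable): Ne log-uniform
[1e3, 1e6] diploids for all five demes; T0 uniform [1e3, 1e4] and T1
uniform [100, 1e4] generations with T1 < T0 by rejection; bottleneck
fraction log-uniform [0.01, 1]; 4Nm uniform [0, 20] per active edge.

Summary statistics (37, fixed order): per population S, θπ, Tajima's D,
H_E over dataset variant sites, private S; per pair Hudson F_ST
(ratio of sums), d_xy, shared S; across-locus SDs of per-locus θπ, F_ST
and d_xy; pooled S, θπ and Tajima's D; and the fraction of the four D
statistics that were defined. Undefined values are imputed as 0 and that
last indicator keeps the imputation visible to the classifier. All site
kernels are the same functions the windowed empirical scans call, so the
observed and simulated vectors share one definition of every statistic.

Dimension reduction is PLS-DA: statistics standardized (constant columns
dropped with a warning), one-hot model labels as the response, 9
components by default. When the supervised fit is degenerate (identical
class distributions) the reducer falls back to PCA so symmetric inputs
still yield well-defined (uniform) posteriors. Note the full-component
PLS transform is an *oblique* change of basis: it loses no information
(lossless linear reconstruction, which the tests assert) but does not
preserve raw distances.

Model choice: `rejection` keeps the globally nearest `retain_fraction` of
all simulations in PLS space and reports vote shares; `glm` keeps the
nearest fraction within each model (at least enough draws to identify the
regression: components + parameters + 5), fits s = c + Cθ + ε with
standardized parameters and ridge 1e-8, and averages the Gaussian density
of the observed vector over the retained parameter draws — all in log
space, so posteriors stay comparable when densities underflow. Posteriors
are normalized over an equal model prior; simulation counts are equalized
by subsampling first, which makes the posterior invariant to duplicating
every model's table.

At desk scale (30 loci × 2 kb, 5 diploids per deme, 2000 simulations per
model) the eight models are far from fully separable — nested migration
scenarios overlap — so validation asserts above-chance recovery, not high
accuracy; a green run establishes the machinery ranks the true model
better than guessing, nothing stronger.

## Synthetic generator: what it does and does not emulate

The generator reproduces the panel's *shape*: group sizes 19/25/21/4, a
deep outgroup (split 5e5 generations ago, small Ne so it is near-fixed at
polarizable sites), two chromosomes tiled from independent 10-kb loci, a
planted introgressed tract (donor haplotypes copied over a chosen fraction
of recipient haplotypes — by construction locally identical to the donor)
and a planted sweep (founder haplotype plus Poisson new singletons). The
default "true" demography is anchored to field estimates for this system:
wild Ne 1e5, domestic 6e4 with a 0.15 bottleneck, SEASA 1e4 with a 0.10
bottleneck, splits at 3500 and 1700 generations.

Not emulated: within-locus recombination in the tiled genome (LD is blocky
at locus boundaries; LD-decay behaviour is exercised on a dedicated
single-locus simulation *with* recombination), sequencing/genotyping
error, missing data (the simulated VCF is complete), variable mutation or
recombination rate, and reference bias. A green recovery test therefore
establishes that the statistics find the planted signal under clean
coalescent noise — not that they are robust to artifacts of real calling
pipelines.

## Limitations

* Tajima's D with heavy, non-random missingness inherits the modal-n
  approximation; the exact per-site bookkeeping lives only in the oracle.
* The f_d zero-floor for negative-D windows biases region-level means
  upward slightly relative to an NaN convention; both are available.
* ABC parameter *estimation* is not provided (model choice only); retained
  draws can be inspected but carry no regression adjustment.
* The GLM density assumes a linear-Gaussian stats-on-parameters map within
  the retained neighbourhood; strongly curved posteriors will favor the
  rejection method.
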