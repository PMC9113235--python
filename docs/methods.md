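# Methods

## Scope and model

`islandscan` re-implements the standard divergence-scan toolkit for
population resequencing data. All estimators are allele-frequency based and
operate on a samples × sites matrix of alternate-allele dosages (0..ploidy,
or missing), so mixed-ploidy cohorts (diploid/tetraploid/hexaploid) are
supported throughout; only the full heterozygosity-aware F<sub>ST</sub>
decomposition is diploid-specific (see below). Coordinates are 0-based
half-open internally; VCF I/O converts to/from 1-based positions.

## Windowed statistics

**Windows.** Default 40-kb windows advanced by 20 kb. Full windows start at
0, step, 2·step, … while they fit; a contig shorter than one window yields
the single window [0, L); an uncovered tail of ≥ step bp yields one
truncated trailing window (configurable).

**π.** Unbiased per-site heterozygosity n/(n−1)·2p̂(1−p̂) summed over window
sites, divided by the full window length L. No accessibility mask is applied
(callable-site data are rarely available for such scans); π is therefore a
lower bound wherever parts of a window are unalignable. The same convention
applies to D<sub>XY</sub>.

**F<sub>ST</sub>.** Per-site Weir & Cockerham (1984) components a (between
populations), b (between individuals within populations), c (within
individuals), using observed heterozygote frequencies when every sample in
both populations is diploid. For mixed-ploidy cohorts the haploid
(allele-copies) mean-square form is used instead: a = (MSP − MSG)/n_c,
b = MSG, c = 0. The window estimate is the ratio of sums Σa/Σ(a+b+c)
(the "weighted" VCFtools convention); a mean-of-ratios column is emitted for
comparison. Sites monomorphic across both populations are skipped. Raw
(possibly negative) values are stored; clipping to 0 happens only where a
downstream ratio requires non-negativity.

**Tajima's D.** Window-level S and absolute π with the 1989 normalizing
constants. The allele-sample size n entering the constants is the minimum
per-site non-missing allele count across the window's segregating sites — a
deterministic, conservative choice when missingness varies (without missing
data it is simply the population allele count). Undefined (NaN) when S = 0
or fewer than 4 allele copies are available; undefined windows are excluded
from summaries.

**D<sub>XY</sub>** uses point-estimate allele frequencies,
Σ[p̂_A(1−p̂_B) + p̂_B(1−p̂_A)]/L. A genotype-likelihood-weighted frequency
mode is a possible extension; the point-estimate form is exact for the
dosage data the package consumes.

**LD r².** Squared Pearson correlation between dosage vectors
(composite/Rogers–Huff form), valid on unphased genotypes; haplotype-based
(EM) r² would differ on heterozygote-rich data and is not implemented.
Monomorphic sites contribute no pairs; missing dosages are mean-imputed per
site. Background level for unlinked loci is ≈ 1/n individuals.

## Outlier machinery

**Z-F<sub>ST</sub>** standardizes window F<sub>ST</sub> by the genome-wide
mean and standard deviation per comparison; Z ≥ 2 approximates a top-5%
tail. An alternative "printed" mode evaluating (F<sub>ST</sub> ×
mean)/sd is provided for fidelity experiments with literature variants of
the formula; it is not the default because it is not location-invariant and
does not map Z = 2 onto the upper 5% tail. Quantiles and standardization are
genome-wide (not per chromosome); windows with undefined statistics are
excluded from both the threshold estimation and the calls.

**Sweep outliers** require a window to lie simultaneously in the top
fst_q of F<sub>ST</sub> and the top ratio_q of log₂(π_ref/π_target)
(defaults 0.05/0.05). The orientation must name the target population
(the one scanned for diversity loss) explicitly, and is echoed in the
output header. π_target = 0 gives a +inf ratio, always in the tail; ties at
a cutoff are included; q = 0 returns the empty set.

**Randomization test.** Island/background labels are permuted over windows
(island count preserved) and the difference of means recomputed. With at
most 10⁵ distinct labelings the null is enumerated exhaustively and p is the
exact tail fraction; otherwise n_perm (default 1000) random relabelings are
drawn and p = (1 + hits)/(1 + n_perm). Two-sided by absolute difference by
default; the direction (elevated/reduced) is always reported so both
elevated-D<sub>XY</sub> (species divergence) and reduced-D<sub>XY</sub>
scenarios are expressible. A one-way ANOVA F-test p-value is reported
alongside, and rank-sum (Mann–Whitney) summaries compare π, Tajima's D,
D<sub>XY</sub> and SNP counts between islands and background.

## GWAS

The binary (0/1) trait is analyzed as quantitative in a linear mixed model
y = Xα + Sβ + u + e, u ~ (0, σ²_g K), e ~ (0, σ²_e I) — the standard LMM
treatment of a presence/absence contrast in a structured cohort (a logistic
mixed model would be the alternative; the linear form is what GWAS practice
and the tooling this package mirrors actually use).

- **K** is the simple-matching kinship: K_ij = mean over shared sites of
  1 − |d_i/p_i − d_j/p_j|, reducing to the classic 1/0.5/0 diploid scores;
  the matrix is symmetrized exactly and, if numerically indefinite, its
  diagonal is shifted by ε so the smallest eigenvalue is ≥ 0.
- **S** is an intercept plus the top 3 principal components of the centered
  (mean-imputed) dosage matrix, with signs fixed deterministically.
- Variance components are estimated once on the null model by REML through a
  single eigendecomposition of K (grid + bounded refinement over log δ,
  δ = σ²_e/σ²_g) — the EMMAX approximation; each SNP is then tested by
  weighted least squares in the rotated basis with a Wald t-test
  (df = n − p) on the marker coefficient, with the GLS scale re-estimated
  per SNP. This makes the σ²_g = 0 limit collapse exactly onto per-SNP
  ordinary least squares. Missing dosages are mean-imputed per tested SNP;
  monomorphic or collinear SNPs are flagged, not fatal.
- λ (genomic inflation) is the median χ²(1) quantile of the p-values over
  0.4549. Association inputs follow the resequencing GWAS preset
  (MAF ≥ 0.05, missingness ≤ 0.1, depth ≥ 2): rare variants yield discrete,
  poorly calibrated single-marker tests at cohort sizes of tens of samples
  and are removed before testing, as they would be in practice.

## Synthetic data

The generator creates the statistical structure the scan assumes, not a
biological replica:

- **Standing variation** is drawn from the neutral frequency spectrum
  (density ∝ 1/x), which reproduces Watterson's E[S] = 4NeμL·a_n exactly in
  expectation. Default μ = 5.4 × 10⁻⁹ per bp per generation; the 6-year
  generation time is carried as metadata only.
- **Drift** after each population split is binomial resampling, time-
  compressed into ≤ 64 diffusion-equivalent steps (a step of c generations
  uses a binomial denominator 2Ne/c, preserving the per-generation variance
  p(1−p)/2Ne). New mutations enter at the chain's one-copy frequency with
  influx 2NeμL per step — the rate that keeps the stationary spectrum at the
  target 4NeμL/x independent of the compression. Optional symmetric
  migration mixes group frequencies each step.
- **Islands** are planted as divergent directional frequency shifts
  (target A toward 1, target B toward 0, by the given intensity), restricted
  to sites already polymorphic in the target populations so that islands
  change divergence rather than SNP density. This elevates F<sub>ST</sub>
  and D<sub>XY</sub> jointly.
- **Sweeps** are imposed on the sampled genotypes: a fraction `intensity`
  (rounded up) of the target population's minor-allele copies in the
  interval is converted to the major allele, deterministically (highest-
  dosage carriers first), so intensity 1 makes the window monomorphic.
  There are no selection dynamics through time.
- **Traits** are binary: dominant near-deterministic penetrance on one
  causal SNP (planted at frequency 0.5 in every population) with a
  configurable phenotyping-error rate, a fair-coin null, or a fully
  population-confounded mode. The default error rate in the pipeline is
  0.02 — the presence/absence contrasts such scans map are essentially
  fully penetrant, and a strong-effect trait is what the recovery analyses
  are calibrated against (with ~300 SNPs after filtering, a causal p-value
  must beat a null minimum of ~3 × 10⁻³, which a noisier trait at n = 30–40
  does not reliably do).
- **Depth/MQ** per site: Poisson(7.7) coverage and MQ 60 with 2% of sites
  perturbed into [10, 59], so the filter rules act on realistic inputs.
- **Determinism:** one top-level seed, spawned into per-contig substreams;
  identical config + seed gives bit-identical output.

What the generator does **not** emulate: linkage (sites are exchangeable, so
LD decay is flat at background), recombination-rate variation, background
selection, sequencing reads/genotyping error beyond the depth/MQ fields, and
selection trajectories. Passing tests therefore demonstrate estimator
correctness and pipeline calibration under the assumed statistical
structure, not robustness to the full messiness of real resequencing data.

## Filters and bookkeeping

SNP retention uses the canonical resequencing thresholds (depth 2–50,
RMS MQ ≥ 20, MAF ≥ 0.05, missingness ≤ 0.1), each disableable. MAF is pooled
across all samples (a per-population MAF variant would drop private rare
alleles differently; pooled matches the common VCFtools workflow).
Removed sites are attributed to exactly one rule in the fixed order
multiallelic → depth-low → depth-high → MQ → missingness → MAF, so the
report always balances. Filtering is idempotent.

## Problem sizes

Calibration and recovery analyses run at desk scale by design: 1–4 Mb
genomes, 20–40 samples, ~1000 SNPs per Mb (matching θ = 4Neμ with
Ne = 10⁴), 10 replicate seeds for recovery rates, 600–1000 replicates for
type-I calibration. These sizes put Monte-Carlo noise comfortably inside the
stated tolerance bands while keeping any single analysis under a minute.

## Known limitations

- No genotype likelihoods; dosages are taken at face value.
- Window denominators use the full window length (no accessibility mask).
- The haploid F<sub>ST</sub> fallback ignores within-individual correlation
  in autopolyploids.
- The LMM analyzes a binary trait linearly; p-values near 0/1 phenotype
  separation are approximate.
- The simulator's compressed drift slightly coarsens the rare-frequency end
  of the spectrum between splits (entry frequency is the chain's one-copy
  class, c/2Ne rather than 1/2Ne).
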