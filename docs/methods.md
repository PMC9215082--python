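# Methods

Definitions, parameter choices and numerical design decisions for every
stage of the scan. Population A is always the scan target (the population
suspected of recent positive selection); population B is the reference.

## Windows

Sliding windows of `window_size` = 50,000 bp every `step` = 20,000 bp.
Windows start at 1, 1 + step, 2·step + 1, … for every start inside the
contig; the final windows are truncated at the contig end. Sites are
assigned by position (1-based, inclusive on both ends).

## θπ — nucleotide diversity

Per site, with n called haplotypes of which k carry the alternate allele:

    π_site = 2 k (n − k) / (n (n − 1))

the unbiased mean pairwise difference. The window value is the sum of
per-site π over the sites in the window divided by the *full window span*
(not the number of SNPs), so sweep-flattened windows are not rescued by
their low SNP counts. Sites with fewer than two called haplotypes are
skipped. Input sites are MAF ≥ 0.05 and missingness ≤ 0.1 filtered within
population A.

## CLR — composite likelihood ratio sweep scan

The classic SweepFinder model (Nielsen et al. 2005) re-implemented:

- The genome-wide background SFS is tallied empirically from all analysed
  sites (folded to minor-allele classes by default; unfolded available).
  Sites whose called sample size differs from the modal n are
  hypergeometrically down-projected onto n (or rejected, by option).
- Under a sweep of intensity α at distance d, each of the n lineages
  escapes the sweep independently with probability p_e = 1 − exp(−α d).
  The k escapees plus the single hitchhiking ancestor form a pre-sweep
  sample of size k + 1 whose derived count is a hypergeometric subsample
  of a background draw; every non-escapee copies the hitchhiker's allele
  (a uniformly chosen member of the pre-sweep sample). When all n lineages
  escape, the site is a plain background draw.
- Because only segregating sites are observed, mass on monomorphic
  outcomes is dropped and the polymorphic classes renormalised; folded
  spectra are refolded after the distortion.
- The CLR at a grid point is 2·(max_α ℓ(α) − ℓ₀), maximised over 40
  log-spaced α spanning p_e ∈ [0.01, 0.99] at one grid step, floored at 0.
  Grid points sit at the centres of consecutive 50 kb blocks; a window's
  CLR is the mean of the grid points it contains.

Numerical notes:

- Class probabilities are precomputed on a 401-point p_e grid and linearly
  interpolated, making the scan O(grid × α × sites) in vectorised numpy.
- **Zero inflation is expected.** The likelihood ratio is floored at zero
  and the boundary MLE (neutral model wins) is the typical outcome away
  from sweeps, so ~95% of windows carry CLR = 0 on the desk data. These
  zeros are genuine maximum-likelihood results, not failures; downstream
  code (rank p-values, MCD) is written to tolerate the resulting point
  mass.
- **CLR input is missingness-filtered only.** A MAF cut truncates exactly
  the rare-frequency classes the sweep spectrum predicts in excess and
  empirically zeroes the statistic genome-wide, so the pipeline routes an
  unfiltered-MAF site set to the CLR while θπ keeps the conventional MAF
  filter. Sites monomorphic *within A* (e.g. fixed hitchhikers) are
  excluded inside the scan because the model conditions on polymorphism.

## F_ST — Weir & Cockerham (1984)

Per site, the three variance components a (among populations), b (among
individuals within populations) and c (within individuals) are computed
from the two populations' sample sizes, allele frequencies and observed
heterozygote fractions (r = 2 formulas). The window estimate is the
ratio-of-sums Σa / Σ(a + b + c) over the window's sites (the weighted
estimator; a mean-of-ratios column is also emitted). Sites where either
population has fewer than two complete genotypes get NaN components and
are excluded from window sums. Input sites are pooled-MAF and
pooled-missingness filtered on the shared site set of both populations.

## XP-EHH

Whole-sample EHH from each core site: at offset x the haplotype partition
uses every site from the core through x inclusive, EHH(0) = 1 by
convention. iHH is the trapezoid integral of EHH over physical distance on
both sides, stopping after the first segment that crosses EHH < 0.05
(crossing segment included) or at 1 Mb. XP-EHH_raw = ln(iHH_A) − ln(iHH_B)
per core site (the log difference, not log of the ratio, keeps population
swap exactly antisymmetric in floating point); scores are z-standardised
genome-wide and a window's value is the mean standardised score over cores
inside it. Cores with zero iHH in either population are dropped.

## DCMS combination

For each statistic t, a one-sided fractional-rank p-value across all n
windows: p_i = rank / (n + 1), ranked toward the tail that indicates a
sweep (ties share the rank; the n + 1 denominator keeps p strictly inside
(0, 1)). Default tails are π left, CLR left, F_ST right, XP-EHH right —
matching a scan whose CLR column ranks *low* values as interesting;
`RECOVERY_TAILS` (used in all sweep-recovery experiments and the
`--recovery-tails` CLI flag) flips CLR to the right tail, which is the
scientifically correct direction for positive selection.

    DCMS_i = Σ_t log10((1 − p_it) / p_it) / Σ_s |r_st|

where r is the t × t correlation matrix of the raw statistics across
windows, estimated by the minimum covariance determinant (alpha = 0.75,
50,000 random starts) so that sweep windows — outliers by construction —
do not inflate the weights.

### FAST-MCD implementation

In-package FAST-MCD: h = ⌈alpha·n⌉; each random (t+1)-subset start is
refined by two vectorised concentration steps (chunked, batched matrix
inverses); the ten most concentrated candidates are iterated to a local
determinant minimum and the best subset's covariance is converted to a
correlation matrix. alpha = 1 reproduces the classical estimator exactly.
**Exact-fit fallback:** with a zero-inflated statistic (CLR) the optimal
h-subset can have a zero-variance coordinate, making the correlation
undefined; the estimator then falls back to the classical correlation
matrix with a warning and a `degenerate` flag — mirroring the exact-fit
singularity handling of standard MCD implementations. The robustness
properties are validated on continuous data where no fallback occurs.

## Calibration and FDR

DCMS scores are calibrated with an intercept-only Huber M-estimate
(tuning constant 1.345, MAD scale, IRLS iterated on the coefficients to
1e-8): the robust location μ̂ and scale σ̂ ignore the sweep-induced upper
tail, and p_i = Φ̄((DCMS_i − μ̂)/σ̂) is the upper-tail normal p-value.
Benjamini–Hochberg (step-up) adjustment gives q-values; windows with
q < 0.05 that overlap or abut are unioned into candidate regions
(min_q = minimum member q). Genes from a GFF3 overlap a region if they
share ≥ 1 bp.

## Simulator

Two populations A and B of diploid size N_a = N_b = 500 split from an
ancestral population (N_anc = 500) `split_gen` = 300 generations ago;
mutation μ = 2.5e-7 /bp/gen (equilibrium diversity 4Nμ = 5e-4 /bp, giving
realistic SNP densities at a computationally tractable scale),
recombination ρ = 1e-7 /bp/gen, three contigs of 2 Mb, 30 + 30 sampled
individuals. Output is a phased VCF restricted to sites polymorphic in the
pooled sample, plus a truth table for any sweep.

Routing:

- **Neutral contigs** are drawn from the exactly equivalent two-population
  split coalescent (msprime, binary mutation model, continuous positions
  integerised and deduplicated).
- **Sweep contigs** run a forward Wright–Fisher engine seeded from an
  msprime-equilibrium ancestral population: per-generation fitness-weighted
  parent sampling (additive fitness 1 / 1+s / 1+2s on the focal allele),
  Poisson crossovers, infinite-sites mutation, and removal of fixed/lost
  columns each generation (numba kernels keep a desk contig at a few
  seconds). The focal mutation is injected `start_gen` = 250 generations
  before present at frequency 1/(2N) and re-injected on loss — the
  conditional-on-establishment convention, so every sweep replicate
  carries a real sweep. s = 0 routes to the neutral path, making the
  no-selection invariant exact.
- **Sample at fixation:** establishment-conditioned fixation takes
  ~180–245 generations at s = 0.05, N = 500; if the allele has not fixed
  by generation 0 both populations keep evolving until it does (capped at
  1000 extra generations). The preset therefore models a *recently
  completed* sweep — the scenario the scan targets — at the cost of a
  slightly variable effective split age.

Realism and limitations: panmictic discrete generations, uniform μ and ρ,
no gene conversion, no background selection, binary alleles with REF=A /
ALT=T placeholders, and a single hard sweep per run. These are deliberate:
the simulator is a validation instrument whose expectations (4Nμ
diversity, F_ST growth with split age, sweep footprint width ~s/(ρ ln 2N))
are analytically checkable, not a demographic model of any real species.

## Determinism

Each contig derives its RNG stream from (seed, contig index); msprime
seeds are drawn from that stream; the MCD uses a fixed seed from
`PipelineConfig`; all output writers format floats with `%.6g`. Identical
configuration + seed reproduce every output file byte-for-byte.
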