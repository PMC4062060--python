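# Methods

`methprog` implements the statistical core of a stage-wise CpG-island (CGI)
methylome progression analysis for two-color methyl-CpG-immunoprecipitation
(MCIp) arrays, in which highly methylated DNA from transcription-factor
knockdown (kd) animals and matched wildtype (wt) animals is co-hybridised and
differential methylation is read from the per-probe log-ratio
M = log2(kd/wt). This note documents the models, the tunable parameters, the
synthetic-data generator behind the tests, and the numerical and design
choices that were genuinely open.

## Array preprocessing

**Background correction (NormExp).** Each channel's observed probe intensity
is modelled as X = B + S with normal background B ~ N(mu, sigma^2) and
exponential specific signal S with mean alpha. The corrected intensity is the
posterior mean

    E[S | X = x] = mu_sx + sigma * phi(mu_sx/sigma) / Phi(mu_sx/sigma),
    mu_sx = x - mu - sigma^2/alpha,

evaluated through log-densities (`log Phi` via `scipy.special.log_ndtr`) so
the Mills ratio stays finite arbitrarily far below background. Any corrected
value below 0.5 is reset to 0.5 before the stabilising offset (default 50) is
added; the result is strictly positive and monotone in x. Parameters are
estimated from negative-control probes when at least 30 are present
(mu, sigma = control moments; alpha = mean excess of all probes over mu);
otherwise a method-of-moments fit over all intensities is used (the
exponential's third central moment 2*alpha^3 identifies alpha), with floors
sigma, alpha >= 0.01 so degenerate inputs cannot produce invalid parameters.

**Normalization.** Within each co-hybridised pair, M is regressed on
A = (log2 R + log2 G)/2 by LOESS (tricube weights, local linear, span 0.4 of
the fitting subset, one robustifying iteration) estimated **only** on
rank-invariant probes (within-channel ranks differing by at most 0.05*n)
united with all negative controls, so genuinely differential probes do not
bend the curve; the robustifying iteration additionally downweights the
occasional differential probe that slips through the rank filter. The fitted
curve is evaluated at the subset points, linearly interpolated to every
probe's A, and clamped to the subset's A-range at the extremes. A final
location step subtracts the median subset residual: a degree-1 local fit
leaves an O(span^2) curvature remnant of any smooth bias whose median need
not be zero, and centring on the presumed-null subset removes it without
touching the differential signal. Normalization is not exactly idempotent —
no local smoother is a projection — but a second pass changes M by an order
of magnitude less than the first (median absolute change ~0.008 on the
sinusoidal-bias fixture versus ~0.3 for the first pass).

## Differential methylation (one-class SAM)

For each disease stage separately (stages assigned from bone-marrow blast
counts: <20% preleukemic, 20–50% inclusive early leukemic, >50% late
leukemic; animals without a count may carry a forced label), the one-class
moderated statistic per probe is d = mbar/(s + s0) with s = sd/sqrt(n). The
fudge factor s0 is selected from the percentiles {0, 5, ..., 100} of the
per-probe s values (plus zero) by minimising the coefficient of variation of
median |d| across 100 s-quantile windows.

The null is generated by sign-flip permutations applied per sample column
(preserving probe-wise correlation); all 2^n flips are enumerated when
2^n <= B, otherwise B = 1,000 random flip vectors are drawn from a mandatory
seed. For each threshold Delta on a 200-point grid, probes are called beyond
the first sorted index whose observed d departs from the permutation-expected
order statistic by more than Delta (upper crossing -> hypermethylated, lower
-> hypomethylated; the cut is monotone). The FDR estimate is

    FDR(Delta) = pi0 * mean over permutations of #{null d beyond the cuts} / #called,

with pi0 = min(1, #{d inside the permutation interquartile band}/(0.5 n)).
The mean false count follows the original SAM formulation; the permutation
median is reported alongside in the Delta table but is anti-conservative for
very small call sets (it is zero whenever fewer than half the permutations
reach the cut). The reported `fdr` column is the left-running minimum of the
raw estimate, making it non-increasing in Delta; the smallest Delta at or
below the target (default 5%) is selected, and an empty call set is returned
when no Delta qualifies.

Two operating characteristics worth knowing:

- At n = 7 the sign-flip null has granularity 1/128. Roughly one null array
  in ten contains a probe whose configuration no flip can reproduce; its
  estimated FDR (1–6)/128 falls under 5% and it is called. This is intrinsic
  to permutation tests at this sample size, not noise in the estimator.
- At n = 5 with a sizable planted fraction, flipped versions of truly
  differential probes inflate the null and the 32-pattern granularity is
  coarse; sensitivity drops sharply. The early-leukemic stage of the default
  design sits in this regime and calls few probes.
- When a large asymmetric fraction of probes is truly shifted (the late
  stage plants ~33% of signal probes), pi0 is underestimated and the
  realized false-discovery proportion of the *opposite-direction* calls can
  exceed the target; the primary recovery guarantees are stated for the
  preleukemic configuration.

Stage call sets are compared by a full Venn partition (hyper and hypo
separately); "unique" means called in exactly one stage.

## Annotation and gene aggregation

A probe is a **promoter** probe when it overlaps the strand-aware window from
2,000 bp upstream to 500 bp downstream of a gene's TSS; else **gene body**
when it overlaps the gene span; else **downstream** within 2 kb past the
strand-appropriate gene end; else **unknown**. Promoter > gene body >
downstream when several genes compete, and ties go to the nearest TSS. Gene
level calls require at least `min_probes` called probes per gene (default
stringencies 1 and 2); probes without a gene aggregate under their CGI
identifier so genes and other genomic locations are counted jointly.
Gene-list overlaps are case-insensitive after whitespace stripping, with an
upper-tail hypergeometric enrichment p against a caller-supplied universe.

## Enrichment of peaks and motifs in hypermethylated islands

Consensus-motif occurrences (IUPAC alphabet, overlapping matches allowed,
forward strand by default with an optional both-strands mode) and binding
peaks are intersected with CGI sets by a sorted-merge sweep counting each
query interval at most once. Significance is assessed two ways:

- **Permutation:** each query interval is repositioned uniformly on its own
  chromosome (length preserved) B = 1,000 times;
  p = (1 + #{null >= observed})/(B + 1), so p is never zero. The B null
  rounds are drawn jointly and resolved with a vectorised binary search.
- **Fisher:** the 2x2 table [hyper islands with/without >= 1 overlapping
  peak; remaining islands with/without], two-sided, with the island
  stringency filter (>= 1 or >= 2 supporting probes) applied first.

## Quantitative validation

Amplicon-level methylation is the mean over non-missing CpG units (missing
cells propagate, never imputed). Group differences use the two-sided
Mann-Whitney U test, exact when both groups have <= 8 values and no ties
(the study's 5–7 animals per group sit in the exact regime), otherwise the
normal approximation with tie and continuity corrections. Samples are
clustered with Euclidean distance and average linkage; missing features are
pairwise-deleted and the squared distance rescaled by n_total/n_shared.
Cluster confidence uses the multiscale bootstrap: features are resampled
with replacement at sizes round(r * n_features) for r in {0.5, ..., 1.4}
(10 scales, B = 1,000 each); BP_r(node) is the fraction of resampled trees
containing the node's exact leaf set, and AU comes from the weighted
least-squares fit Phi^-1(1 - BP_r) = v*sqrt(r) + c/sqrt(r) over scales with
BP_r strictly inside (0,1) (binomial weights B*phi(z)^2/(BP(1-BP))), with
AU = 1 - Phi(v - c). Nodes with BP_r = 1 everywhere are reported saturated at
AU = 1, nodes never observed get AU = 0, and nodes with fewer than three
usable scales fall back to BP with a flag. PCA uses the SVD of the
feature-centered matrix with a deterministic sign convention
(largest-magnitude score positive); variance fractions are normalised squared
singular values.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes, not
sequence realism. A uniform-composition genome (default two 600 kb
chromosomes) carries 300 non-overlapping CGIs (600–1,400 bp) tiled by ~5–6
probes each of 45–60 bp, plus 150 off-island negative controls; exact
occurrences of the consensus motif (default GAGGAA) are planted in half the
islands; ~70% of islands anchor a gene model whose TSS sits near the island
midpoint. Baseline methylation beta is low (U(0.05, 0.25)) except at islands
designated for hypomethylation (U(0.55, 0.75)). Planted per-stage island sets
share a common core and expand sharply in the late stage (defaults 30/28/100
hyper and 15/12/15 hypo islands), with methylation shifts
delta_beta = +0.45 / -0.40 applied to every probe of a planted island in the
planted stage.

Channel intensities follow X = N(50, 10^2) + Gamma(k, mean alpha*g(beta))
with alpha = 200 and the linear MCIp enrichment response
g(beta) = 1 + 5*beta. The Gamma shape k = 30 models replicate-feature
averaging on the array: k = 1 is the single exponential draw assumed by
NormExp, but a single draw would put ~2.6 log2 units of noise on every M
value, a regime in which no seven-animal comparison has power; k = 30 gives
per-probe M noise of ~0.35 log2 units, the operating point at which the
calling guarantees are stated. The background-plus-exponential *mean*
structure that NormExp estimates is unchanged. Dye bias multiplies the kd
channel by 2^(b*sin(A/2)) with b = 0.5 — a smooth intensity-dependent
distortion of exactly the kind LOESS normalization must remove. Peaks are
placed inside the preleukemic hyper islands with odds rho (default 10)
against the island subset's genomic share w, P(inside) = rho*w/(rho*w+1-w),
and uniformly outside those islands otherwise, so rho = 1 reduces to uniform
placement. Amplicon tables add N(0, 0.05) noise to the island's true beta,
include six standard rows at 0/20/40/60/80/100% methylation, and inject 5%
missingness into animal rows.

What the generator does **not** model — CpG-density-dependent probe affinity,
spatial array artifacts, copy-number or immune-infiltration confounds,
between-array batch effects, and sequence-driven motif clustering — bounds
what passing tests show about real arrays: they validate the statistical
machinery under its stated assumptions, not robustness to those artifacts.

## Reproducibility and problem sizes

Every stochastic step takes an explicit seed; the pipeline derives per-stage
seeds from SHA-256 of the master seed and the stage name (all below 2^31),
and a rerun with the same configuration is bit-identical across all
artifacts. Default problem sizes (1,800 probes, 19 animals, B = 1,000
permutations and bootstrap replicates, 200 calibration repetitions at 2,000
peaks) were chosen so a full run completes in seconds and the complete
statistical validation in about a minute on one core, while keeping every
estimate's Monte-Carlo error well inside the tolerances it is tested at.

## Known limitations

- The FDR-calibration guarantees are for the mean-false-count estimator; the
  samr-style median column is provided for comparison but should not be used
  for automatic threshold selection at small call counts.
- Early-leukemic (n = 5) sensitivity is intrinsically low (see above).
- AU values for clean separations saturate at 1.0 rather than interpolating,
  because every resample reproduces the split; this matches the behaviour of
  multiscale-bootstrap implementations on well-separated data.
- The interval shuffle preserves chromosome and length but not inter-peak
  spacing or island masking; an island-restricted shuffle can be selected in
  configuration but is not the default.
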