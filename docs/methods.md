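# Methods

## The measurement model

Pool sequencing estimates a population's allele frequency with two
layers of sampling noise: a finite pool of N diploid females carries
2N chromosomes drawn from the population, and the sequencer samples R
reads from the pool at each site. On the arcsine-square-root scale
z = arcsin(√p) the sampling variance of a binomial proportion is
approximately 1/(4n) regardless of p, which motivates the two-stage
variance used throughout:

    Var(z_pool) ≈ 1/(8N) + 1/(4R).

The shift statistic for population j is dz_j = z_sel,j − z_ctrl,j with
variance V_j equal to the sum of the two pools' variances, each using
that pool's own realized depth. Shifts are treated as independent
Gaussians dz_j ~ N(δ_j, V_j).

Because the Gaussian likelihood on the stabilized scale has known
variances, all four model fits are closed-form weighted means:

* Model 0: δ = 0, no parameters; LL0 = Σ_j log φ(dz_j; 0, V_j).
* Model 1: single δ; MLE is the inverse-variance weighted mean
  δ̂ = Σ(dz_j/V_j)/Σ(1/V_j).
* Model 2: one δ per exposure group (high/low); group-wise weighted
  means.
* Model 4: δ_j = dz_j, saturated; LRT4 reduces to Σ dz_j²/V_j.

LRT_k = 2(LL_k − LL_0) is compared to χ² with k degrees of freedom
(k = 1, 2, 4; there is deliberately no "model 3" — models are named by
parameter count). The χ² reference is exact for this Gaussian model, so
the degrees of freedom require no simulation calibration; the test suite
nevertheless verifies them by simulation.

### Significance and model assignment

The free-model p-values (p4) are screened by Benjamini–Hochberg at
q = 0.10 — a deliberately permissive filter, accepting extra false
positives rather than missing shared architecture. Each flagged SNP is
then labelled with the model achieving the smallest *raw* p-value among
{p1, p2, p4}. Ties are resolved by the highest log-likelihood and, if
still tied, by the fewest parameters. Tie detection is *relative*
(1e-12) plus the exact case of simultaneous underflow to zero: raw
p-values at strong loci span many orders of magnitude below any absolute
tolerance, so an absolute band would spuriously tie almost every strong
hit and misroute it to the saturated model through the log-likelihood
tie-break.

### Numerical choices

* Boundary frequency estimates (p̂ = 0 or 1) are transformed as-is to
  z = 0 or π/2 with no pseudo-counts; the MAF filter removes near-fixed
  sites before testing, so the boundary is rarely reached in practice.
* LRT values in [−1e-9, 0) are clipped to 0 (floating-point rounding of
  nested fits); anything more negative raises, as the closed forms
  guarantee nesting mathematically.
* χ² survival values that underflow to exactly 0 are clipped to the
  smallest positive double before BH adjustment.
* Output TSVs use 6-significant-digit formatting so identical runs are
  byte-identical.

## Site filters

Sites are retained when (i) they lie on the five major *D. melanogaster*
chromosome arms (2L, 2R, 3L, 3R, X); (ii) every pool reaches the depth
threshold (default 100) — applied per pool so the variance model is
well-behaved in each term, and easily switched to an aggregate rule;
(iii) the folded control-pool frequency reaches 0.05 in at least one
population — the control pools are used because they represent the
unselected populations. Dropped sites are attributed to the first rule
they fail, and per-rule drop counts are logged and returned.

## F_ST estimation

Differentiation is estimated from control pools only. The pool-seq
effective allele count n_e = 2NR/(2N + R) — the harmonic combination of
chromosomes sampled into the pool and reads sampled from it — replaces
the sample size in a two-level Weir–Cockerham-style ANOVA: with
per-population frequencies p_i and sizes n_i, the between-population
mean square MSP and within mean square MSI give

    a = (MSP − MSI)/n_c,     a + b = a + MSI,

with the usual unbalanced-design coefficient n_c. Genome-wide and
pairwise values aggregate the components as a ratio of sums
Σa / Σ(a+b); the mean of per-SNP ratios is reported alongside because
the two differ on heterogeneous data and the distinction matters when
comparing scans. Per-SNP estimates are *not* truncated at zero, so the
aggregation stays unbiased; sites with non-positive total variance
(monomorphic everywhere) report missing F_ST and are never flagged. The
high-differentiation flag is a strict fst > 0.15 comparison. Pairwise
standard errors come from a delete-one-block jackknife over contiguous
blocks of 500 SNPs in genomic order, which is robust to local linkage
disequilibrium.

A deliberate consequence of coverage-awareness: scaling all counts (same
frequencies, doubled claimed depth) shifts the estimate by the change in
the precision correction, ~(1/n_e − 1/n_e′); the estimator is exactly as
sensitive to the stated depth as the sampling model implies.

## The synthetic generator

The generator is the package's instrument for validating every stage
without external data. It emulates the target study design:

* **Structure** — Balding–Nichols: per-population control frequencies
  are Beta(p_a(1−F)/F, (1−p_a)(1−F)/F) around an ancestral p_a drawn
  uniformly from (0.05, 0.95) (so most sites pass the MAF filter).
  Default F = 0.005, the weak differentiation typical of wild
  *D. melanogaster* populations; one parameter, directly testable by the
  F_ST estimator. F = 0 degenerates to identical frequencies.
* **Effects** — additive on the z scale: the selected pool's true
  frequency is sin²(clamp(z_ctrl + δ, 0, π/2)). Effect patterns mirror
  the test models: null, parallel (one δ), group (δ_high, δ_low), free
  (per-population δ). Defaults: pools of 150 females, mean depth 130
  (within the 122–310x range of the motivating design), 4 populations
  (2 per exposure group).
* **Reads** — two-stage: chromosomes k ~ Bin(2N, p_true), then depth
  ~ Poisson(mean) truncated at ≥ 1 and ref reads ~ Bin(depth, k/2N).
  Depth truncation keeps frequencies defined; sites can still fail the
  depth-100 filter, mimicking real filtering.

What it does **not** model: linkage and recombination (SNPs are
independent, so window summaries and jackknife SEs understate real
spatial correlation), multi-generation selection dynamics, sequencing
error, reference bias, and X-vs-autosome dosage (pools are all-female,
so all arms are sampled as 2N chromosomes). Passing tests therefore
demonstrate correctness of the inference machinery under the stated
sampling model, not robustness to artefacts real data may carry.

## Problem sizes and calibration checks

Desk-scale validation uses 20,000 SNPs for null calibration and FDR
checks, 10,000 for F_ST recovery, and 2,000–5,000 for effect recovery
and end-to-end runs — large enough for the Monte-Carlo tolerances
asserted, small enough that the full suite runs in seconds.

Known limitation: the first-order variance 1/(8N) + 1/(4R) understates
the true variance of the plain arcsine transform by about 2% at
effective allele counts near 90 (mean null LRT4 ≈ 4.09 rather than 4.0;
empirical size ≈ 0.055 at nominal 0.05). A sensitive goodness-of-fit
test at 20,000 SNPs can detect this small defect in roughly half of
replicates. The practical consequence is mild anti-conservatism of the
raw p-values; the realized FDR of the BH screen in mixture simulations
stays near the nominal 10%. An Anscombe-type correction would remove
most of the bias but would change the method's stated transform and
variance, so it is not applied.

## Design choices that were genuinely open

* The depth filter is per pool (the aggregate-across-pools alternative
  is a one-line change); the MAF filter reads control pools only.
* Gene proximity uses gap distance to the nearest gene edge, strand
  ignored, adjacency = 1 bp; windows are anchored at position 1 of each
  arm.
* Window summaries emit every window from the arm start through the
  last SNP-bearing window, including empty ones, so adjacent-window
  comparisons are well-defined.
* The simulator places SNPs at fixed 200 bp spacing across the five
  arms: coordinates are plumbing for windows and jackknife blocks, and
  fixed spacing keeps runs reproducible.
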