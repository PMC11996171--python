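# Methods

This note documents the statistical models implemented in `parallelpy`,
the choices made where the design was genuinely open, and what the
synthetic-data generator does and does not emulate.

## The parallelism statistic 1/F

For each gene, the evolutionary response of evolved sample *j* of
population *i* is the log2 fold change against the mean ancestral
expression (CPM scale),

    X_ij = log2( CPM_ij / mean(CPM_ancestral) ).

Heterogeneity across populations is summarized by

    MS_pop = Σ_i (X̄_i − X̄)² / (P − 1)
    MS_e   = Σ_ij (X_ij − X̄_i)² / (N − P)
    F      = MS_pop / MS_e,        parallelism = 1/F.

`MS_pop` averages squared deviations of the population means without
the replicate-count multiplier of the textbook one-way ANOVA, so for a
balanced design F equals the classical statistic divided by R and its
null distribution is F(P−1, N−P)/R.  The package adopts this
mean-of-means convention throughout; because the design is balanced,
every downstream use (ranks, ln(1/F)) differs from the classical
convention only by a constant.  Genes with MS_e = 0 are flagged as
degenerate; genes with MS_pop = 0 get an infinite-parallelism sentinel
and are excluded from log-scale analyses with a logged count.

Log2FC uses CPM with a prior count of 0.5 (scaled per sample by
relative library size) so that a zero ancestral mean cannot produce
infinities; the 0.1-CPM expression filter, by contrast, uses prior-free
CPM to apply the stated rule literally.  Both choices are configurable.

## Normalization and dispersion

TMM factors follow the published defaults: reference sample = the one
whose 75th-percentile count fraction is closest to the mean; per-sample
factor = precision-weighted mean of gene-wise log2 ratios after
trimming 30% of M-values and 5% of A-values on each tail; factors are
renormalized to geometric mean 1.  The implementation is validated
against an independently written step-by-step oracle and against the
canonical R implementation on a composition fixture.

Per-gene biological variance (BCV² = NB dispersion φ) is estimated by
maximizing the Cox–Reid adjusted profile likelihood on a log-spaced
dispersion grid with quadratic refinement, then shrinking each
per-gene maximum toward the common dispersion with weight
n/(n + n₀), n₀ = 10 pseudo-individuals.  The Cox–Reid term (−½ log of
the Fisher information of the fitted means) removes most of the bias
from estimating the mean; at the study scale (20 individuals,
2000 genes, φ = 0.09) the mean estimate is unbiased to within the
simulation's bootstrap band.  The estimator is deliberately its own
documented procedure, validated by simulation rather than by matching
any particular package's output.

## Differential expression

Each evolved population is contrasted separately against the common
ancestral samples: per gene, an NB log-link GLM with a two-level
evolution factor, offset = log effective library size, and a fixed
tagwise dispersion estimated from the contrast's own samples under the
two-group model.  The evolution effect is tested by a 1-df likelihood
ratio test against χ²₁; p-values are BH-adjusted within the test.  The
FDR level defaults to 0.05 (configurable).  With only 8 samples per
contrast the per-gene dispersion is noisy and the χ² tail becomes
anti-conservative under weak shrinkage, so the DE path shrinks more
strongly (n₀ = 20) than the 20-individual panel estimator (n₀ = 10);
global-null simulations confirm the observed false-discovery
proportion stays at the nominal level under this setting.  Fitting is vectorized
Newton iteration on per-gene group intercepts, which keeps a
2000-gene × 35-sample dataset in the hundreds of milliseconds.

Putatively adaptive genes are those significant in the same direction
in at least 3 evolved populations (inclusive threshold); the replicate
frequency spectrum counts genes by their per-direction maximum number
of significant populations.

## Pleiotropy proxies

τ = Σ_i (1 − x_i/x_max)/(N − 1) over N ≥ 2 tissues; 1 − τ is the
tissue-breadth pleiotropy score.  Connectivity is the sum of incident
adjacency weights in an undirected reading of the regulatory network;
duplicate (a,b)/(b,a) rows are merged by summing once and self-loops
never count.  Genes missing from a source are excluded pairwise per
analysis, not listwise.

## Causal model selection and path analysis

The per-gene triple (Pa, A, Pl) = (ln 1/F, ln BCV², pleiotropy proxy)
is fitted under five Gaussian graphical factorizations (chain,
common-cause, full, independent-parents, full independence).  Every
factor has a closed-form MLE: marginals via mean and variance (÷n),
conditionals via OLS with residual variance RSS/n, giving per-factor
log-likelihood −(n/2)(ln 2πσ̂² + 1).  BIC = −2 ln L + k ln n with k
counting every mean, intercept, slope and variance:
k = {I: 8, II: 8, III: 9, IV: 8, V: 6}.  The MLE (÷n) variance
convention keeps −2 ln L internally consistent with the k counts; both
are configurable in principle and the k vector is exposed as a
constant.  Ties within 1e−9 resolve to the smaller k.  BIC fitting
uses the transformed (not standardized) variables; standardization
cannot change the selection because it only shifts each model's
log-likelihood by the same Jacobian constant.

Path analysis standardizes all three variables, then fits
Pa ~ A + Pl (β₁, β₂) and A ~ Pl (β₃).  Direct effect = β₂, indirect =
β₁β₃; on standardized data cor(Pl, Pa) = β₂ + β₁β₃ exactly, which is
asserted to 1e−10.  The indirect-effect CI is a seeded nonparametric
bootstrap (1000 resamples, percentile).  Pl is standardized but not
log-transformed; an optional ln(1+x) pre-transform for skewed
connectivity is available and off by default.

## Synthetic data: what it emulates

The generator mirrors the study layout: 5 pooled ancestral samples,
10 evolved populations × 3 biological replicates, two 20-individual
ancestral panels.  Ground truth is the latent triple (Pl, A, Pa) drawn
from one of the five graphs (Pl ~ N(0,1), unit-SD residuals; default
slopes a = −0.5, b = −0.4, c = +0.3, signs following the biology the
package models).  Observables are declared monotone links:

* individual-panel counts: NB with dispersion exp(A + ln 0.09), i.e. A
  is the log biological variance centered on a realistic BCV² of 0.09;
* evolved log2FC: shared adaptive shift ±(1.0 + |N(0, 0.5)|) per gene,
  population-level deviations with SD exp(−Pa/2) shared by replicates;
* tissue profile realizes 1 − τ = Φ(Pl) exactly; network realizes
  connectivity = exp(Pl) exactly when feasible.

Pooled-sample counts use a small constant dispersion (0.01): pooling
~50 individuals averages away individual-level biological variance,
and a constant keeps measurement error independent of A so the
estimated causal links reflect the planted ones rather than an
error-coupling artifact.  Mean expression is log-normal (median 200
counts, ln-SD 1); per-sample depth factors are log-normal (ln-SD
0.15).

The generator does not emulate read-level artifacts (GC/length bias),
gene-gene correlation, or single-cell structure, so passing recovery
tests demonstrate correctness of the estimators under the declared
model, not robustness to those real-data features.  The Pa → log2FC-SD
link is a convenient monotone choice (the statistic defines
parallelism only as ln 1/F), so recovery tests are rank-based
(observed rank correlation ≈ 0.8 between latent Pa and estimated
ln 1/F at the default noise).

## The polygenic simulation

A trait is the sum of four gene-level phenotypes controlled additively
by 5, 15, 30 and 50 unlinked loci of equal allelic effect, so a gene's
standing variance scales with its locus count — the locus-count
gradient stands in for the pleiotropy gradient (pleiotropic genes held
at lower variation by purifying selection).  Ten replicate populations
(N = 300 diploids) are founded by resampling 189 synthetic founder
haplotypes (per-locus frequencies from Beta(0.2, 0.2) conditioned on
polymorphism, linkage equilibrium) and evolve for 100 generations
under Gaussian stabilizing selection, fitness
w = exp(−(z − opt)²/2ω²), with the optimum shifted by one ancestral
trait SD and ω = 2 ancestral trait SDs.  Gametes are sampled with
probability proportional to parental fitness with free recombination.

Measurement mirrors the empirical pipeline: per population, three
measurement replicates (Gaussian noise, SD = 0.55 ancestral trait SD)
around the evolved gene mean; X_ij = change from the ancestral gene
mean; parallelism = 1/F.  Each experiment's founders are shared by all
100 runs; per run, one of the four genes is sampled and the Spearman
correlation between ancestral gene variance and ln(1/F) is reported.
The default experiment yields ρ ≈ −0.3 (negative in every founder
seed tried): genes with more standing variation respond less in
parallel because replicates distribute the optimum shift across the
redundant genes idiosyncratically, and the high-variance gene absorbs
the most idiosyncratic share.

ω and the measurement-noise scale are free knobs of the measurement
model, not estimated quantities; ω = 2 SD is a conventional moderate
stabilizing strength, and the noise default is set so that measurement
error contributes at a level comparable to the between-replicate
signal, which places the default experiment's correlation in the
moderate regime rather than the deterministic one.  Both are recorded
in every output header.  A per-locus-effect scaling of 1/n_loci
(equalizing gene contributions instead of locus effects) is *not* used:
under that scaling the 5-locus gene receives outsized per-locus
effects, sweeps quasi-deterministically for some founder draws, and
the variance–parallelism correlation becomes unstable in sign.

## Problem sizes used by the test suite

Unit and property tests run at reduced sizes chosen for statistical
resolution per check: null-distribution checks at 2×10⁴–10⁵ genes,
causal recovery at n = 5000 × 50 seeds, DE calibration at 1000–2000
genes × 50 null runs, end-to-end recovery at 1200 genes × 20 seeds,
and the polygenic experiment at its full default of 100 runs.

## Known limitations

* The DE model has a single evolution factor; batch or replicate
  covariates are out of scope.
* Dispersion shrinkage uses a fixed prior weight, not an estimated
  prior df; it is validated by simulation, not against any reference
  package.
* The causal machinery assumes Gaussian likelihoods after the stated
  transforms and compares only the five enumerated graphs.
* The simulator omits recombination maps, sex and epistasis, and its
  founder haplotypes are synthetic; quantitative agreement with any
  particular empirical correlation is therefore approximate by design.
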