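# Methods

## Scope

`scpipesim` benchmarks two-group differential-expression (DE) analysis
pipelines for single-cell RNA-seq by simulation: it estimates count-model
parameters from real (or fixture) data, simulates experiments with known
ground truth, runs natively implemented normalisation and DE-testing
stages, and scores each pipeline against the truth. Upstream quantification
(alignment, UMI collapsing) is out of scope; the package starts from a
genes x cells count matrix.

## Count model and estimation

Counts are modelled per gene as negative binomial, `var = mu + phi mu^2`
(`size = 1/phi`), with per-cell exposure offsets. UMI-based protocols are
treated as plain NB; full-length read-level protocols add per-gene zero
inflation (ZINB). The family is a caller flag, not a per-gene test: the
protocol, not the gene, determines whether extra zeros are needed.

Estimation (`estimation.estimate_params`):

- Cells are rescaled to the median library size before mean estimation, so
  means are on a counts-per-typical-cell scale.
- Dispersion is a per-gene profile maximum likelihood (mean plugged in),
  solved by vectorised bisection on the score function in log size, with
  method-of-moments initialisation. Genes where the score has no interior
  root keep the boundary/moment value and are flagged; moment estimates
  below the floor `1e-4` are clamped and flagged. The floor corresponds to
  effectively Poisson behaviour; the ceiling is `1e4`.
- Zero inflation is fitted by an EM (8 iterations) whose M-step reuses the
  weighted NB bisection; the mixing weight is initialised at the moment
  estimate of excess zeros (EM started exactly at zero cannot leave the
  boundary).
- Dropout is simply the observed zero fraction.

The mean-dispersion relation is a cubic smoothing spline of log2 phi on
log2 mean with the smoothing parameter chosen by generalised
cross-validation. Numerical choices: the scatter is collapsed to at most
400 weighted quantile-bin means before the GCV fit (GCV on thousands of
near-duplicate abscissae is ill-posed), evaluation clamps the abscissa to
the observed log2-mean range and the ordinate to the observed log2
dispersion range (no extrapolation, no overshoot where the abscissa is
sparse), and the 95% variability band is the fit +- 1.96 x a moving-window
(101 genes) residual SD.

## Simulation

A `DESetup` fixes group sizes, the DE fraction `p_de` in {0.05, 0.20,
0.60}, and the asymmetry pattern: symmetric (50% of DE genes
up-regulated), asymmetric (75%) or completely asymmetric (100%). The full
design grid is 3 sample-size configurations (96 vs 96, 384 vs 384, 50 vs
200) x 3 DE fractions x 3 patterns = 27 setups.

- |log2 fold change| ~ Gamma(shape = 1, rate = 2), i.e. exponential with
  mean 0.5 — "narrow" changes. The rate reading of the second parameter is
  configurable (`lfc_rate`), since shape/rate vs shape/scale is a genuine
  ambiguity; rate is the default because it yields the narrow distribution
  the design calls for.
- The whole fold change is applied to group 2; group 1 stays at baseline.
- Cell size factors ~ N(1, 0.1), truncated to positive values by redraw
  (the truncation mass is ~1e-23 at the default; the contract is total
  anyway).
- The dispersion used at a DE-shifted mean is the spline trend evaluated
  at the shifted mean **plus the gene's own residual from the trend**: at
  baseline each gene reproduces its estimated dispersion exactly, and
  shifted means follow the protocol's mean-variance relation without
  discarding gene-level scatter.
- Exactly `round(p_de * G)` genes are flagged DE, `ceil(up_frac * n_de)`
  of them up-regulated; assignment over genes is randomised.

Spike-ins: 92 synthetic transcripts with known molecule counts. Per cell a
capture efficiency is drawn log-normally (CV = capture_sd/capture_mean)
and multiplied by the cell's true size factor — spike counts therefore
carry the depth signal and *only* the depth signal (no biological DE),
which is what makes spike-in normalisation informative. Counts per spike
are NB with a small technical dispersion.

Sequencing-depth experiments: `thin_counts` applies independent
binomial thinning Binomial(c, p) per entry; `reconstruct_umis` maps a
read-thinning rate p to UMI survival using a per-gene reads-per-UMI model
with mean equal to the estimated amplification rate. The default model is
a shifted Poisson, r ~ 1 + Poisson(amp - 1), giving survival
`1 - (1-p) exp(-(amp-1) p)`; a fixed-depth model (`1 - (1-p)^amp`) is
available via `model="fixed"`. The true reads-per-UMI distribution is
protocol-specific, so the model is pluggable.

Seed discipline: every run is addressed by a sub-seed derived from
(master seed, setup label, bundle, replicate) through SHA-256, below 2^31;
identical descriptors reproduce bit-identical datasets and score rows.

## Normalisation

All size factors are *full* per-cell factors standardised to geometric
mean 1 — the gauge in which they are comparable to the simulated truth.

- **MR** (median-of-ratios): reference = per-gene geometric mean over
  cells, genes with any zero excluded; factor = median ratio. The
  **positive counts** variant computes the geometric mean over positive
  entries only and takes each cell's median over genes where both the
  count and the reference are positive, making it usable on sparse data.
- **TMM**: reference cell chosen by the upper-quartile rule; per pair, a
  doubly-trimmed (30% on M, 5% on A) precision-weighted mean of M-values;
  the composition factor is combined with library size. Fewer than 10
  doubly-positive genes for a pair yields factor 1 with a warning.
- **Deconvolution**: within each (optional) cluster, cells are ring-ordered
  by library size (ascending odds, descending evens, so neighbours are
  similar) and summed into pools of sizes {21, 41, 61, 81, 101} (capped at
  the cluster size) over all rotations. The median ratio of each pool
  profile to the cluster pseudo-cell (genes with pseudo-cell mean >= 0.1)
  gives one equation `sum_{j in pool} sf_j = ratio`; low-weight per-cell
  anchor equations towards library-size ratios keep the least-squares
  system well conditioned (within a cluster there is no composition bias,
  so the anchor is unbiased). Rank-deficient systems get a ridge term and
  a flag; non-positive solutions are floored and reported as failed cells.
  Cluster factors are rescaled through median ratios of cluster
  pseudo-cells to the global pseudo-cell.
- **Clustering**: Ward linkage on the top 10 principal components of
  log-CPM over the 2000 most variable genes, cut at n_cells/min_size
  clusters, with undersized clusters merged into the nearest centroid
  until every cluster has >= 100 cells. (A rank-correlation distance was
  tried first and could not separate DE groups on sparse data; the PC
  recipe is the field's standard and separates them cleanly.)
- **Spike-in factors**: proportional to each cell's total spike count;
  zero-total cells get factor 1 and are flagged.

Preprocessing applies *only* to size-factor estimation: `filter` drops
genes with more than 80% zeros (threshold configurable; all-zero genes are
always dropped), `impute` delegates to a registered plug-in (an imputer is
any callable counts -> dense matrix of the same shape). DE testing always
uses the raw counts with the externally supplied factors.

## DE testing

Tests run on log2 CPM, `y = log2((c + 0.5) / (L_j + 1) * 1e6)` with
effective depth `L_j = sf_j x mean library size` (the factors are full
size factors, so multiplying by the raw per-cell library size would count
depth twice).

- **Welch t**: per-gene two-sided t with Satterthwaite df; genes with zero
  variance in both groups report p = 1.
- **Trended moderated t**: per-gene residual variances s^2 with d = n - 2
  df; a lowess trend (span 0.4) of log s^2 on average expression defines
  the prior variance s0^2(abar); the prior df d0 solves
  `trigamma(d0/2) = var(log s^2 - trend) - trigamma(d/2)` (moment matching
  of the scaled-F distribution of s^2/s0^2; non-positive excess variance
  means d0 = infinity, i.e. complete shrinkage, flagged). Posterior
  variances `(d0 s0^2 + d s^2)/(d0 + d)` feed a t with d + d0 df.
  `prior_df=0` recovers the ordinary pooled t exactly; `prior_df=inf`
  shares the trend variance.
- Benjamini-Hochberg adjustment throughout, nominal level 10%.

Moderation matters when residual df is scarce: at 5 vs 5 cells it
dominates Welch in pAUC; at 50+ cells per group the two tests coincide to
within noise (both behaviours are asserted in the test suite).

## Evaluation metrics

- Confusion at q < alpha: TPR = TP/(TP+FN) (0 if nothing is truly DE),
  FDR = FP/(FP+TP) (0 if nothing is discovered).
- TPR-vs-observed-FDR curve at every distinct p-value cutoff (ties share
  a point).
- **pAUC**: trapezoidal area of TPR over observed FDR restricted to the
  controlled region — the largest prefix of cutoffs whose running-maximum
  observed FDR stays <= 0.1 — normalised by 0.1. The last attained TPR is
  constant-extended to 0.1 (disable with `extend=False`), so
  over-conservative methods are not penalised; an empty controlled region
  scores 0.
- **max MCC**: the maximum Matthews correlation over the same controlled
  cutoff prefix; a zero denominator defines MCC = 0; an empty region
  reports 0 with a flag. Rescaled to [0,1] via (MCC+1)/2.
- **Size-factor RMSE**: both vectors standardised to geometric mean 1; an
  intercept-only Huber M-estimator (tuning 1.345) is fitted to the
  differences and the RMSE is the Huber-*weighted* RMS residual
  `sqrt(sum w r^2 / sum w)`. The weighting is what makes the metric
  robust in substance: isolated gross failures (e.g. cells where a method
  fell back to factor 1) are down-weighted instead of dominating the
  score, while for well-behaved difference vectors all weights are 1 and
  the value is the plain RMS deviation.

## Contribution analysis

Rescaled MCC scores are squeezed into (0,1) with
`y' = (y (n-1) + 0.5)/n` (n = number of scores entering the regression)
and modelled by beta regression with log-log mean link
`g(mu) = -log(-log mu)` and constant precision (fitted on the log scale).
Pseudo-R^2 is the squared correlation of g(y) and g(mu_hat). Each pipeline
step's contribution is the pseudo-R^2 drop when that covariate is left
out, also reported as a percentage of the full model's R^2. Non-convergent
reduced models yield a missing (not zero) contribution; negative drops
(possible, since pseudo-R^2 is not monotone in nested fits) are reported
as-is with a flag; rank-deficient designs raise an error naming the
collinear columns.

## Fixture bundles (the study conditions)

`make_fixture` replaces protocol estimates from real data:

- `umi_like` (NB): gene means log2-normal(1, 2.2) — median ~2 counts per
  cell with a heavy right tail, so a few hundred genes are expressed
  highly enough to serve as zero-free references at 768 cells, as in real
  UMI data; dispersion trend `phi = 0.1 + 1.5/mu` with log2-normal scatter
  (sd 0.25) — overdispersion decays with expression towards a plateau of
  ~0.1; dropout = the NB zero probability.
- `readlevel_like` (ZINB): higher dispersion trend `phi = 0.3 + 3/mu` and
  zero inflation `zi = 0.6 exp(-mu/4)` — extra zeros concentrated at low
  expression, vanishing for highly expressed genes.
- Spikes: 23 log2-spaced concentration levels (2^-2 .. 2^11 molecules) x 4
  spikes = 92, capture mean 0.1 with 2% cell-to-cell CV, technical
  dispersion 0.005; expected spike total ~2,300 counts per cell.

What the fixtures emulate: the mean-dispersion-dropout structure, library
size variation, DE asymmetry and spike-in behaviour that drive the
benchmark's conclusions. What they do not emulate: gene-gene correlation,
batch effects, more than two groups, cell-type substructure beyond the two
simulated groups, amplification-noise artefacts of specific protocols, and
the detection-rate differences between aligners/annotations. Passing tests
therefore validate the machinery and the qualitative phase diagram (where
normalisation breaks and what restores it), not any quantitative claim
about a particular real protocol.

## Problem sizes used in tests and the acceptance script

Benchmark-level checks run at the design's reference scale — 10,000 genes,
384 vs 384 cells — with 5 seeds for the FDR phase diagram, 3 seed-matched
pairs for the good-vs-naive comparison, and 20 seeds for the
contribution-recovery check; unit tests use 500-5,000-gene bundles. These
sizes give stable means (the asserted margins are several times the
seed-to-seed spread) at about a minute of total compute for the
acceptance script.

## Known limitations

- Strict MR requires zero-free genes; on very sparse matrices it errors by
  design (use the positive-counts variant).
- TMM is exactly scale-equivariant only without composition noise; its
  precision weights depend on library sizes, so rescaling one noisy cell
  moves its factor by ~1-2%.
- The deconvolution anchor equations assume within-cluster homogeneity; if
  clustering fails to separate genuinely distinct populations the anchor
  inherits the composition bias of library size.
- d0 estimation for the moderated test uses a fixed lowess span (0.4); very
  small gene sets (< ~200) make the trend and d0 noisy.
- The beta-regression model is additive (no interactions), matching the
  benchmark design it serves.
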