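# Methods

This note documents the models implemented in `microdrivers`, the
defaults that matter, what the synthetic-data generator does and does
not emulate, and the numerical choices made where the design was open.

## Data model and preprocessing

The universal input is an ASV × sample table of non-negative integer
counts with per-sample metadata (state ∈ {BT, AT}, subject id,
covariates) and optional taxonomy strings. Filtering keeps an ASV when
it is detected (count > 0) in at least `min_prevalence` (default 0.20)
of samples **or** its mean relative abundance exceeds
`min_mean_relabund` (default 0.025). The OR combination reflects the
usual intent of such filters — retain both prevalent taxa and rare but
locally dominant ones; both thresholds are logged and the filter is
applied to the pooled table before any per-state split. Presence is a
plain nonzero count: ASV tables are denoised, so no pseudo-detection
threshold is used.

TMM normalization follows the canonical recipe: reference sample = the
one whose upper-quartile count fraction is closest to the mean
(lexicographic tie-break on sample id), per-sample scale factor = the
inverse-asymptotic-variance weighted mean of M-values after trimming
30% of each M tail and 5% of each A tail, factors rescaled to geometric
mean 1. Samples sharing no nonzero taxon with the reference get factor
1 with a warning.

## Diversity and ordination

Shannon diversity uses the natural logarithm (emitted in output
headers). Rarefaction curves are the analytic expectation
E[S_d] = Σᵢ [1 − C(N−nᵢ, d)/C(N, d)], evaluated with log-gamma and
clipped to [0, min(richness, d)] against round-off. Bray–Curtis is a
semimetric; no triangle inequality is assumed. PCoA is classical
scaling of the double-centered Gower matrix; axes come from positive
eigenvalues only, negative eigenvalues are reported unaltered (no
Cailliez correction). NMDS minimizes Kruskal stress-1 by iterative
majorization with monotone regression (best of `restarts`
initializations; seeded); taxon scores are abundance-weighted averages
of sample coordinates. PERMANOVA permutes labels freely by default,
matching an unrestricted one-way analysis; because BT/AT samples are
paired by subject, a `strata` option restricts permutations within
subject for a paired test. p-values use the
(1 + #{F* ≥ F})/(1 + permutations) convention throughout the package.

## Assembly inference

**Neutral model.** For each taxon, mean relative abundance p̄ and
occurrence frequency f are computed; the neutral prediction is
F̂(p̄) = 1 − I_d(Nm·p̄, Nm·(1−p̄)) with detection limit
d = 1/mean(library size) (standard practice when depths vary;
configurable). N·m is fitted by Levenberg–Marquardt least squares in
log(Nm) after a coarse grid search over 10⁰–10⁵ (stabilizes the local
optimizer). Goodness of fit is R² = 1 − SSE/SST computed on
frequencies, never counts. The 95% prediction band is the Wilson
binomial interval of F̂ at n = sample count; taxa are labelled
above/within/below. Fits are run per state, mirroring a BT-vs-AT
contrast. Parameter recovery on neutrally simulated cohorts (N·m = 500,
50 samples, 300 taxa) returns the truth within ±25% with R² > 0.9.

**Niche breadth.** Levins B = 1/Σⱼ(nᵢⱼ/Nᵢ)² ∈ [1, #samples]. Classes
come from comparing B to the 2.5/97.5 percentiles of a fixed-marginal
null. The null is sampled by independent sequential multivariate
hypergeometric fills (the `r2dtable` scheme), not by a unit-swap MCMC:
swap chains mix extremely slowly at realistic count totals (thousands
of units per row), which makes percentile bands incoherent, whereas the
hypergeometric fill draws exact independent samples from the same
independence-given-margins null. Calibration: a table drawn from that
null is classed ≈95% neutral. Note the null conditions on margins, so
data with genuine overdispersion (e.g. Poisson or log-normal noise)
legitimately classifies many taxa as specialists — that is signal, not
miscalibration.

**C-score.** Observed C = mean over species pairs of
(rᵢ−Sᵢⱼ)(rⱼ−Sᵢⱼ). The null preserves both marginals exactly via
sequential 2×2 checkerboard swaps: 5,000 burn-in attempts, then one
saved matrix every 100 attempts (standard mixing guidance;
configurable), 1,000 null matrices by default. SES and a two-sided
empirical p are reported; positive SES means segregation. Matrices
without any checkerboard submatrix raise a degenerate-matrix error.

## Networks

**SparCC.** Per iteration, fractions are drawn from a per-sample
Dirichlet posterior (counts + 1), the log-ratio variation matrix
T is formed, and basis variances solve the linear system implied by
the sparsity assumption; the strongest still-included pair with
|ρ| above 0.1 is excluded and the system re-solved, up to 10 rounds.
The estimate is the element-wise median over 20 iterations, clipped to
[−1, 1]. These defaults follow the method's canon. Edge p-values come
from tables with each taxon's counts independently permuted across
samples (destroying association, preserving marginals), two-sided on
|ρ|; null tables use 5 inner iterations by default for speed, which
only adds noise to the null and is configurable.

**Edge rule and modules.** Edges require |ρ| > 0.3 (strict) and
p < 0.05. Absolute value is used although a signed mode exists:
negative associations are ecologically meaningful. Isolated nodes are
dropped. Modules come from greedy agglomerative modularity
maximization on absolute weights; Q is reported. Metrics: average
degree 2E/N, density 2E/(N(N−1)), average shortest-path length over
connected pairs, mean normalized betweenness.

**Indicator species.** IndVal_ik = A·B with A the state-specificity of
mean abundance and B the within-state occurrence fraction; p by state-
label permutation (10,000 by default).

**BT-vs-AT comparison.** On the union of nodes present in either
network, each node x with BT neighbor set A and AT neighbor set B gets:
shared = |A∩B|, exclusive = |B∖A|, Jaccard = |A∩B|/|A∪B|, and

    NESH(x) = |B∖A|/|B| + |B∖A|/|A∪B| + |B∖A| / max_y |B_y∖A_y|

The first two terms are the node's case-exclusive neighbor fraction and
its union-normalized exclusivity; the third scales the node's absolute
exclusivity against the network-wide maximum, a network-level
normalization chosen here because the published variants of the score
differ in this constant. Different admissible constants reorder nothing
within the monotone components, and driver calling depends only on the
quantile rank of NESH. DelBet is normalized betweenness in AT minus BT;
positive values are rescaled so the maximum is 1 (matching the
convention of reporting the strongest gainer as 1.000; a flag
disables this). Drivers = nodes at or above the 0.9 NESH quantile ∪
nodes with DelBet > 0. A "core (AT)" column counts a node's AT
neighbors sharing its AT module; it is reported but never used in
driver calling.

## Models

**Classifier.** Features are TMM-normalized abundances z-scored per
feature. The forest is explicit bagging over sklearn decision trees
(sqrt feature subsampling, 500 trees, stratified 80/20 split): explicit
bagging is used so MDA can be computed the classical way — each tree's
out-of-bag accuracy drop under per-feature permutation, averaged over
trees — which the stock forest API does not expose. MDG is the mean
per-tree impurity decrease. AUC uses the Mann–Whitney rank statistic
(ties count ½) on the held-out split only; everything is reproducible
from one seed.

**Regression.** The covariate screen fits a Gaussian working model on
log1p counts for every subset (≤ 15 covariates) and reports adjusted
R²; final inference uses a log-link NB2 negative-binomial fit —
Fisher-scoring IRLS for the mean with a Pearson method-of-moments
update for the dispersion α (variance = μ + αμ²), iterated to joint
convergence. The fit is written directly (rather than calling a
packaged MLE) because bootstrap calibration requires ~2·10⁵ refits;
it agrees with the reference MLE to ~10⁻³ in coefficients and reduces
exactly to Poisson IRLS at α = 0. Term significance is a case-
resampling bootstrap: p = 2·min(#{β* ≤ 0}, #{β* ≥ 0}) with the
(1 + extreme)/(1 + B) convention; percentile 2.5/97.5 intervals are
reported. 9,999 resamples in faithful mode; 999 by default for
desk-scale runs. Empirical coverage of the 95% interval at n = 200 is
94–96%.

## Synthetic cohorts

`simulate_neutral_community` draws each sample's composition from
Dirichlet(Nm·source) — whose marginals are the Beta distributions of
the Sloan model — and counts from a multinomial at a negative-
binomially drawn library size (mean 29,319 reads, NB shape 10; real
per-subject depth variance is unreported, so the shape is a free
parameter). `simulate_paired_cohort` gives each taxon a log-normal
baseline (log-sd 2), adds N(0, 0.8²) within-state noise on the log
scale, and layers plants on top: differential taxa (log2FC added in
AT), correlation modules through a shared subject-level latent factor
(Gaussian copula — correlation is induced on the latent normal scale,
so count marginals are preserved) active only in their designated
state, indicator taxa zeroed outside their state, and covariate
effects entering the focal taxon's log-mean linearly in the z-scored
covariate. Planted taxa are lifted to at least the community's median
baseline abundance: plants emulate effects on major, filter-surviving
taxa, and a 4-fold effect on a major taxon should be detectable at
n = 25/25 (BH rank-sum), which fixes the admissible noise scale — the
0.8 default sits at the typical short-interval test-retest variability
of taxon log-abundance. Covariates: age uniform on 18–70, adult-male
anthropometrics, education and three habit variables ordinal, three
habits Bernoulli. Column sums equal drawn library sizes exactly; one
seed determines everything; the truth object carries every plant.

What the generator does **not** emulate: read-level error or chimeras,
phylogenetic structure, taxon-specific depth biases, subject-level
covariance between states beyond the planted structure, and zero
inflation beyond what multinomial sampling of log-normal compositions
produces. Passing recovery tests therefore demonstrate correctness of
the estimators under a realistic compositional count model, not
robustness to every artifact of real amplicon data.

## Pipeline

`run_pipeline` chains simulate/ingest → filter/normalize → diversity →
assembly → networks → NetShift → models, writes per-stage TSVs, a
resolved `config.yaml` and a `summary.json`. One global seed is fanned
out per stage as (seed·1009 + offset) mod 2³¹ with fixed offsets, so a
single integer reproduces the whole run. Stage failures keep partial
outputs and name the stage; a missing input exits with a distinct code.
Default problem sizes for simulated runs (150–2,000 taxa, 50 samples,
100 edge bootstraps, 999 permutations) keep a full run in the
tens-of-seconds to minutes range on one core.

## Known limitations

* The NESH network-level normalization constant is a documented choice
  among published variants; absolute NESH values are comparable within
  a run, not across tools.
* SparCC edge p-values are pseudo-p-values from a finite permutation
  null; with 100 bootstraps the smallest attainable p is 1/101.
* PERMANOVA's unrestricted default ignores subject pairing; use
  `strata` for the paired design.
* The NB bootstrap is case-resampling, which assumes exchangeable
  observations; it does not model within-subject correlation.
* The C-score swap null counts attempts, not accepted swaps; extremely
  sparse or full matrices mix slowly and may need larger thinning.
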