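# Methods

This note documents the statistical models and procedures implemented in
`rootfungi`, the numerical choices behind them, what the synthetic-data
generator does and does not emulate, and the problem sizes used by the test
suite and the reproduction script.

## Data model and filtering

Community data are integer count matrices (samples × OTUs) with root-tip and
bulk-soil samples kept in separate tables; metadata attach a sampling
position, planar coordinates in metres, a habitat kind (`root`/`soil`) and —
for root samples — a host-plant genus to every sample.  The standard
filtering sequence before analysis is:

* root samples with fewer than 1,000 reads and soil samples with fewer than
  5,000 reads are discarded (`filter_low_depth`; ≥ keeps the boundary);
* root samples at positions without a soil sample are dropped when soil
  covariates are required;
* root samples of host plants with fewer than 30 root samples are dropped
  (15 in the supplementary-covariate mode of `prepare_inputs`);
* OTU-level occurrence filters are applied per analysis (e.g. ≥ 30 root
  samples for the preference statistics; ≥ 30 root and ≥ 15 soil samples for
  the habitat surface).

## Coverage-based rarefaction

Sample coverage is the Chao–Jost estimator
C = 1 − (f₁/n)·[(n−1)f₁ / ((n−1)f₁ + 2f₂)], with n the read depth and f₁, f₂
the singleton/doubleton counts.  `coverage_rarefy` subsamples each sample
without replacement (one hypergeometric draw, seeded) to the smallest depth
m whose *expected* coverage reaches the common target; for m < n the
expectation has the closed form 1 − Σᵢ (xᵢ/n)·C(n−xᵢ, m)/C(n−1, m), at m = n
the Chao–Jost estimate is used.  The default target is the minimum
full-depth coverage across samples, and samples sitting at that minimum are
returned unchanged by rule (the interpolated coverage curve is discrete and
can otherwise reach the target a few reads early).  An explicit target of 0
degenerates to depth-1 subsamples.

## Ordination and spatial eigenvectors

PCoA is classical scaling of the double-centred −½d² matrix.  Negative
eigenvalues (Bray–Curtis is semimetric) are dropped without Cailliez/Lingoes
correction, and the cumulative contribution is computed over positive
eigenvalues only; axes are retained until it reaches the configured
threshold (0.90 for the soil covariate block).  Spatial eigenvectors are the
principal coordinates of the sampling positions' Euclidean distance matrix
(double-centred, positive-eigenvalue columns, descending).  For a planar
design this yields exactly two columns — an orthogonal, zero-mean rotation
of the coordinates; the construction is deliberately truncation-free, and
the number of columns used downstream is configurable.

## Joint species distribution model

Occurrences are modelled as a multivariate probit with shared latent
factors:

    P(y_is = 1 | u_i) = Φ(α_s + x_i'β_s + λ_s'u_i),   u_i ~ N(0, I_r).

The marginal likelihood integrates u out per sample.  It is estimated by
Monte Carlo with **common random numbers**: a fixed set of M standard-normal
draws (seeded) shared across samples and across optimizer iterations, so the
objective is a smooth deterministic function and fits are bit-reproducible
given (seed, M, optimizer settings).  Gradients are exact for the MC
objective (posterior-weighted probit scores) and the optimizer is L-BFGS on
all parameters jointly.  Numerical choices:

* log-probabilities are computed with `log_ndtr` and clipped at log(1e-12);
  clipped cells contribute zero gradient;
* a ridge of 1e-6 on non-intercept coefficients and loadings keeps
  separation finite; its effect on well-posed problems is below the 1e-4
  oracle-agreement tolerance (verified against an unpenalized IRLS probit);
* models without the Cov term have r = 0 and M = 1: the likelihood is the
  exact Bernoulli likelihood and the model factorises into independent
  probit regressions;
* latent-factor models are initialised from the coefficients of the
  corresponding factor-free fit with near-zero loadings, so training
  log-likelihood is non-decreasing along every nesting edge of the model
  lattice up to Monte Carlo error;
* defaults: r = 8 latent factors and M = 100 for fitting, M = 1000 for
  reported log-likelihoods (the scaled-down experiments below use r = 2 and
  M = 40/400).

**Per-OTU log-likelihood decomposition.**  The joint LL of a latent-factor
model does not factorise over OTUs.  The reported per-OTU vector is the
posterior-weighted expected per-OTU log-Bernoulli term plus an equal per-OTU
share of the factor-mixing entropy gap, which sums exactly to the joint MC
log-likelihood; the equal share shifts every OTU in a model comparison by
the same constant, so OTU and guild *rankings* are unaffected.  For r = 0
the decomposition is the exact Bernoulli one.

**Model lattice and factor attribution.**  All 16 subsets of
{P, S, Sp, Cov} are fitted ("Full (P + S + Sp + Cov)" … "Null", the null
model fitting only intercepts; models without P/S/Sp but with Cov retain the
intercept).  Factor contributions are per-OTU log-likelihood ratios between
fixed pairs: P, S and Sp are each attributed by comparing `P + S + Sp`
against the model dropping that one factor, never against the full model
(residual covariance may soak up unmeasured environment); Cov is attributed
by `Full` against `P + S + Sp`.  Guild differences in the per-OTU ratios are
tested with all-pairs Steel–Dwass–Critchlow–Fligner comparisons (average-rank
ties, studentized-range calibration with k groups and infinite df, guilds
with ≥ 5 OTUs) — the multiplicity control is inherent to the studentized
range; no extra FDR layer is added.

**Fitted probabilities and AUC.**  `predicted_probabilities` offers marginal
(prior-integrated) and posterior (conditioned on the sample's occurrence
vector) fitted values; the latter is the default in-sample notion, as for
any mixed model.  The AUC pools all (sample, OTU) cells.  Pooled AUC mixes
between-OTU prevalence differences into the score: on global-null data an
intercept-only model already reaches ≈ 0.63, so in-sample optimism is
assessed against that prevalence-only baseline, not against 0.5.

## Host-preference statistics

For the bipartite matrix N(i, j) (root samples containing OTU i on plant j),
the specialization of row i with total Aᵢ against availability qⱼ = Aⱼ/m is

    dᵢ = Σⱼ p′ᵢⱼ ln(p′ᵢⱼ/qⱼ),   p′ᵢⱼ = N(i,j)/Aᵢ,
    d′ = (dᵢ − d_min)/(d_max − d_min) ∈ [0, 1],

where d_min/d_max are the exact extremes over integer redistributions of the
Aᵢ interactions with cell caps at the column totals.  Both bounds are
computed exactly:

* d_min — proportional apportionment polished by single-unit exchanges; the
  objective is separable convex, so exchange-local minima are global;
* d_max — vertex enumeration: a convex maximum has at most one partially
  filled column, and since qⱼ ∝ capⱼ every fully-filled column contributes
  ln(m/Aᵢ) per interaction, d_max reduces to a subset-sum problem solved
  with boolean knapsack tables (validated against exhaustive enumeration for
  small totals).

Because the bounds are integer-granular they relax slightly as the whole
matrix is scaled by an integer factor; d′ is invariant up to this
discretisation term, which vanishes for large matrices.

**Permutation null.**  Host labels are shuffled only among root samples from
the same sampling position (10,000 permutations by default), preserving each
position's host multiset.  Every randomized matrix is scored against **its
own marginals**: the plant column totals are richness-weighted sums over
samples and change under the shuffle, so availability and the d′ bounds are
recomputed per permutation (freezing them at their observed values biases
the null; the engine caches the subset-sum tables on the column-total
vector, which makes the invariant transposed problem — plants' preference
for fungi — nearly free).  The standardized score is
z = (d′_obs − mean(d′_perm))/sd(d′_perm); two-tailed p-values use
permutation ranks of d′ with the (#exceedances + 1)/(n_perm + 1) convention,
and q-values are Benjamini–Hochberg.  A degenerate null (sd = 0, e.g. all
positions monocultures) yields score 0 with an explicit flag.  The
two-dimensional pair preference applies the same z construction to each
N(i, j) cell and shares the permutation stream with the d′ statistic for
equal seeds.

## Habitat preference and spatial autocorrelation

The habitat surface reports, per OTU passing the occurrence filters, root
and soil detection counts and the mean log₁₀ relative read proportion over
the samples where the OTU occurs.  The soil-coupling GLM has Poisson errors
and log link: the response is the count of root samples containing the OTU
per (position × host genus), the offset is the log of the number of root
samples of that genus at that position, and the predictors are host genus
dummies plus the log₁₀ soil relative abundance at the position (pseudocount
= half the smallest positive proportion).  The soil coefficient is
standardized by multiplying with the predictor's standard deviation; a
constant predictor is dropped with coefficient 0 by convention, and
non-convergence is flagged rather than raised.

The Mantel correlogram pools root samples to position-level presence/absence
(idempotent), computes the Jaccard matrix between positions, bins pairwise
geographic distances into equal-width classes (Sturges' rule by default) and
reports per class r_c = −cor(D, 1[pair ∈ class]) — positive r means similar
communities within the class.  p-values come from shuffling position
identities (two-tailed, same (+1)/(n+1) convention), q from BH across the
retained classes; classes with fewer than two pairs are dropped with a
warning.  Guild-restricted correlograms subset the OTU columns first.

## Sparse + low-rank association networks

Un-rarefied counts are CLR-transformed (log(x+1), row-centred; pseudocount
configurable) and summarised by their empirical **correlation** matrix
(scale stability).  The estimator solves

    min −logdet(S−L) + tr(Σ̂(S−L)) + λ‖S‖₁,offdiag + γ·tr(L),
    s.t. S−L ≻ 0,  L ⪰ 0

by ADMM with closed-form updates (eigendecomposition for the logdet block,
off-diagonal soft threshold for S, eigenvalue shrinkage + PSD projection for
L; ρ = 2, tolerance 1e-7, 800 iterations, non-convergence flagged).  γ is
bisected until rank(L) hits the requested target, ties resolved toward the
smaller γ (the larger latent part); rank 0 bypasses L and reproduces the
plain graphical lasso (agrees with an independent coordinate-descent
implementation to 1e-4).  λ is chosen on a fixed log path as the densest
value whose rank-0 graph stays at or below a 5 % edge-density ceiling; no
stability selection is attempted.  The latent dimension is selected by

    BIC = n·[−logdet Θ̂ + tr(Σ̂Θ̂)] + ln(n)·[|E(S)| + r·p − r(r−1)/2]

over ranks 0–20.  Edges are off-diagonal S entries above 1e-8, reported as
partial correlations ρ_uv = −S_uv/√(S_uu S_vv); positive and negative
subnetworks are analysed separately, AMF–AMF pairs are flagged (their
co-occurrence signal can reflect multi-genome biology rather than
interaction), Louvain modules (resolution 1, seeded, via networkx) are
computed on the positive network, and concordance of degree centrality with
the jSDM Cov attribution uses Kendall τ-b.

## Synthetic study conditions

The generator emulates the sampling design: positions on a jittered grid
guaranteeing ≥ 4 m spacing (cell 1.5×, jitter 0.25× the spacing), ten woody
host genera with spatially clumped assignment probabilities (per-genus
Gaussian hotspots, 25 m clump range), a Poisson number of root samples per
position (mean 13 at full scale) and one soil sample per position.  Each
OTU belongs to a guild archetype that sets the scales of four generative
effects on the occurrence probit: per-(OTU, plant) host shifts
(plant_effect_sd), coupling to the OTU's standardized latent soil field
(soil_coupling), a Gaussian-process spatial field with exponential
covariance (spatial_sd, spatial_range in metres; exact Cholesky simulation),
and loadings on r shared latent factors (factor_loading_sd).  Baseline
prevalences are drawn uniformly (0.05–0.45 at full scale).  Read counts for
present OTUs are multinomial over lognormal abundances with
negative-binomial depths (root mean 2×10⁴, soil mean 10⁵, size 2 — plausible
MiSeq magnitudes, configurable).  Defaults mirror the field contrast:
EcMF-like fungi strongly soil-coupled and spatially structured with no host
filtering, endophyte-like fungi dominated by latent-factor covariance,
AMF-like fungi strongly host-filtered.

The copula network generator plants a sparse symmetric precision part
(diagonally dominant; edge partial correlations ≈ 0.2 at the default edge
strength 0.4) minus a deliberately strong rank-r confounder (orthonormal
loadings, equal eigenvalues at 0.9 of the sparse part's smallest eigenvalue)
and maps latent Gaussians to counts by per-OTU negative-binomial quantile
transforms.

**What the generator does not emulate:** read-level error, chimeras,
contamination and PCR/primer bias; taxonomy and guild mis-assignment;
abundance–occurrence coupling beyond presence (abundances are lognormal
i.i.d. given presence); temporal variation; unequal OTU richness between
root and soil pools.  Passing tests therefore demonstrate that the
estimators recover the stated structures under a faithful but idealised
sampling design — not that real sequencing artefacts are handled.

## Problem sizes used by the tests and the reproduction script

The package's evaluation experiments run at deliberately scaled-down study
conditions:

* *null preset* — the full 124-position design, 60 OTUs, all generative
  effects zero; preference calibration uses 50 replicates × 1,000
  permutations in the acceptance tests (30 × 800 in the script), the Mantel
  calibration 100 × 1,000 (60 × 600 in the script);
* *assembly preset* — 75 positions (~300 root samples), 40 OTUs in three
  guild archetypes, r = 2 latent factors; recovery aggregates 20 seeded
  replicates in the tests (12 in the script) with M = 40 fitting draws and
  400 evaluation draws;
* *network preset* — p = 50 OTUs, n = 500 samples, 40 true edges, rank-3
  confounder; BIC scans ranks 0–20 over 10 replicates in the tests (6 in
  the script).

## Known limitations

* The Monte Carlo likelihood with common random numbers is biased upward by
  the log of an average over finitely many draws; comparisons between models
  evaluated with the same draws are much more accurate than absolute values,
  and only orderings should be interpreted.
* Absolute jSDM log-likelihoods depend on r, M and the ridge; they are not
  comparable across software.
* The equal-share entropy term in the per-OTU decomposition is a convention;
  alternative decompositions shift all OTUs of a model pair equally but
  would change per-OTU absolute values.
* The SLR λ is fixed by an edge-density ceiling, so absolute edge counts are
  a function of that ceiling; only relative comparisons (e.g. latent vs
  rank-0 edge counts) are meaningful.
* Steel–Dwass p-values use the asymptotic studentized-range calibration;
  for very small guilds they are approximate.
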