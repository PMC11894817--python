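# Methods

## Model

`conntraj` fits a clustering-enabled regression to edge-valued brain
networks.  Each of R regions carries a latent cluster label
m_i ∈ {1..K}; the connectivity of edge (i, j) for subject s at site d is

    F_ij^(d,s) = Σ_{l=1..5} B_{l, k(i)k(j)} x_{sl} + ε_ij^(d,s),
    ε ~ N(0, σ²_ij δ²_{d,ij}),  δ²_{1,ij} ≡ 1,

with x_s the standardized predictors (age, age², sex, age×sex,
age²×sex) and B_1..B_5 symmetric K×K coefficient matrices.  Responses
are harmonized, per-edge standardized Fisher-z correlations, so no
intercept is needed and coefficients are in standardized-FC units per
standardized-predictor unit.  Fixing the reference site's variance
multiplier at 1 makes σ² and δ² separately identifiable.

Priors are conditionally conjugate throughout: multinomial labels with
Dirichlet mixture weights (concentration 1/K by default; a symmetric
Dirichlet(1) is available via `GibbsConfig.alpha` since the typeset
prior is ambiguous between the two), zero-mean normal coefficients with
inverse-gamma variances ξ² ~ IG(ρ₀, ρ₀), and IG(ϱ₀, ϱ₀) noise variances
with ρ₀ = 0.01 and ϱ₀ = 10⁻⁶ as weakly informative defaults.  The
`GibbsConfig` also accepts separate shape/rate values (`rho0_rate`,
`varrho0_rate`); equal shape and rate reproduces the default prior
family.

### Full conditionals

The supplement-level derivations are implemented directly and validated
by the test suite rather than assumed:

- ξ²_{l,k1k2} | B ~ IG(ρ₀ + 1/2, ρ₀ + B²_{l,k1k2}/2), lower triangle
  drawn and mirrored.
- σ²_ij | · ~ IG(ϱ₀ + S/2, ϱ₀ + ½ Σ_s r²_{ij,s}/δ²_{d_s,ij}) with r the
  current residual.
- δ²_{d,ij} | · ~ IG(ϱ₀ + S_d/2, ϱ₀ + ½ Σ_{s: d_s=d} r²_{ij,s}/σ²_ij)
  for d ≥ 2; site 1 is never sampled.  A site with no subjects falls
  back to its prior with a warning.
- β_{k1k2} (the 5-vector across coefficient matrices) is drawn jointly
  from its multivariate normal conditional with precision
  diag(1/ξ²) + Σ_{edges in pair} Σ_s x_s x_s'/(σ² δ²); an empty cluster
  pair falls back to the N(0, diag ξ²) prior.  Joint (blocked) sampling
  was chosen over element-wise updates as the natural conjugate scheme.
- p | m ~ Dirichlet(α·1_K + counts).
- m_i is updated sequentially (ascending region id by default,
  random-permutation order via config) from log p_k plus the quadratic
  residual terms of all selected edges incident to i; categorical draws
  go through log-sum-exp.

Variance draws use the shape/rate gamma parameterization with an
underflow guard at 1e−300.  Divergence (non-finite state) aborts with
the iteration index.

### Validation of the sampler

Three independent routes check the conditionals:

1. **Geweke getting-it-right** (`studies.geweke_study`): the
   successive-conditional chain (sweep, then refresh the data from the
   model) must have the prior as its marginal over parameters.  First
   and second moments of scalar functionals of every block (B, log ξ²,
   log σ², log δ², p, label frequencies) are compared with direct prior
   simulation at 10⁴ draws, chain autocorrelation absorbed via Geyer
   initial-positive-sequence effective sample sizes; the suite requires
   |z| < 4.  The validation instance (R=6, K=2, S=20, D=2) runs at
   inverse-gamma shapes of 3 with a small coefficient-variance rate:
   shapes below 1 (as in the analysis prior) have no finite moments, so
   a moment comparison would be undefined, and near-equal coefficient
   blocks keep the label chain mixing rather than frozen by its own
   simulated data.  The code paths exercised are identical at any
   hyperparameter values.
2. **Enumeration oracle**: label conditionals on an R=3, K=2 instance
   match brute-force enumeration of the K choices through the full
   likelihood to 1e−10.
3. **GLS oracle**: the blocked coefficient conditional matches a
   loop-written generalized-least-squares closed form to 1e−8.

## Upstream pipeline

- **FC computation**: per run, Pearson correlations over frames with
  framewise displacement below 0.2 mm (configurable); a run with fewer
  than two retained frames is dropped with a warning.  Per-run
  correlation matrices are averaged on the r scale and Fisher z is
  applied to the run-averaged correlation — the stated processing order,
  although z-then-average is the more common convention.  Correlations
  are clamped at 1 − 1e−7 before arctanh.
- **Harmonization**: parametric empirical-Bayes ComBat, written here
  (location/scale batch model, moment-matched normal and inverse-gamma
  priors, fixed-point EB estimates) and verified against the
  Bioconductor `sva::ComBat` reference to near machine precision.  By
  default no biological covariates are protected; passing the age/sex
  design columns via `covariates=` preserves them, since the source
  protocol does not state which variant was used.  Note the EB
  adjustment equalizes site means only up to prior shrinkage — per-edge
  residual gaps shrink by well over 90% but are not exactly zero.
- **Standardization**: every edge column and every predictor column is
  centered and scaled with the n−1 variance convention (the unstated
  alternative, population variance, differs by O(1/S) and none of the
  package's conclusions depend on it).  The per-column transforms are
  stored so prediction rows for arbitrary age grids live on the training
  scale.
- **Mass-univariate screen**: no-intercept OLS per edge, R² about zero,
  grouped partial F-tests — the age group {Ã, Ã², ÃG̃, Ã²G̃} and the sex
  group {G̃, ÃG̃, Ã²G̃}, interactions deliberately in both — with
  Benjamini–Hochberg selection at 1% FDR and a strict R² > 0.10
  practical-significance screen (0.05 as the sensitivity alternative).
  The partial (not marginal) F-test was chosen where the wording is
  ambiguous.
- **Covariate extensions**: race enters as four standardized dummies
  appended to the five predictors, reported as a block partial-F and
  incremental R²; vascular adjustment regresses each edge on BMI and
  the two blood pressures (with intercept — unstated, flagged) and
  hands the residuals to the age/sex regression.

## Initialization and K selection

Per-pair fitted trajectories (female curve then male curve over a
q-point age grid; q = 93 integer ages 8..100 by default) are compared
across shared partners: the similarity of regions i and j is the mean
correlation of the (i,k) and (j,k) trajectory vectors over all k ∉
{i, j}, using all region pairs rather than only screened edges.  The
resulting symmetric matrix is clustered spectrally.

The affinity transform is `exp(-(1 - psi)/h)` with h = 0.5.  The linear
shift (psi+1)/2 remains available, but it maps uncorrelated trajectory
families to affinity 0.5 and moderately correlated between-cluster
pairs (ψ ≈ 0.26 in the planted three-cluster scenario) to 0.63, which
erases the K-cluster eigengap of the normalized Laplacian; the
exponential kernel recovers the planted K robustly for bandwidths in
[0.25, 1].  K is the largest eigengap of the symmetric-normalized
Laplacian spectrum within 2..min(60, R−1) unless fixed by the caller; a
flat spectrum falls back to the lower bound with a warning.  The
embedding is row-normalized and clustered by k-means with 50 restarts
at a recorded seed.

Initial values for the Gibbs sampler come from the edge-fit MLEs: B as
the per-cluster-pair average of edge coefficients, σ² as residual
variances, δ² = ξ² = 1, labels from the spectral clustering.

## Posterior inference

Hard labels follow the strict m̄ > 0.5 rule on posterior label
frequencies; regions failing it are reported UNASSIGNED, never dropped.
Trajectory point estimates use the across-draw mean coefficients;
uncertainty bands are pointwise 2.5/97.5 percentiles of the per-draw
curves — percentile credible intervals, implemented exactly as that
construction even where the surrounding literature calls them
confidence intervals.  A pairwise co-clustering matrix is available as a
label-switching-proof diagnostic; no online relabeling is attempted.
Cluster pairs are reported when more than three selected connections
link them (configurable).  Multi-network clusters are subdivided into
per-network subclusters named `{network}-{a,b,...}` by descending region
count, and a reporting filter keeps clusters with ≥ 4 regions OR ≥ 500
grayordinates (inclusive or).

## Synthetic cohorts

The generator draws data from the model's own law.  Truth coefficients
live on the standardized-predictor/response scale and per-edge noise is
set so the population response variance is exactly one, which makes the
implied population R² of every edge available in closed form (uniform
age moments and independent Bernoulli sex give the exact predictor
correlation matrix).  Cohorts default to ages uniform on [8, 100],
balanced sexes, and six equiprobable sites; site variance multipliers
are log-uniform on [0.5, 2] with site 1 fixed at 1.

Registered scenarios (all fully reproducible from their name):

- `well_separated_K3` — R=24, K=3, S=400, D=3, implied R² 0.3–0.4 per
  edge, six distinct trajectory shapes (decline, inverted-U, rise, U,
  and two mixed patterns).  Used for planted-truth recovery.
- `null` — zero coefficients, no cluster structure; calibrates false
  positives.
- `site_heteroscedastic` — K=2 over six sites with the full multiplier
  range.
- `coverage_moderate` — R=12, K=2, S=150, D=2 at implied R² 0.20; the
  band-coverage study.
- `r2_ten_percent` — all edges at implied R² = 0.10 with S = 1673
  (mirroring the aggregated study cohort size); the split-half
  reproducibility study.
- `paper_like_R60_K6` — R=60, K=6, S=1673, D=6; a minority of cluster
  pairs carries implied R² > 0.10, the rest sit at 0.01–0.04, emulating
  the finding that only a small fraction of connections shows
  practically significant age-related change.

What the generator does **not** emulate: spatial autocorrelation between
edges sharing a region beyond the cluster structure, non-Gaussian FC
distributions, realistic BOLD autocorrelation (time-series inputs for
the FC stage are plain Gaussian draws), age-dependent motion, or
scanner drift.  Passing tests therefore certify the estimator under its
own assumptions — correctness, calibration and reproducibility — not
robustness to real-data violations of them.

## Study sizes and numerical choices

The validation studies run at sizes chosen to keep a full suite run in
minutes on one CPU while leaving the conclusions stable across seeds:
Geweke at 10⁴ draws; recovery with 800 sweeps (400 burn-in); coverage
over 50 replicates at 500 sweeps each; FDR calibration over 200
replicates of 5,000 edges; split-half reproducibility over 20 random
divisions (the analysis default is 50).  Gibbs runs retain every
post-burn-in draw; the analysis default is 2,000 iterations with the
last 1,000 retained.

One caveat on coefficient recovery: with ages uniform on [8, 100] the
standardized age and age² columns correlate at 0.977 and the age×sex
interaction has a variance inflation factor near 140, so individual
coefficients along the near-collinear directions are intrinsically
hard to pin down — an oracle GLS fit with known labels and known
variances shows per-entry standard deviations up to ≈ 0.09 at the
recovery scenario's size.  Fitted *trajectories* are unaffected (the
collinear directions barely move the curves), which is why trajectory
correlations sit near 1 while the worst coefficient entry can miss by
~0.1.

## Known limitations

- K is fixed during sampling; no reversible-jump or mixture-of-finite-
  mixtures inference over K.
- No relabeling: summaries rely on the m̄ rule and co-clustering
  diagnostics, which is adequate when clusters are well separated but
  blurs under heavy label switching.
- Chains are not label-permutation equivariant draw-for-draw (random
  number consumption orders differ), only in distribution.
- The edge set entering the model is the R²-screened set; regions with
  no surviving edges are excluded and reported as unmodeled.
- Raw fMRI preprocessing, atlas construction and brain-surface
  rendering are out of scope; the region→network lookup is consumed as
  given.
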