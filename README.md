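# conntraj

Clustering-enabled regression for sex-specific lifespan trajectories of
brain functional connectivity (FC).

## The problem

Resting-state fMRI studies summarize each subject's brain as a network:
nodes are parcellated regions, edges carry the Pearson correlation
between the two regions' activity time courses.  Mapping how each edge's
connectivity changes from childhood to old age — separately for females
and males — runs into a power problem: with R regions there are
R(R−1)/2 edges (64,620 for a 360-region parcellation), and fitting every
edge independently multiplies comparisons while leaving each fit noisy.

`conntraj` implements a Bayesian hierarchical answer: cluster the
*regions*, not the edges, so that every edge inherits its regression
coefficients from the cluster pair of its two endpoints.  Regions whose
connections share identical sex-specific, age-related FC trajectories
end up in the same cluster, and trajectory estimates pool information
across all edges between a cluster pair.

## The model

The response for edge (i, j) of subject s at site d is the harmonized,
per-edge standardized Fisher-z connectivity F_ij^(d,s).  With
standardized predictors x_s = (Ã, Ã², G̃, ÃG̃, Ã²G̃) built from age A
(years) and sex G (0 = female, 1 = male):

    F_ij^(d,s) = Σ_l  m_i' B_l m_j · x_sl  +  ε_ij^(d,s),
    ε_ij^(d,s) ~ N(0, σ²_ij · δ²_{d,ij}),    δ²_{1,ij} = 1,

where m_i is the one-hot cluster label of region i and B_1..B_5 are
K×K symmetric coefficient matrices.  No intercept: both sides are
centered.  Priors: m_i | p ~ Multinomial(1, p), p ~ Dirichlet((1/K)·1_K),
B_l,k1k2 ~ N(0, ξ²), ξ² ~ Inv-Gamma(ρ₀, ρ₀), σ², δ² ~ Inv-Gamma(ϱ₀, ϱ₀)
with ρ₀ = 0.01, ϱ₀ = 10⁻⁶.  All full conditionals are conjugate; a Gibbs
sampler sweeps ξ², σ², δ², B, p, m.

Around the model sits the full pipeline: per-run Pearson FC on
motion-retained frames → run averaging → Fisher z → multi-site ComBat
harmonization → per-edge standardization → mass-univariate screening
(grouped partial F-tests, Benjamini–Hochberg FDR, a strict 10% R²
practical-significance screen) → spectral initialization on a
trajectory-similarity matrix with eigengap K selection → Gibbs sampling
→ posterior cluster assignment (m̄ > 0.5 rule), trajectory bands, and
split-half reproducibility metrics.

## Worked example

Simulate a cohort of 400 subjects (ages 8–100, three sites) with 24
regions planted in three clusters, run the whole pipeline, and inspect
the posterior:

```python
import numpy as np
from conntraj import make_scenario, generate_fc, run_pipeline, GibbsConfig

truth, covariates = make_scenario("well_separated_K3")
dataset = generate_fc(truth, covariates, seed=1)
result = run_pipeline(dataset, covariates, r2_threshold=0.10,
                      config=GibbsConfig(n_iter=800, n_burn=400, seed=2))

print("edges passing the 10% R^2 screen:", int(result.selected.sum()),
      "of", dataset.n_edges)
print("eigengap-selected K:", result.init.n_clusters)
assignment = result.results.assign_clusters()
print("regions assigned by the mbar > 0.5 rule:",
      (assignment.hard_labels >= 0).sum(), "of", len(assignment.hard_labels))
bands = result.results.trajectories(np.arange(8.0, 101.0))
frame = bands.to_frame()
print(frame[(frame.cluster_i == 0) & (frame.cluster_j == 0)
            & (frame.age == 60.0)].to_string(index=False))
```

Output:

```
edges passing the 10% R^2 screen: 276 of 276
eigengap-selected K: 3
regions assigned by the mbar > 0.5 rule: 24 of 24
 cluster_i  cluster_j    sex  age      mean        lo        hi
         0          0 female 60.0 -0.139506 -0.164591 -0.111722
         0          0   male 60.0  0.080302  0.058035  0.101818
```

The spectral initialization recovers the planted K = 3, every region is
confidently assigned, and the within-cluster-0 trajectory at age 60 is
reported as a posterior-mean FC (standardized units) with its pointwise
95% credible band — here females sit below males, with narrow bands
because all 28 within-cluster edges share one coefficient vector.

A thin CLI wraps the same pipeline for file-based runs:

```bash
conntraj simulate well_separated_K3 --seed 1 --out data/
conntraj fit --connectivity data/connectivity.csv --covariates data/covariates.csv \
             --n-iter 800 --n-burn 400 --out fit/
conntraj reproduce --connectivity data/connectivity.csv \
                   --covariates data/covariates.csv --splits 50 --out rep/
```

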