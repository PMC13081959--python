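# rqpca

Contrastive principal component analysis via Rayleigh-quotient generalized
eigenproblems, with two extensions for genomics: a spatial kernel-weighted
form (**k-ρPCA**) for spatially resolved transcriptomics, and a functional
basis-coefficient form (**f-ρPCA**) for longitudinal expression
trajectories.

## Who this is for

Computational biologists who have a *target* dataset whose interesting
variation they want to isolate from a *background* dataset that carries the
uninteresting variation — a spatial tumor section vs. non-spatial scRNA-seq
of adjacent normal tissue, or booster-dose expression time courses vs.
primer-dose time courses — and who want the result as interpretable
loadings, eigenfunctions and per-observation scores rather than a black-box
embedding.

## The model

Contrastive PCA finds directions `v` maximizing the Rayleigh quotient

```
R(v) = (vᵀ Σ_T v) / (vᵀ Σ_B v),
```

the ratio of target to background variance along `v`.  Its maximizers are
the generalized eigenvectors of `(Σ_T, Σ_B)`, and each eigenvalue λ is
itself the target-to-background variance ratio along its direction — λ = 4
means "four times more variable in the target".  The solver whitens with a
Cholesky factor of `Σ_B + εI` and solves an ordinary symmetric
eigenproblem, so eigenvalues are real and eigenvectors are
`Σ_B`-orthonormal.

**k-ρPCA** replaces the target covariance with its kernel-weighted
counterpart `Σᵀᴷ = XᵀKX/(n−1)`, where `K_ij = exp(−‖s_i−s_j‖²/2h²)` weights
pairs of spatial locations (bandwidth `h` defaults to the square root of
the median pairwise distance; large datasets can truncate `K` at a radius,
e.g. the radius giving a mean number of spatial neighbors).  The kernel
up-weights locally coherent covariance, so the generalized eigenvectors
pick out gene programs that vary *smoothly in space* in the target while
being normalized against ordinary cell-type variation in the background.

**f-ρPCA** represents each curve in a basis `B(t) = (b₁…b_D)` (cubic
B-splines by default), giving coefficient matrices `A_X`, `A_Y`.  With the
Gram matrix `G_kl = ∫ b_k b_l` accounting for non-orthogonal bases, the
quotient in coefficient space is whitened by `G^{1/2}`:

```
argmax_w  (wᵀ G^{1/2} Σ_X^A G^{1/2} w) / (wᵀ G^{1/2} Σ_Y^A G^{1/2} w),
```

with coefficient covariances centered per group.  Eigenfunctions are
reconstructed as `v(t) = (G^{-1/2}w)ᵀ B(t)`; projecting a fitted curve onto
an eigenfunction (`θ = aᵀG f`, exact in coefficient space) gives f-GE
scores whose target/background variance ratio on component 1 equals λ₁,
which is the statistic used to rank genes.

The package also ships the surrounding pipeline: count filters
(min/max counts, expression prevalence, mitochondrial fraction),
depth-normalize + log, DESeq2-style median-of-ratios size factors, day-0
trajectory scaling, highly-variable-gene selection on the background, an
R²/group-size quality filter for fitted trajectories, synthetic-data
generators with planted contrastive structure, and readers/writers for
Matrix Market triplets, dense delimited matrices, coordinate tables and
long-format trajectories.

## Worked example

```python
import numpy as np
from rqpca import *

# spatial: recover a planted spatially coherent gene program
ds = make_spatial_dataset(SpatialScenario(seed=0))
target = center_columns(ds.target_values, ds.feature_ids, ds.coords.obs_ids)
background = center_columns(ds.background_values, ds.feature_ids)
res = k_rho_pca(target, ds.coords, background, k=3)
corr = np.corrcoef(res.decomposition.eigenvectors[:, 0], ds.truth["u_star"])[0, 1]

# functional: contrast two groups of expression trajectories
fds = make_functional_dataset(FunctionalScenario(seed=11, background_sd=1.0))
fit_t = fit_samples(fds.target_times, fds.target_values, fds.basis, group="target")
fit_b = fit_samples(fds.background_times, fds.background_values, fds.basis, group="background")
fit_t, fit_b, report = qc_filter(fit_t, fit_b, r2_min=0.5, min_per_group=7)
efs = f_rho_pca(fit_t, fit_b, k=2)
ratio = score_variance_ratio(score_samples(fit_t, efs), score_samples(fit_b, efs))
```

prints (via the surrounding `print` calls):

```
bandwidth (median heuristic): h = 3.193
eigenvalues (target/background variance ratios): 318.88, 5.66, 3.13
|corr(GE1 loadings, planted program)| = 0.990
QC: kept 50 target / 50 background trajectories
top eigenvalue lambda_1 = 4.62
f-GE1 score variance ratio (target/background) = 4.62
```

The spatial GE1 loading matches the planted gene program (|corr| 0.99) and
its eigenvalue dwarfs the rest because the kernel concentrates the smooth
spatial mode; the functional top eigenvalue and the f-GE1 score variance
ratio coincide, as the theory says they must when scores come from the
fitting data.

The same pipelines are available from the shell:

```
rqpca synth --kind spatial --out fixture --seed 0
rqpca krho --target fixture/target --background fixture/background \
      --coords fixture/coords.csv --k 3 --out results/run --seed 0
rqpca frho --input long.csv --target-label booster --background-label primer \
      --basis bspline --n-basis 5 --r2-min 0.5 --min-per-group 7 \
      --out results/f --seed 0
```

`krho` writes eigenvalues, loadings and per-spot scores plus a JSON run
log; `frho` writes per-gene eigenvalues, gridded eigenfunctions, f-GE
scores and a variance-ratio ranking table.

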