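# bltsa — branched local tangent space alignment for single-cell pseudotime

`bltsa` infers a per-cell **pseudotime** — a scalar in [0, 1] ordering cells
along a developmental trajectory — from single-cell expression snapshots,
for trajectories with **bifurcations and multi-furcations**. It is aimed at
computational biologists who have a genes × cells expression matrix (or a
precomputed low-dimensional embedding) and want branch assignments plus a
smooth global ordering without specifying the branch count in advance.

## Method

Cells are assumed to be sampled from a low-dimensional, possibly
self-intersecting one-dimensional manifold embedded in expression space.
After size-factor normalisation and a diffusion-map embedding
`X = [x_1, …, x_N] ∈ R^{D×N}` (D = 2 by default), the method runs in three
steps:

1. **Tip and branching cells.** For each cell the k-nearest-neighbour
   cloud `X_i` is fit by a rank-d affine model
   `min ‖X_i − (x̄_i e^T + U_i Θ_i)‖_F²` (solved by SVD of the centred
   neighbourhood). The *nonlinearity* `σ_{d+1}² / (σ_1²+…+σ_d²)` flags
   junction (branching) cells above its 80th percentile; the *direction
   consistency* `(2/k(k−1)) Σ_{p,q∈N_i∖i} sgn((x_p−x_i)ᵀ(x_q−x_i))` flags
   trajectory tips above δ_t = 0.9. The root is the tip at the earliest
   experimental time (or a seeded choice).
2. **Branches.** Non-branching cells are clustered by spectral clustering
   (symmetric normalised Laplacian on a Gaussian affinity with
   median-distance bandwidth), the branch count selected by the mean
   silhouette; branching cells are then absorbed greedily, each joining the
   branch minimising the average of its tangent distance
   `‖(I − U_j U_jᵀ)(x_i − x_j)‖` and Euclidean distance to the branch's
   nearest anchors, with its neighbourhood and tangent model updated on
   absorption.
3. **Alignment.** Neighbourhoods are redistributed within each cell's own
   branch plus the root branch, with an adaptive size in [k_min, k_max]
   chosen by the tangent-fit ratio. Each local coordinate set Θ_i yields an
   alignment matrix `W_i = (I − ee^T/k)(I − Θ_i⁺Θ_i)`, and the global
   coordinates minimise `Σ_i ‖T S_i W_i‖_F²`: the eigenvector of
   `B = Σ_i S_i W_i W_iᵀ S_iᵀ` for the smallest non-trivial eigenvalue,
   oriented so the root sits at 0 and rescaled to [0, 1].

Defaults: `k = 50`, `δ_b` = 80th percentile, `δ_t = 0.9`,
`[k_min, k_max] = [40, 100]`, `D = 2`.

## Worked example

Generate the built-in geometric trifurcation benchmark (400 cells on a root
segment that splits into three arms, uniform noise on the vertical
coordinate), run the pipeline, and score it against the ground truth:

```bash
$ bltsa simulate --regime sim3 --seed 1 --out sim3/
sim3: 400 cells x 2 features written to sim3

$ bltsa run --matrix sim3/matrix.tsv --out run/ --seed 1 \
        --no-normalize --root cell_0000
pseudotime for 400 cells written to run (3 branches, root cell_0000)

$ bltsa evaluate --inferred run/pseudotime.tsv --truth sim3/truth.tsv
pcc	srcc
0.973397	0.981151
```

`run/pseudotime.tsv` holds one row per cell — pseudotime `tau` in [0, 1]
(0 at the root cell), the branch index, and the adaptively chosen
neighbourhood size — alongside `branches.tsv` (branch membership and
absorption order), `cells.tsv` (per-cell nonlinearity, consistency and
tip/branching/intermediate category), a resolved config and a run log.
The evaluate step prints the Pearson and Spearman correlation between the
inferred pseudotime and the true progression coordinate: here 0.97/0.98,
i.e. the ordering along every arm is recovered almost perfectly.

`--no-normalize` is used because this benchmark provides geometric
coordinates rather than read counts; for expression matrices the default
size-factor normalisation applies. Dataset-style option sets (e.g. the
499-cell kinetic tree, or very large datasets needing PCA pre-reduction)
are in `examples/*.toml` and can be passed via `--config`.

The same pipeline is available as a library:

```python
import bltsa

traj = bltsa.simulate_geometric_trifurcation(seed=1)
expr = bltsa.ExpressionMatrix(traj.matrix, traj.feature_ids,
                              traj.cell_ids, traj.true_tau)
result, branches, cells = bltsa.run_bltsa(
    expr, bltsa.PipelineConfig(seed=1, normalize=False))
print(bltsa.correlation_metrics(result.tau, traj.true_tau))
```

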