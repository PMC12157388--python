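# kompot

Cluster-free comparison of multi-condition single-cell datasets.

Given a co-embedded, batch-corrected latent representation of cells from two
or more conditions, `kompot`:

1. builds a **diffusion-map cell-state space** shared by all conditions
   (adaptive-bandwidth kernel, anisotropic normalization);
2. fits a **condition-specific Gaussian-process log-density** function from
   nearest-neighbor distances (Poisson-process likelihood in the estimated
   intrinsic dimension, Laplace uncertainty), yielding per-cell
   **differential abundance**: a normalized density log-fold change
   `Δ(x) = μ_b(x) − μ_a(x) − log(N_a/N_b)` and a **posterior tail
   probability** `PTP(x) = Φ(−|Δ|/√(σ_a² + σ_b²))`;
3. fits **condition-specific landmark GP expression functions** (shared
   Matérn-5/2 kernel and noise across genes, so the landmark covariance is
   computed once per condition), yielding per-cell counterfactual
   **fold changes** and a per-gene, covariance-aware
   **Mahalanobis distance** `D = √((μ_a−μ_b)ᵀ(Σ_a+Σ_b)⁻¹(μ_a−μ_b))`.

PTPs are Bayesian posterior tail probabilities, reported without any
multiple-testing correction; `D` is a ranking score with no claimed null
distribution. Default significance thresholds: DA `|Δ| > 1`, `PTP < 1e-3`;
DE `|mean lfc| > 0.15`, `D > 3`; "divergent" genes `|mean lfc| < 0.07`,
`D > 6`.

## Python API

```python
import kompot

# synthetic two-condition dataset with known ground truth
ds = kompot.make_preset("da-shift", seed=0, n_per_condition=(600, 600))

dm = kompot.compute_diffusion_map(ds.coords, n_components=10, n_neighbors=30)

mask_a, mask_b = ds.condition == "A", ds.condition == "B"
d = kompot.estimate_intrinsic_dimension(dm.coords)
dens_a = kompot.fit_density(dm.coords[mask_a], intrinsic_dim=d, condition="A")
dens_b = kompot.fit_density(dm.coords[mask_b], intrinsic_dim=d, condition="B")
da = kompot.compare_abundance(dens_a, dens_b, dm.coords)   # Δ, PTP, calls

expr_a = kompot.fit_expression_gp(dm.coords[mask_a], ds.expression[mask_a],
                                  gene_ids=ds.gene_ids, condition="A")
expr_b = kompot.fit_expression_gp(dm.coords[mask_b], ds.expression[mask_b],
                                  gene_ids=ds.gene_ids, condition="B")
de = kompot.compare_expression(expr_a, expr_b, dm.coords, n_landmarks=50)
top = kompot.rank_genes(de, "up")
```

Expression input must be log-normalized (e.g. log1p of size-normalized
counts); raw-count normalization is an upstream responsibility.

## CLI

Each stage is independently invocable:

```bash
kompot simulate --preset da-shift --seed 0 --out fixture/
kompot embed --input fixture/ --n-components 10 --n-neighbors 30 --out dm.tsv
kompot density --input fixture/ --condition A --out densA.h5
kompot density --input fixture/ --condition B --out densB.h5
kompot da --model-a densA.h5 --model-b densB.h5 --out da.tsv
kompot fit-expression --input fixture/ --condition A --out exprA.h5
kompot fit-expression --input fixture/ --condition B --out exprB.h5
kompot de --model-a exprA.h5 --model-b exprB.h5 --input fixture/ --out de
kompot run --input fixture/ --out results/run --seed 0   # end to end
```

Inputs: an `.h5ad` container (embedding in `obsm`, condition column in
`obs`) or a CSV/TSV directory bundle (`coords.csv`, `metadata.tsv`,
optionally `expression.csv` or `expression.mtx` + `genes.tsv` +
`cells.tsv`). `kompot run` emits TSV tables per ordered condition pair plus
a JSON run manifest; everything is deterministic given `--seed`.

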