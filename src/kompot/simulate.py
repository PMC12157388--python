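"""Synthetic multi-condition datasets with known ground truth.

Manifolds are Gaussian mixtures; "curve"/branch components are represented
internally as fine sub-mixtures of Gaussians along a segment, so the true
per-condition density is always available in closed form (as a mixture
density). Expression is generated as smooth functions of latent position
(random linear forms squashed through tanh) plus Gaussian noise on the log
scale, with per-gene condition effects planted according to an effect
descriptor. This is a statistical test double, not a realistic scRNA-seq
count simulator.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SyntheticDataset",
    "make_mixture_manifold",
    "plant_expression",
    "write_fixture",
    "PRESETS",
]


@dataclass
class SyntheticDataset:
    coords: np.ndarray  # (n_total, dims)
    condition: np.ndarray  # per cell
    cell_ids: np.ndarray
    component: np.ndarray  # top-level mixture component per cell
    true_log_density: dict  # condition -> (n_total,) log cells/volume
    weights: dict  # condition -> simplex over components
    n_per_condition: dict  # condition -> int
    seed: int
    expression: np.ndarray | None = None  # (n_total, G), log scale
    gene_ids: np.ndarray | None = None
    effects: list[dict] | None = None  # one descriptor per gene
    atoms: list = field(default_factory=list, repr=False)  # (mean, cov, w, comp)

    @property
    def n_cells(self) -> int:
        return self.coords.shape[0]

    def condition_mask(self, condition) -> np.ndarray:
        return self.condition == condition

    def true_delta(self, cond_a, cond_b) -> np.ndarray:
        """Generator-truth density log-fold change a -> b at every cell
        (size-corrected the same way the estimator is)."""
        n_a, n_b = self.n_per_condition[cond_a], self.n_per_condition[cond_b]
        return (
            self.true_log_density[cond_b]
            - self.true_log_density[cond_a]
            - (np.log(n_a) - np.log(n_b))
        )


def _expand_components(component_params, dims):
    """Expand component specs into Gaussian atoms (mean, cov_scalar, subweight)."""
    atoms = []
    for ci, spec in enumerate(component_params):
        if spec.get("kind", "gaussian") == "gaussian":
            mean = np.asarray(spec["mean"], dtype=float)
            sd = float(spec.get("sd", 1.0))
            atoms.append((mean, sd, 1.0, ci))
        elif spec["kind"] == "curve":
            start = np.asarray(spec["start"], dtype=float)
            end = np.asarray(spec["end"], dtype=float)
            sd = float(spec.get("sd", 0.3))
            n_k = int(spec.get("n_kernels", 25))
            ts = np.linspace(0.0, 1.0, n_k)
            for t in ts:
                atoms.append((start + t * (end - start), sd, 1.0 / n_k, ci))
        else:
            raise ValueError(f"unknown component kind {spec['kind']!r}")
        if atoms[-1][0].shape[0] != dims:
            raise ValueError("component mean dimension mismatch")
    return atoms


def _mixture_log_density(X, atoms, weights):
    """Log of the mixture pdf (fraction of cells per volume)."""
    dims = X.shape[1]
    comps = np.zeros((X.shape[0], len(atoms)))
    logw = []
    for j, (mean, sd, subw, ci) in enumerate(atoms):
        d2 = np.sum((X - mean) ** 2, axis=1)
        comps[:, j] = -0.5 * d2 / sd**2 - dims * np.log(sd) - 0.5 * dims * np.log(
            2 * np.pi
        )
        logw.append(np.log(weights[ci]) + np.log(subw))
    logw = np.asarray(logw)
    m = comps + logw[None, :]
    mmax = m.max(axis=1, keepdims=True)
    return (mmax + np.log(np.exp(m - mmax).sum(axis=1, keepdims=True))).ravel()


DEFAULT_COMPONENTS = (
    {"mean": (0.0, 0.0), "sd": 1.0},
    {"mean": (6.0, 0.0), "sd": 1.0},
)


def make_mixture_manifold(
    n_per_condition=(500, 500),
    weights_a=(0.5, 0.5),
    weights_b=(0.5, 0.5),
    component_params=None,
    seed: int = 0,
    conditions=("A", "B"),
) -> SyntheticDataset:
    """Two-condition mixture manifold with analytic per-condition densities."""
    weights_a = np.asarray(weights_a, dtype=float)
    weights_b = np.asarray(weights_b, dtype=float)
    if weights_a.shape != weights_b.shape:
        raise ValueError("weight vectors must have equal length")
    if (weights_a < 0).any() or (weights_b < 0).any():
        raise ValueError("weights must be non-negative")
    weights_a = weights_a / weights_a.sum()
    weights_b = weights_b / weights_b.sum()

    if component_params is None:
        component_params = DEFAULT_COMPONENTS
    if len(component_params) != len(weights_a):
        raise ValueError("one weight per component required")
    dims = len(np.asarray(component_params[0]["mean"] if "mean" in component_params[0]
                          else component_params[0]["start"]))
    atoms = _expand_components(component_params, dims)

    rng = np.random.default_rng(seed)
    n_per = dict(zip(conditions, np.atleast_1d(n_per_condition).astype(int)))
    weights = {conditions[0]: weights_a, conditions[1]: weights_b}

    all_coords, all_cond, all_comp = [], [], []
    for cond in conditions:
        w = weights[cond]
        n = n_per[cond]
        atom_w = np.array([w[ci] * subw for (_, _, subw, ci) in atoms])
        atom_w = atom_w / atom_w.sum()
        choice = rng.choice(len(atoms), size=n, p=atom_w)
        X = np.empty((n, dims))
        for j in np.unique(choice):
            mean, sd, _, _ = atoms[j]
            mask = choice == j
            X[mask] = mean + sd * rng.standard_normal((mask.sum(), dims))
        all_coords.append(X)
        all_cond.append(np.full(n, cond, dtype=object))
        all_comp.append(np.array([atoms[j][3] for j in choice]))

    coords = np.vstack(all_coords)
    condition = np.concatenate(all_cond)
    component = np.concatenate(all_comp)
    cell_ids = np.array([f"cell_{i}" for i in range(coords.shape[0])], dtype=object)

    true_log_density = {
        cond: np.log(n_per[cond]) + _mixture_log_density(coords, atoms, weights[cond])
        for cond in conditions
    }

    return SyntheticDataset(
        coords=coords,
        condition=condition,
        cell_ids=cell_ids,
        component=component,
        true_log_density=true_log_density,
        weights=weights,
        n_per_condition=n_per,
        seed=seed,
        atoms=atoms,
    )


def plant_expression(
    dataset: SyntheticDataset,
    n_genes: int = 50,
    effect_spec: list[dict] | None = None,
    noise_sd: float = 0.2,
    seed: int = 0,
) -> SyntheticDataset:
    """Add a log-scale expression matrix with planted condition-b effects.

    ``effect_spec`` is a list of descriptors, each covering a contiguous
    block of genes: {"type": "null"} | {"type": "global_shift", "delta": d,
    "n": m} | {"type": "localized_shift", "delta": d, "region": comp, "n": m}
    | {"type": "opposing_shift", "delta": d, "n": m} (sign +d on component 0,
    -d on component 1). Unspecified remainder genes are null.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    X = dataset.coords
    Xs = (X - X.mean(axis=0)) / X.std(axis=0)
    dims = X.shape[1]

    # expand spec into one descriptor per gene
    effects: list[dict] = []
    if effect_spec:
        for block in effect_spec:
            m = int(block.get("n", 1))
            for _ in range(m):
                effects.append({k: v for k, v in block.items() if k != "n"})
    if len(effects) > n_genes:
        raise ValueError("effect_spec covers more genes than n_genes")
    effects.extend({"type": "null"} for _ in range(n_genes - len(effects)))

    # smooth baseline: offset + amplitude * tanh(w . x + b)
    W = rng.normal(size=(dims, n_genes))
    b = rng.normal(size=n_genes)
    amp = rng.uniform(0.5, 1.0, size=n_genes)
    offset = rng.uniform(2.5, 3.5, size=n_genes)
    expr = offset + amp * np.tanh(Xs @ W + b)

    conditions = list(dataset.n_per_condition)
    cond_b = dataset.condition == conditions[1]

    for g, eff in enumerate(effects):
        etype = eff.get("type", "null")
        delta = float(eff.get("delta", 0.0))
        if etype == "null":
            continue
        elif etype == "global_shift":
            expr[cond_b, g] += delta
        elif etype == "localized_shift":
            region = int(eff.get("region", 0))
            expr[cond_b & (dataset.component == region), g] += delta
        elif etype == "opposing_shift":
            expr[cond_b & (dataset.component == 0), g] += delta
            expr[cond_b & (dataset.component == 1), g] -= delta
        else:
            raise ValueError(f"unknown effect type {etype!r}")

    expr += noise_sd * rng.standard_normal(expr.shape)
    np.maximum(expr, 0.0, out=expr)  # log-normalized expression is non-negative

    dataset.expression = expr
    dataset.gene_ids = np.array([f"gene_{g:03d}" for g in range(n_genes)], dtype=object)
    dataset.effects = effects
    return dataset


PRESETS = {
    "null": dict(weights_a=(0.5, 0.5), weights_b=(0.5, 0.5), effect_spec=None),
    "da-shift": dict(weights_a=(0.85, 0.15), weights_b=(0.15, 0.85), effect_spec=None),
    "de-global": dict(
        weights_a=(0.5, 0.5),
        weights_b=(0.5, 0.5),
        effect_spec=[{"type": "global_shift", "delta": 1.0, "n": 5}],
    ),
    "de-opposing": dict(
        weights_a=(0.5, 0.5),
        weights_b=(0.5, 0.5),
        effect_spec=[{"type": "opposing_shift", "delta": 1.0, "n": 5}],
    ),
}


def make_preset(
    preset: str,
    seed: int = 0,
    n_per_condition=(600, 600),
    n_genes: int = 50,
    noise_sd: float = 0.2,
) -> SyntheticDataset:
    """Build one of the named presets end to end (geometry + expression)."""
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; options: {sorted(PRESETS)}")
    cfg = PRESETS[preset]
    ds = make_mixture_manifold(
        n_per_condition=n_per_condition,
        weights_a=cfg["weights_a"],
        weights_b=cfg["weights_b"],
        seed=seed,
    )
    ds = plant_expression(
        ds, n_genes=n_genes, effect_spec=cfg["effect_spec"], noise_sd=noise_sd,
        seed=seed + 1,
    )
    return ds


def write_fixture(dataset: SyntheticDataset, path, fmt: str = "csv") -> None:
    """Write a dataset to disk in a form the package's readers round-trip.

    ``csv``: directory bundle (coords.csv, metadata.tsv, expression.csv,
    truth TSVs); ``h5ad``: annotated container with the embedding in
    ``obsm["X_latent"]``.
    """
    path = Path(path)
    if fmt == "csv":
        path.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(
            dataset.coords,
            index=pd.Index(dataset.cell_ids, name="cell_id"),
            columns=[f"dim_{j}" for j in range(dataset.coords.shape[1])],
        ).to_csv(path / "coords.csv", float_format="%.17g")
        meta = pd.DataFrame(
            {
                "cell_id": dataset.cell_ids,
                "condition": dataset.condition,
                "component": dataset.component,
            }
        )
        meta.to_csv(path / "metadata.tsv", sep="\t", index=False)
        truth = pd.DataFrame(
            {f"true_log_density_{c}": v for c, v in dataset.true_log_density.items()}
        )
        truth.insert(0, "cell_id", dataset.cell_ids)
        truth.to_csv(path / "true_density.tsv", sep="\t", index=False,
                     float_format="%.17g")
        if dataset.expression is not None:
            pd.DataFrame(
                dataset.expression,
                index=pd.Index(dataset.cell_ids, name="cell_id"),
                columns=dataset.gene_ids,
            ).to_csv(path / "expression.csv", float_format="%.17g")
            pd.DataFrame(
                {
                    "gene_id": dataset.gene_ids,
                    "effect": [json.dumps(e, sort_keys=True) for e in dataset.effects],
                }
            ).to_csv(path / "gene_effects.tsv", sep="\t", index=False)
        with open(path / "manifest.json", "w") as fh:
            json.dump(
                {
                    "seed": dataset.seed,
                    "n_per_condition": {
                        str(k): int(v) for k, v in dataset.n_per_condition.items()
                    },
                    "weights": {
                        str(k): list(map(float, v)) for k, v in dataset.weights.items()
                    },
                },
                fh,
                indent=2,
            )
    elif fmt == "h5ad":
        import anndata as ad

        n, g = dataset.n_cells, (
            dataset.expression.shape[1] if dataset.expression is not None else 0
        )
        Xmat = (
            dataset.expression
            if dataset.expression is not None
            else np.zeros((n, 1))
        )
        var_names = (
            dataset.gene_ids if dataset.gene_ids is not None else np.array(["dummy"])
        )
        adata = ad.AnnData(
            X=np.asarray(Xmat, dtype=float),
            obs=pd.DataFrame(
                {
                    "condition": pd.Categorical(dataset.condition.astype(str)),
                    "component": dataset.component,
                },
                index=dataset.cell_ids.astype(str),
            ),
            var=pd.DataFrame(index=np.asarray(var_names, dtype=str)),
        )
        adata.obsm["X_latent"] = dataset.coords
        for c, v in dataset.true_log_density.items():
            adata.obs[f"true_log_density_{c}"] = v
        if dataset.effects is not None:
            adata.uns["gene_effects"] = json.dumps(dataset.effects)
        adata.uns["seed"] = dataset.seed
        adata.write_h5ad(path)
    else:
        raise ValueError(f"unsupported fixture format {fmt!r}")
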