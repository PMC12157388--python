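"""End-to-end orchestration: embed -> density per condition -> DA ->
expression GPs per condition -> DE, with a machine-readable run manifest."""

from __future__ import annotations

import json
import logging
import time
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .abundance import compare_abundance, summarize_by_group
from .config import RunConfig
from .density import estimate_intrinsic_dimension, fit_density
from .diffexp import compare_expression
from .expression import fit_expression_gp
from .io import read_dataset, save_density, save_predictor
from .state_space import compute_diffusion_map

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "stage_seed"]

_STAGE_IDS = {"embed": 1, "density": 2, "da": 3, "expression": 4, "de": 5}


def stage_seed(global_seed: int, stage: str, item: int = 0) -> int:
    """Derive a per-stage seed from the single global seed (documented rule:
    SeedSequence spawned from [global_seed, stage_id, item])."""
    ss = np.random.SeedSequence([int(global_seed), _STAGE_IDS[stage], int(item)])
    return int(ss.generate_state(1)[0])


def run_pipeline(config: RunConfig) -> dict:
    """Run the full workflow described by ``config``; returns output paths.

    The manifest is written even when a stage fails (with the failing stage
    recorded) and the partial outputs written so far are preserved.
    """
    prefix = config.ensure_output_dir()
    manifest = {
        "version": __version__,
        "config": config.__dict__.copy(),
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "stages": [],
        "outputs": {},
        "error": None,
    }
    outputs: dict = {}
    t_start = time.time()
    stage = "read"
    try:
        ds = read_dataset(
            config.input_path, rep=config.rep, condition_col=config.condition_col
        )
        emb = ds.embedding
        conditions = list(config.conditions) or sorted(set(emb.condition))
        if len(conditions) < 2:
            raise ValueError("need at least 2 conditions for a comparison")
        manifest["stages"].append("read")

        stage = "embed"
        if config.use_diffusion_map:
            dmap = compute_diffusion_map(
                emb,
                n_components=config.n_components,
                n_neighbors=config.n_neighbors,
                alpha=config.alpha,
                scale_by_eigenvalues=config.scale_by_eigenvalues,
            )
            states = dmap.coords
            coords_path = f"{prefix}.diffusion.tsv"
            pd.DataFrame(
                states,
                index=pd.Index(emb.cell_ids, name="cell_id"),
                columns=[f"DC{j + 1}" for j in range(states.shape[1])],
            ).to_csv(coords_path, sep="\t", float_format="%.12g")
            outputs["diffusion_coords"] = coords_path
        else:
            states = emb.coords
        manifest["stages"].append("embed")

        stage = "density"
        d = config.intrinsic_dim or estimate_intrinsic_dimension(states)
        densities = {}
        for i, cond in enumerate(conditions):
            mask = emb.condition == cond
            est = fit_density(
                states[mask],
                intrinsic_dim=d,
                condition=str(cond),
                lengthscale=config.density_lengthscale,
                seed=stage_seed(config.seed, "density", i),
            )
            path = f"{prefix}.density.{cond}.h5"
            save_density(est, path)
            outputs[f"density_model_{cond}"] = path
            densities[cond] = est
        manifest["stages"].append("density")

        stage = "da"
        for a, b in combinations(conditions, 2):
            comp = compare_abundance(
                densities[a],
                densities[b],
                states,
                cell_ids=emb.cell_ids,
                lfc_threshold=config.da_lfc_threshold,
                ptp_threshold=config.da_ptp_threshold,
            )
            path = f"{prefix}.da.{a}_to_{b}.tsv"
            comp.to_frame().to_csv(path, sep="\t", index=False, float_format="%.12g")
            outputs[f"da_{a}_to_{b}"] = path
            if config.group_col and emb.cell_annotations is not None:
                groups = emb.cell_annotations[config.group_col].to_numpy()
                gpath = f"{prefix}.da.{a}_to_{b}.groups.tsv"
                summarize_by_group(comp, groups).to_csv(
                    gpath, sep="\t", index=False, float_format="%.12g"
                )
                outputs[f"da_groups_{a}_to_{b}"] = gpath
        manifest["stages"].append("da")

        if ds.expression is not None:
            stage = "expression"
            predictors = {}
            for i, cond in enumerate(conditions):
                mask = emb.condition == cond
                pred = fit_expression_gp(
                    states[mask],
                    ds.expression[mask],
                    condition=str(cond),
                    gene_ids=ds.gene_ids,
                    n_landmarks=config.n_landmarks,
                    kmeans_iters=config.kmeans_iters,
                    lengthscale=config.expression_lengthscale,
                    noise_variance=config.noise_variance,
                    jitter=config.jitter,
                    seed=stage_seed(config.seed, "expression", i),
                )
                path = f"{prefix}.expression.{cond}.h5"
                save_predictor(pred, path)
                outputs[f"expression_model_{cond}"] = path
                predictors[cond] = pred
            manifest["stages"].append("expression")

            stage = "de"
            for a, b in combinations(conditions, 2):
                comp = compare_expression(
                    predictors[a],
                    predictors[b],
                    states,
                    n_landmarks=min(config.n_landmarks, states.shape[0]),
                    kmeans_iters=config.kmeans_iters,
                    seed=stage_seed(config.seed, "de", 0),
                    lfc_threshold=config.de_lfc_threshold,
                    d_threshold=config.de_d_threshold,
                    divergent_lfc_max=config.divergent_lfc_max,
                    divergent_d_min=config.divergent_d_min,
                )
                path = f"{prefix}.de.{a}_to_{b}.tsv"
                comp.to_frame().to_csv(
                    path, sep="\t", index=False, float_format="%.12g"
                )
                outputs[f"de_{a}_to_{b}"] = path
            manifest["stages"].append("de")
    except Exception as exc:
        manifest["error"] = {"stage": stage, "message": str(exc)}
        raise
    finally:
        manifest["outputs"] = outputs
        manifest["elapsed_seconds"] = round(time.time() - t_start, 3)
        manifest_path = f"{prefix}.manifest.json"
        with open(manifest_path, "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
        outputs["manifest"] = manifest_path

    return outputs
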