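"""Run configuration with YAML round-trip."""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """End-to-end pipeline configuration. All thresholds must be positive."""

    input_path: str = ""
    output_prefix: str = "kompot_run"
    rep: str = "X_latent"
    condition_col: str = "condition"
    conditions: list[str] = field(default_factory=list)  # ordered; empty = discover
    group_col: str | None = None

    # state space
    n_components: int = 10
    n_neighbors: int = 30
    alpha: float = 1.0
    scale_by_eigenvalues: bool = False
    use_diffusion_map: bool = True

    # density
    intrinsic_dim: float | None = None
    density_lengthscale: float | None = None

    # landmarks / expression
    n_landmarks: int = 5000
    kmeans_iters: int = 10
    expression_lengthscale: float | None = None
    noise_variance: float | None = None
    jitter: float = 1e-6

    # thresholds
    da_lfc_threshold: float = 1.0
    da_ptp_threshold: float = 1e-3
    de_lfc_threshold: float = 0.15
    de_d_threshold: float = 3.0
    divergent_lfc_max: float = 0.07
    divergent_d_min: float = 6.0

    seed: int = 0
    verbosity: str = "INFO"

    def __post_init__(self):
        for name in (
            "da_lfc_threshold",
            "da_ptp_threshold",
            "de_lfc_threshold",
            "de_d_threshold",
            "divergent_lfc_max",
            "divergent_d_min",
            "jitter",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def content_hash(self) -> str:
        canonical = yaml.safe_dump(asdict(self), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]

    def ensure_output_dir(self) -> Path:
        out = Path(self.output_prefix)
        out.parent.mkdir(parents=True, exist_ok=True)
        return out
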