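"""Run configuration shared by the library and the CLI."""

from __future__ import annotations

from dataclasses import asdict, dataclass

import yaml


@dataclass
class InferenceConfig:
    """Tunable knobs of the inference pipeline.

    Inference itself is deterministic; ``seed`` only feeds optional
    Monte-Carlo diagnostics and the FDR mixture's randomized restarts.
    """

    gap_threshold: int = 3000       # bp gap starting a new chunk
    min_fraction: float = 0.5       # sample-coverage filter
    grid_step: float = 0.75         # hyperparameter grid step, in SDs
    log_density_drop: float = 3.0   # grid extension cutoff, nats
    quad_nodes: int = 20            # Gauss-Hermite nodes for E[expit]
    level_precision: float = 1e-5   # anchoring of the intrinsic random walk
    newton_tol: float = 1e-6        # max |gradient| at the mode
    newton_max_iter: int = 50
    distance_cap: float = None      # optional cap on CpG spacing (bp)
    n_workers: int = 1
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "InferenceConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {k: v for k, v in data.items() if k in cls.__dataclass_fields__}
        return cls(**known)
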