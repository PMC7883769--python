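"""Run configuration: YAML loading with strict keys, plus audit snapshots.

Every CLI command serializes the configuration it actually ran with into its
output directory, so any run can be reproduced from its artifacts alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .feature_space import ComponentRegistry, default_registry, registry_from_config
from .selection import DEFAULT_COUNTS

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "load_config", "resolve_registry", "write_snapshot"]


@dataclass
class RunConfig:
    """Parameters shared by the pipeline commands."""

    registry: str = "default"          # "default", "reduced" or a YAML path
    seed: int = 0
    levels: int = 32                   # grey-level quantization bins
    filter_order: str = "image"
    # selector
    n_fits: int = 50
    subsample: float = 0.8
    counts: tuple[int, int, int, int] = DEFAULT_COUNTS
    pca_dim: int = 15
    lasso_c: float = 1.0
    # benchmark
    trials: int = 100
    folds: int = 10
    k: int = 288
    selectors: tuple[str, ...] = ("ours", "lasso_topk", "rfe", "variance", "all_pca", "all")
    models: tuple[str, ...] = ("lasso", "svm", "mlp", "xgboost", "rf", "lr")

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["counts"] = list(self.counts)
        out["selectors"] = list(self.selectors)
        out["models"] = list(self.models)
        return out


def load_config(path: str | Path | None, **overrides) -> RunConfig:
    """Load a YAML config (flat key-value); unknown keys are rejected."""
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ValueError("config file must contain a mapping")
        data.update(loaded)
    data.update({k: v for k, v in overrides.items() if v is not None})
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for tup_key in ("counts", "selectors", "models"):
        if tup_key in data:
            data[tup_key] = tuple(data[tup_key])
    return RunConfig(**data)


def resolve_registry(spec: str) -> ComponentRegistry:
    """Resolve a registry spec: "default", "reduced" or a YAML file path."""
    if spec == "default":
        return default_registry()
    if spec == "reduced":
        from .synthetic import reduced_registry

        return reduced_registry()
    path = Path(spec)
    if not path.exists():
        raise ValueError(f"registry {spec!r} is neither a known name nor a file")
    with open(path) as fh:
        return registry_from_config(yaml.safe_load(fh) or {})


def write_snapshot(outdir: str | Path, config: RunConfig, extra: dict | None = None) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    payload = {"config": config.to_dict()}
    if extra:
        payload.update(extra)
    path = outdir / "run_config.json"
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=str)
    return path
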