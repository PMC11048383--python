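"""Run configuration, seed derivation and run manifests.

All randomness in a pipeline run flows from a single root seed: each stage
draws its own child seed through a fixed counter scheme
(``SeedSequence([root, stage_index])``), so any stage can be re-run in
isolation and reproduce its in-pipeline behaviour exactly.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import yaml

__all__ = ["STAGES", "stage_seed", "load_yaml_config", "merge_config", "write_manifest"]

#: Stage names in counter order; the index is the child-seed key.
STAGES = ("simulate", "split", "preprocess", "subsample", "train", "evaluate", "learning_curve")


def stage_seed(root_seed: int, stage: str) -> int:
    """Deterministic per-stage child seed (always < 2**31)."""
    try:
        idx = STAGES.index(stage)
    except ValueError:
        raise ValueError(f"unknown stage {stage!r}; valid stages: {STAGES}") from None
    ss = np.random.SeedSequence([int(root_seed), idx])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def load_yaml_config(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if doc is None:
        return {}
    if not isinstance(doc, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    return doc


def merge_config(base: dict, overrides: dict) -> dict:
    """Overlay non-None override values onto a base config."""
    merged = dict(base)
    for key, val in overrides.items():
        if val is not None:
            merged[key] = val
    return merged


def config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_manifest(path, command: str, config: dict, outputs: list[str] | None = None) -> Path:
    """Record the fully resolved configuration of a finished command."""
    path = Path(path)
    doc = {
        "command": command,
        "config": config,
        "config_hash": config_hash(config),
        "outputs": outputs or [],
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=2, default=str)
    return path
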