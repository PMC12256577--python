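"""YAML run configuration and provenance manifests.

A run config is a YAML file with up to three blocks: ``phantom`` (the
simulator template and dataset sizes), ``train`` (everything in
TrainConfig, including nested ``generator`` / ``critic`` /
``loss_weights`` / ``window`` blocks) and ``evaluate`` (split,
reference, ROI area).  Every command writes a ``run_manifest.json``
into its output directory recording the resolved configuration, the
seed, the package version and timestamps, so any artifact directory is
reproducible from its manifest alone.
"""

from __future__ import annotations

import json
import platform
from datetime import datetime, timezone
from pathlib import Path

import yaml

from . import __version__
from .phantom import Ellipse, Lesion, PhantomSpec
from .training import TrainConfig


class ConfigFileError(ValueError):
    """Unreadable or invalid YAML configuration."""


def load_yaml(path: str | Path) -> dict:
    path = Path(path)
    if not path.exists():
        raise ConfigFileError(f"config file not found: {path}")
    try:
        with open(path) as fh:
            data = yaml.safe_load(fh)
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        loc = f" (line {mark.line + 1})" if mark is not None else ""
        raise ConfigFileError(f"invalid YAML in {path}{loc}: {exc}") from exc
    if not isinstance(data, dict):
        raise ConfigFileError(f"config root must be a mapping: {path}")
    return data


def phantom_spec_from_config(block: dict) -> PhantomSpec:
    block = dict(block)
    for key in ("n_phantoms", "slices_per_phantom", "dose_fraction",
                "split", "n_lesions"):
        block.pop(key, None)
    if "body" in block:
        block["body"] = Ellipse(**block["body"])
    if "liver" in block:
        block["liver"] = Ellipse(**block["liver"])
    if "lesions" in block:
        block["lesions"] = [Lesion(**l) for l in block["lesions"]]
    if "lesion_suv_range" in block:
        block["lesion_suv_range"] = tuple(block["lesion_suv_range"])
    try:
        return PhantomSpec(**block)
    except TypeError as exc:
        raise ConfigFileError(f"bad phantom block: {exc}") from exc


def train_config_from_config(block: dict, seed: int | None = None
                             ) -> TrainConfig:
    block = dict(block)
    if seed is not None:
        block["seed"] = seed
    try:
        return TrainConfig.from_dict(block)
    except TypeError as exc:
        raise ConfigFileError(f"bad train block: {exc}") from exc


def write_run_manifest(out_dir: str | Path, command: str, config: dict,
                       seed: int | None, inputs: dict | None = None,
                       outputs: dict | None = None) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "command": command,
        "config": config,
        "seed": seed,
        "version": __version__,
        "timestamp_utc": datetime.now(timezone.utc).isoformat(),
        "platform": platform.platform(),
        "inputs": inputs or {},
        "outputs": outputs or {},
    }
    path = out_dir / "run_manifest.json"
    path.write_text(json.dumps(manifest, indent=1, default=str))
    return path
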