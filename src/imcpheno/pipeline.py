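"""End-to-end orchestration: preprocess -> measure -> phenotype, with a
machine-readable run manifest.

The pipeline is a pure function of (inputs, configuration, seed): it uses no
wall-clock state, and the manifest records input hashes, parameters and
package version so a rerun with the same manifest reproduces byte-identical
CSV outputs.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .errors import ConfigurationError
from .io import PreprocessSettings, preprocess_stack, read_mask, read_panel, read_roi_dir, write_roi_dir
from .measure import LabelMask, measure_cells
from .phenotype import assign_metaclusters, transform_scale
from .rules import RuleSet, human_rules, mouse_rules

KNOWN_KEYS = {
    "input_dir",
    "masks_dir",
    "panel",
    "meta",
    "params",
    "rules",
    "output_dir",
    "seed",
    "cofactor",
    "log_level",
}

META_COLUMNS = ["roi_id", "sample_id", "condition", "batch"]


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            digest.update(chunk)
    return digest.hexdigest()


def load_config(path: str | Path) -> dict:
    """Load and validate a run configuration; unknown keys are rejected and
    required inputs must exist before any computation starts."""
    path = Path(path)
    with open(path) as fh:
        config = yaml.safe_load(fh) or {}
    unknown = set(config) - KNOWN_KEYS
    if unknown:
        raise ConfigurationError(f"unknown configuration keys: {sorted(unknown)}")
    base = path.parent
    for key in ("input_dir", "masks_dir", "panel", "meta"):
        if key not in config:
            raise ConfigurationError(f"configuration missing required key {key!r}")
        resolved = (base / config[key]).resolve()
        if not resolved.exists():
            raise ConfigurationError(f"{key} does not exist: {resolved}")
        config[key] = str(resolved)
    for key in ("params",):
        if key in config and config[key]:
            resolved = (base / config[key]).resolve()
            if not resolved.exists():
                raise ConfigurationError(f"{key} does not exist: {resolved}")
            config[key] = str(resolved)
    config.setdefault("rules", "human")
    config.setdefault("output_dir", "out")
    config["output_dir"] = str((base / config["output_dir"]).resolve())
    config.setdefault("seed", 0)
    config.setdefault("cofactor", 5.0)
    if config["rules"] not in ("human", "mouse"):
        resolved = (base / config["rules"]).resolve()
        if not resolved.exists():
            raise ConfigurationError(f"rules file does not exist: {resolved}")
        config["rules"] = str(resolved)
    return config


def _load_rules(spec: str) -> RuleSet:
    if spec == "human":
        return human_rules()
    if spec == "mouse":
        return mouse_rules()
    return RuleSet.load(spec)


def run_pipeline(config: dict) -> dict:
    """Execute preprocess -> measure -> phenotype for every ROI and write
    ``cells.csv``, ``labeled.csv`` and ``manifest.json`` to the output
    directory.  Returns the manifest."""
    panel = read_panel(config["panel"])
    meta = pd.read_csv(config["meta"], dtype=str)
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise ConfigurationError(f"metadata file missing columns: {missing}")
    settings = (
        PreprocessSettings.from_yaml(config["params"])
        if config.get("params")
        else PreprocessSettings()
    )
    ruleset = _load_rules(config["rules"])
    markers = list(panel["marker"])
    ruleset.validate(markers)

    input_dir = Path(config["input_dir"])
    masks_dir = Path(config["masks_dir"])
    out_dir = Path(config["output_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)

    input_hashes: dict[str, str] = {}
    tables = []
    for _, row in meta.sort_values("roi_id").iterrows():
        roi_dir = input_dir / row["roi_id"]
        mask_path = masks_dir / f"{row['roi_id']}.tiff"
        if not roi_dir.is_dir():
            raise ConfigurationError(f"ROI directory missing: {roi_dir}")
        if not mask_path.exists():
            raise ConfigurationError(f"mask missing for ROI {row['roi_id']}: {mask_path}")
        stack = read_roi_dir(roi_dir, panel)
        for tif in sorted(roi_dir.glob("*.tif*")):
            input_hashes[str(tif)] = _sha256(tif)
        input_hashes[str(mask_path)] = _sha256(mask_path)
        processed = preprocess_stack(stack, settings, batch=row["batch"])
        write_roi_dir(processed, out_dir / "processed" / row["roi_id"])
        mask = LabelMask(labels=read_mask(mask_path), roi_id=row["roi_id"])
        tables.append(
            measure_cells(
                processed, mask, sample_id=row["sample_id"], condition=row["condition"]
            )
        )
    cells = pd.concat(tables, ignore_index=True)
    cells_path = out_dir / "cells.csv"
    cells.to_csv(cells_path, index=False)

    scaled = transform_scale(cells, markers, cofactor=float(config["cofactor"]))
    labeled = assign_metaclusters(scaled, ruleset, markers)
    labeled_path = out_dir / "labeled.csv"
    labeled.to_csv(labeled_path, index=False)

    manifest = {
        "package_version": __version__,
        "config": {k: config[k] for k in sorted(config)},
        "ruleset": ruleset.name,
        "seed": int(config["seed"]),
        "inputs": dict(sorted(input_hashes.items())),
        "outputs": {
            "cells.csv": _sha256(cells_path),
            "labeled.csv": _sha256(labeled_path),
        },
        "n_cells": int(len(cells)),
        "metacluster_counts": {
            str(k): int(v) for k, v in labeled["metacluster"].value_counts().items()
        },
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
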