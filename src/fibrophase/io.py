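"""Readers/writers for parameter files, gene-set collections and results."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Iterable, List, Mapping

import yaml
from gseapy.parser import read_gmt

from .model import Environment, ReducedParams

__all__ = [
    "load_params",
    "save_params",
    "load_environment",
    "read_gene_sets",
    "write_gmt",
    "load_config",
]


def _load_mapping(path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def load_params(path) -> ReducedParams:
    """Load reduced model parameters from a JSON or YAML mapping."""
    d = _load_mapping(path)
    return ReducedParams.from_dict(d.get("params", d))


def save_params(params: ReducedParams, path) -> None:
    path = Path(path)
    d = params.to_dict()
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(d, indent=2))
    else:
        path.write_text(yaml.safe_dump(d, sort_keys=False))


def load_environment(path) -> Environment:
    d = _load_mapping(path)
    return Environment.from_dict(d.get("environment", d))


def read_gene_sets(path) -> Dict[str, List[str]]:
    """Read a GMT gene-set collection (name, description, genes...)."""
    return read_gmt(str(path))


def write_gmt(gene_sets: Mapping[str, Iterable[str]], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in gene_sets.items():
            fh.write("\t".join([name, description, *sorted(map(str, genes))]) + "\n")


def load_config(path) -> dict:
    cfg = _load_mapping(path)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a mapping")
    return cfg
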