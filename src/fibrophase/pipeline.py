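"""End-to-end orchestration from a single YAML/JSON config.

A run config selects stages (``phases``, ``simulate``, ``overlap``,
``spatial``, ``synth``) and provides their inputs; outputs land in a fresh
run directory together with a manifest recording inputs, seeds and a
SHA-256 checksum for every file written.  Deterministic stages reproduce
identical checksums for identical configs and seeds.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np

from . import __version__
from .equilibria import export_equilibria_csv, find_steady_states
from .io import load_config
from .model import BASELINE_PARAMS, Environment, ReducedParams, ReducedState
from .overlap import Signature, overlap_analysis, read_diff_table, select_degs, EX_VIVO_RULE
from .phases import phase_diagram
from .simulate import integrate
from .spatial import cell_density, neighborhood_profile, read_cell_table
from .synth import (
    PlantedOverlapSpec,
    PointPatternSpec,
    generate_point_pattern,
    plant_overlap_instance,
    plant_ranked_instance,
)

logger = logging.getLogger("fibrophase")

KNOWN_STAGES = ("phases", "simulate", "overlap", "spatial", "synth")


class ConfigError(ValueError):
    pass


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _params_from_config(cfg: dict) -> ReducedParams:
    if "params_file" in cfg:
        from .io import load_params

        return load_params(cfg["params_file"])
    if "params" in cfg:
        return ReducedParams.from_dict(cfg["params"])
    return BASELINE_PARAMS


def run(config, out_dir=None) -> dict:
    """Execute the selected stages and return the run manifest."""
    cfg = load_config(config) if not isinstance(config, dict) else config
    stages = cfg.get("stages")
    if not stages:
        raise ConfigError("config must list at least one stage under 'stages'")
    unknown = set(stages) - set(KNOWN_STAGES)
    if unknown:
        raise ConfigError(f"unknown stage name(s): {sorted(unknown)}; known: {KNOWN_STAGES}")

    out = Path(out_dir or cfg.get("out_dir", "fibrophase_run"))
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    written: List[Path] = []

    for stage in stages:
        scfg = cfg.get(stage, {}) or {}
        logger.info("running stage %s", stage)
        try:
            written += _STAGES[stage](scfg, out, seed)
        except (ConfigError, FileNotFoundError):
            raise
        except Exception as exc:  # surface stage name with the failure
            raise StageError(stage, exc) from exc

    manifest = {
        "version": __version__,
        "stages": list(stages),
        "seed": seed,
        "config": {k: v for k, v in cfg.items() if k != "out_dir"},
        "outputs": {str(p.relative_to(out)): _sha256(p) for p in sorted(written)},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def _stage_phases(scfg: dict, out: Path, seed: int) -> List[Path]:
    params = _params_from_config(scfg)
    y = np.geomspace(scfg.get("ymin", 0.05), scfg.get("ymax", 10.0), scfg.get("ny", 60))
    H = np.linspace(scfg.get("hmin", 0.0), scfg.get("hmax", 2.0), scfg.get("nh", 60))
    pd_ = phase_diagram(params, y, H)
    p1, p2, p3 = out / "phase_labels.csv", out / "separatrix.csv", out / "fold.csv"
    pd_.to_csv(p1)
    pd_.curves_to_csv(p2, p3)
    return [p1, p2, p3]


def _stage_simulate(scfg: dict, out: Path, seed: int) -> List[Path]:
    params = _params_from_config(scfg)
    env = Environment(y=float(scfg.get("y", 1.0)), H=float(scfg.get("H", 0.0)))
    init = ReducedState(m=float(scfg.get("m0", 0.1)), f=float(scfg.get("f0", 0.1)))
    traj = integrate(params, env, init, t_end=float(scfg.get("t_end", 500.0)))
    p_traj = out / "trajectory.tsv"
    traj.to_tsv(p_traj)
    p_eq = out / "equilibria.csv"
    export_equilibria_csv(find_steady_states(params, env), p_eq)
    return [p_traj, p_eq]


def _stage_overlap(scfg: dict, out: Path, seed: int) -> List[Path]:
    from .io import read_gene_sets

    if "exvivo_table" in scfg:
        table = read_diff_table(scfg["exvivo_table"])
        exvivo = select_degs(table, scfg.get("exvivo_rule", EX_VIVO_RULE))
        sets = read_gene_sets(scfg["signatures_gmt"])
        signatures = [
            Signature(name=n, genes=frozenset(g)) for n, g in sets.items()
        ]
        pathways = read_gene_sets(scfg["pathways_gmt"]) if "pathways_gmt" in scfg else None
    else:  # synthetic demo instance
        spec = PlantedOverlapSpec(seed=seed)
        exvivo, signatures, _ = plant_overlap_instance(spec)
        pathways = None
    res = overlap_analysis(exvivo, signatures, pathways)
    p_json = out / "overlap.json"
    p_json.write_text(json.dumps(res.to_json_dict(), indent=2))
    p_mat = out / "shared_matrix.csv"
    res.shared_matrix.to_csv(p_mat)
    return [p_json, p_mat]


def _stage_spatial(scfg: dict, out: Path, seed: int) -> List[Path]:
    if "cells_csv" in scfg:
        table = read_cell_table(scfg["cells_csv"])
    else:
        spec = PointPatternSpec(
            intensities={"CD68+/CD206+": 4e-4, "CD8+": 2e-4, "FAP+": 2e-4}, seed=seed
        )
        table = generate_point_pattern(spec)
    radius = float(scfg.get("radius", 7.5))
    p_dens = out / "density.csv"
    cell_density(table, scfg.get("compartment", "interstitium")).to_csv(p_dens, index=False)
    profiles = {}
    for ph in sorted(table["phenotype"].unique()):
        prof = neighborhood_profile(table, ph, radius_um=radius)
        profiles[ph] = {
            "mean": prof.mean_frequency,
            "sd": prof.sd_frequency,
            "n_focal_cells": prof.n_focal_cells,
            "n_isolated": prof.n_isolated,
        }
    p_prof = out / "neighborhood.json"
    p_prof.write_text(json.dumps(profiles, indent=2))
    return [p_dens, p_prof]


def _stage_synth(scfg: dict, out: Path, seed: int) -> List[Path]:
    from .io import write_gmt

    written = []
    kind = scfg.get("kind", "overlap")
    if kind == "overlap":
        spec = PlantedOverlapSpec(seed=seed, **scfg.get("spec", {}))
        exvivo, signatures, truth = plant_overlap_instance(spec)
        p_gmt = out / "signatures.gmt"
        write_gmt({s.name: s.genes for s in signatures}, p_gmt)
        p_ev = out / "exvivo_genes.txt"
        p_ev.write_text("\n".join(sorted(exvivo)) + "\n")
        written += [p_gmt, p_ev]
    elif kind == "ranked":
        df, planted = plant_ranked_instance(
            scfg.get("universe_size", 500), scfg.get("enriched_size", 25),
            scfg.get("effect", 1.0), seed=seed,
        )
        p_tsv = out / "ranked.tsv"
        df.to_csv(p_tsv, sep="\t", index=False)
        p_truth = out / "planted_genes.txt"
        p_truth.write_text("\n".join(sorted(planted)) + "\n")
        written += [p_tsv, p_truth]
    elif kind == "points":
        spec = PointPatternSpec(seed=seed, **scfg.get("spec", {"intensities": {"CD8+": 3e-4}}))
        p_csv = out / "cells.csv"
        generate_point_pattern(spec).to_csv(p_csv, index=False)
        written.append(p_csv)
    else:
        raise ConfigError(f"unknown synth kind {kind!r}")
    return written


_STAGES = {
    "phases": _stage_phases,
    "simulate": _stage_simulate,
    "overlap": _stage_overlap,
    "spatial": _stage_spatial,
    "synth": _stage_synth,
}
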