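"""End-to-end stage orchestration with a combined, reproducible report.

A :class:`RunConfig` (usually loaded from YAML) names the input files and
stage parameters; :func:`run_pipeline` executes the requested stages in
order, writes per-stage CSV/JSON artifacts into the output directory and
a combined ``report.json`` carrying full parameter provenance.  Outputs
are byte-reproducible for a fixed config and seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import read_map, read_structure, sigma_scale
from .pore import compute_pore_profile, hydrophobicity_annotation, min_constriction
from .selectivity import BiIonicCondition, estimate_erev, read_iv_table, selectivity_table
from .sites import CylinderMask, classify_sites, find_nonprotein_peaks, match_peaks

__all__ = ["RunConfig", "ConfigError", "StageError", "run_pipeline"]

logger = logging.getLogger("ionpore")


class ConfigError(ValueError):
    """Invalid or incomplete run configuration."""


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are retained."""


@dataclass
class RunConfig:
    """Validated pipeline configuration.

    ``stages`` maps stage names (``pore``, ``assign_ions``, ``selectivity``)
    to their parameter dictionaries; file-path parameters are checked for
    existence at validation time.
    """

    output_dir: Path
    seed: int = 0
    stages: dict[str, dict[str, Any]] = field(default_factory=dict)

    _PATH_KEYS = ("structure", "map_primary", "map_partner", "model_primary",
                  "model_partner", "iv_file")
    _KNOWN_STAGES = ("pore", "assign_ions", "selectivity")

    def __post_init__(self) -> None:
        self.output_dir = Path(self.output_dir)
        unknown = set(self.stages) - set(self._KNOWN_STAGES)
        if unknown:
            raise ConfigError(f"unknown stages: {sorted(unknown)}")
        for stage, params in self.stages.items():
            if not isinstance(params, dict):
                raise ConfigError(f"stage {stage}: parameters must be a mapping")
            for key in self._PATH_KEYS:
                if key in params and not Path(params[key]).exists():
                    raise ConfigError(f"stage {stage}: file not found: {params[key]}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"config file not found: {path}")
        payload = yaml.safe_load(path.read_text())
        if not isinstance(payload, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        try:
            return cls(
                output_dir=Path(payload.get("output_dir", "ionpore-out")),
                seed=int(payload.get("seed", 0)),
                stages=payload.get("stages", {}),
            )
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"{path}: {exc}") from exc


def _json_default(obj: Any):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, Path):
        return str(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _write_json(payload: dict, path: Path) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=_json_default) + "\n")


def run_pore_stage(params: dict[str, Any], seed: int, outdir: Path) -> dict[str, Any]:
    structure = read_structure(params["structure"])
    z_range = tuple(params["z_range"]) if "z_range" in params else None
    profile = compute_pore_profile(
        structure,
        axis_origin=params.get("axis_origin"),
        axis_direction=params.get("axis_direction"),
        z_range=z_range,
        step=float(params.get("step", 0.5)),
        seed=seed,
    )
    hydrophobicity_annotation(structure, profile,
                              scale=params.get("scale", "kyte-doolittle"))
    z_min, r_min, lining = min_constriction(profile)
    frame = pd.DataFrame(profile.to_records())
    frame.to_csv(outdir / "pore_profile.csv", index=False, float_format="%.6g")
    return {
        "min_radius": r_min,
        "min_radius_z": z_min,
        "constriction_residues": [f"{c}/{r}/{n}" for c, r, n in lining],
        "n_samples": len(profile.samples),
    }


def run_assign_ions_stage(params: dict[str, Any], seed: int, outdir: Path) -> dict[str, Any]:
    map_primary = sigma_scale(read_map(params["map_primary"]))
    map_partner = sigma_scale(read_map(params["map_partner"]))
    model_primary = read_structure(params["model_primary"])
    sigma_primary = float(params.get("sigma_primary", 12.0))
    sigma_partner = float(params.get("sigma_partner", 8.0))
    exclusion = float(params.get("exclusion_radius", 1.8))
    region = None
    if params.get("pore_cylinder_radius"):
        coords = model_primary.coordinates()
        region = CylinderMask(
            axis_origin=coords.mean(axis=0),
            axis_direction=np.array(params.get("axis_direction", [0.0, 0.0, 1.0])),
            radius=float(params["pore_cylinder_radius"]),
        )
    peaks_primary = find_nonprotein_peaks(map_primary, model_primary, sigma_primary,
                                          exclusion_radius=exclusion, region=region)
    peaks_partner = find_nonprotein_peaks(map_partner, model_primary, sigma_partner,
                                          exclusion_radius=exclusion, region=region)
    pairs, unmatched_primary, _ = match_peaks(
        peaks_primary, peaks_partner,
        criterion=params.get("criterion", "voxel_overlap"),
        cutoff=float(params.get("cutoff", 1.5)))
    assignments = classify_sites(pairs, unmatched_primary)
    rows = [{
        "label": a.label,
        "classification": a.classification,
        "x": a.peak_primary.centroid[0],
        "y": a.peak_primary.centroid[1],
        "z": a.peak_primary.centroid[2],
        "max_sigma_primary": a.peak_primary.max_sigma,
        "centroid_distance": a.centroid_distance,
        "amplitude_ratio": a.amplitude_ratio,
    } for a in assignments]
    pd.DataFrame(rows).to_csv(outdir / "ion_sites.csv", index=False, float_format="%.6g")
    ion_ratios = [a.amplitude_ratio for a in assignments if a.classification == "ion"]
    return {
        "n_ion_sites": sum(a.classification == "ion" for a in assignments),
        "n_water_sites": sum(a.classification == "water" for a in assignments),
        "mean_amplitude_ratio": float(np.mean(ion_ratios)) if ion_ratios else None,
    }


def run_selectivity_stage(params: dict[str, Any], seed: int, outdir: Path) -> dict[str, Any]:
    condition = BiIonicCondition(
        species_internal=params.get("species_internal", "K"),
        species_external=params.get("species_external", "Na"),
        conc_internal=float(params.get("conc_internal", 150.0)),
        conc_external=float(params.get("conc_external", 150.0)),
        temperature=float(params.get("temperature", 298.15)),
    )
    families = read_iv_table(params["iv_file"], condition)
    table = selectivity_table(list(families.values()), labels=list(families))
    table.to_csv(outdir / "selectivity.csv", index=False, float_format="%.6g")
    return {"constructs": table.to_dict(orient="records")}


_STAGE_RUNNERS = {
    "pore": run_pore_stage,
    "assign_ions": run_assign_ions_stage,
    "selectivity": run_selectivity_stage,
}


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute the configured stages and write a combined JSON report.

    Returns the report payload.  A stage failure raises :class:`StageError`
    naming the stage; outputs of earlier stages are retained.
    """
    config.output_dir.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {
        "tool": "ionpore",
        "version": __version__,
        "seed": config.seed,
        "parameters": {name: dict(params) for name, params in config.stages.items()},
        "stages": {},
    }
    for name in self_ordered(config.stages):
        runner = _STAGE_RUNNERS[name]
        logger.info("[%s] starting", name)
        try:
            report["stages"][name] = runner(config.stages[name], config.seed,
                                            config.output_dir)
        except Exception as exc:
            _write_json(report, config.output_dir / "report.json")
            raise StageError(f"stage {name!r} failed: {exc}") from exc
        logger.info("[%s] done", name)
    _write_json(report, config.output_dir / "report.json")
    return report


def self_ordered(stages: dict[str, Any]) -> list[str]:
    """Stages in canonical execution order."""
    return [name for name in ("pore", "assign_ions", "selectivity") if name in stages]
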