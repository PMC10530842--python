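"""Configuration files, result export and run manifests.

Configs are YAML (or JSON) mappings mirroring the dataclasses they build;
unknown keys are rejected so typos fail loudly.  Every export writes a
``manifest.json`` recording the tool version, the config snapshot, the
seed and SHA-256 hashes of the written files, so a results directory can
be verified after the fact.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .imaging import CameraModel, CompressionRecord
from .pores import PoreField
from .solver import ProcessConfig, SimulationResult
from .traces import write_trace_csv

__all__ = [
    "load_config",
    "save_config",
    "load_camera",
    "export_results",
    "write_manifest",
    "verify_manifest",
]


def _load_mapping(path: str | Path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".json":
        data = json.loads(text) if text.strip() else {}
    else:
        data = yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a mapping at the top level")
    return data


def load_config(path: str | Path) -> ProcessConfig:
    """Build a :class:`ProcessConfig` from a YAML/JSON file.

    Missing keys take the reference-process defaults (an empty file is the
    default -19 degC run); unknown keys raise listing the offenders.
    """
    data = _load_mapping(path)
    fields = {f.name for f in dataclasses.fields(ProcessConfig)}
    unknown = sorted(set(data) - fields)
    if unknown:
        raise ValueError(f"unknown configuration keys: {unknown}")
    if "probe_points" in data:
        data["probe_points"] = tuple(tuple(p) for p in data["probe_points"])
    return ProcessConfig(**data)


def save_config(config: ProcessConfig, path: str | Path) -> None:
    d = dataclasses.asdict(config)
    d["probe_points"] = [list(p) for p in config.probe_points]
    Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


def load_camera(path: str | Path) -> CameraModel:
    """Camera calibration file: ``base_scale`` (px/mm), ``working_distance`` (mm)."""
    data = _load_mapping(path)
    unknown = sorted(set(data) - {"base_scale", "working_distance"})
    if unknown:
        raise ValueError(f"unknown camera keys: {unknown}")
    return CameraModel(**data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_manifest(out_dir: str | Path, files: list[Path],
                   config: dict | None = None, seed: int | None = None,
                   wall_time_s: float | None = None) -> Path:
    """Write ``manifest.json`` with version, config snapshot and file hashes."""
    out_dir = Path(out_dir)
    manifest = {
        "tool": "cryogel",
        "version": __version__,
        "seed": seed,
        "config": config,
        "wall_time_s": wall_time_s,
        "outputs": {p.name: _sha256(p) for p in sorted(files)},
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path


def verify_manifest(out_dir: str | Path) -> bool:
    """Re-hash the files listed in a directory's manifest."""
    out_dir = Path(out_dir)
    manifest = json.loads((out_dir / "manifest.json").read_text())
    return all(
        _sha256(out_dir / name) == digest
        for name, digest in manifest["outputs"].items()
    )


def _export_simulation(result: SimulationResult, out_dir: Path) -> list[Path]:
    files = []
    for trace in result.probe_traces:
        r_mm, z_mm = trace.position[0] * 1e3, trace.position[1] * 1e3
        p = out_dir / f"probe_r{r_mm:05.1f}mm_z{z_mm:05.1f}mm.csv"
        write_trace_csv(trace, p)
        files.append(p)
    # final temperature / solid-fraction fields over the gel
    r, z = result.grid.cell_coords()
    cells = result.cryogel_cells
    field = np.column_stack([
        r[cells] * 1e3, z[cells] * 1e3, result.T_history[-1], result.theta_history[-1],
    ])
    p = out_dir / "final_field.csv"
    np.savetxt(p, field, delimiter=",", fmt="%.6g",
               header="r_mm,z_mm,T_degC,theta_ph1", comments="")
    files.append(p)
    # dense history for downstream pore analysis (regeneratable binary)
    p = out_dir / "history.npz"
    np.savez_compressed(
        p, times=result.times, cells=result.cryogel_cells,
        T_history=result.T_history, theta_history=result.theta_history,
    )
    files.append(p)
    return files


def _export_pores(pf: PoreField, out_dir: Path) -> list[Path]:
    p = out_dir / "pores.csv"
    pf.to_dataframe().to_csv(p, index=False, float_format="%.6g")
    return [p]


def _export_compression(rec: CompressionRecord, out_dir: Path) -> list[Path]:
    files = []
    p = out_dir / "geometry.csv"
    rows = np.array([
        [f.t, f.height_mm, f.diameter_mm, f.volume_mL, float(f.flagged)]
        for f in rec.frames
    ])
    np.savetxt(p, rows, delimiter=",", fmt="%.6g",
               header="time_s,height_mm,diameter_mm,volume_mL,shadow_flag",
               comments="")
    files.append(p)
    if rec.stress_kPa.size:
        p = out_dir / "stress.csv"
        np.savetxt(p, np.column_stack([rec.force_times, rec.stress_kPa]),
                   delimiter=",", fmt="%.6g", header="time_s,stress_kPa",
                   comments="")
        files.append(p)
    return files


def export_results(result, out_dir: str | Path, seed: int | None = None,
                   config: dict | None = None) -> list[Path]:
    """Write a result object as CSV files plus a manifest.

    Dispatches on the result type (simulation, pore field or compression
    record); file ordering and content are deterministic so repeated
    exports of the same result hash identically.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()
    if isinstance(result, SimulationResult):
        files = _export_simulation(result, out_dir)
        if config is None:
            config = dataclasses.asdict(result.config)
            config["probe_points"] = [list(p) for p in result.config.probe_points]
    elif isinstance(result, PoreField):
        files = _export_pores(result, out_dir)
    elif isinstance(result, CompressionRecord):
        files = _export_compression(result, out_dir)
    else:
        raise TypeError(f"cannot export object of type {type(result).__name__}")
    write_manifest(out_dir, files, config=config, seed=seed,
                   wall_time_s=round(time.perf_counter() - t0, 3))
    return files
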