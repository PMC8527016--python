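"""File formats, run configuration and result logging.

Spectra travel as CSV (dialect version 1: header row
``seed_id,variety_id,point_index,<wavelength values...>``, one
spectrum per subsequent row) or as an equivalent NPZ container, which
round-trips losslessly.  Run configuration is a YAML file validated
against a strict schema — unknown keys are rejected — covering the
simulation, preprocessing, model and training blocks.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path
from typing import Optional

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field

from .sim import SimConfig, SpectraDataset, SpectrumRecord

__all__ = [
    "read_spectra",
    "write_spectra",
    "RunConfig",
    "load_config",
    "config_hash",
    "write_result",
]

CSV_DIALECT_VERSION = 1
_META_COLUMNS = ("seed_id", "variety_id", "point_index")


def write_spectra(dataset: SpectraDataset, path) -> None:
    """Write a dataset as dialect CSV or (for .npz paths) NPZ."""
    path = Path(path)
    if path.suffix == ".npz":
        np.savez(path,
                 wavelengths=dataset.wavelengths,
                 intensities=dataset.intensity_matrix(),
                 seed_id=np.array(dataset.seed_ids()),
                 variety_id=dataset.labels(),
                 point_index=np.array([r.point_index
                                       for r in dataset.records]))
        return
    with open(path, "w") as fh:
        wl = ",".join(f"{w:.6g}" for w in dataset.wavelengths)
        fh.write(f"{','.join(_META_COLUMNS)},{wl}\n")
        for r in dataset.records:
            vals = ",".join(f"{v:.9g}" for v in r.intensities)
            fh.write(f"{r.seed_id},{r.variety_id},{r.point_index},{vals}\n")


def _fail(path, row, msg):
    raise ValueError(f"{path}, row {row}: {msg}")


def read_spectra(path) -> SpectraDataset:
    """Read the CSV dialect or the NPZ container, with validation."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix == ".npz":
        with np.load(path, allow_pickle=False) as d:
            wl = d["wavelengths"]
            X = d["intensities"]
            sids = [str(s) for s in d["seed_id"]]
            vids = d["variety_id"]
            pts = d["point_index"]
        records = [SpectrumRecord(s, int(v), int(p), x)
                   for s, v, p, x in zip(sids, vids, pts, X)]
        return _validated(path, wl, records)
    with open(path) as fh:
        header = fh.readline().strip()
        if not header:
            raise ValueError(f"{path}: no spectra (empty file)")
        cols = header.split(",")
        if tuple(cols[:3]) != _META_COLUMNS:
            raise ValueError(f"{path}: header must start with "
                             f"{','.join(_META_COLUMNS)}")
        try:
            wl = np.array([float(c) for c in cols[3:]])
        except ValueError:
            raise ValueError(f"{path}: non-numeric wavelength in header")
        records = []
        for row, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            parts = line.split(",")
            if len(parts) != 3 + len(wl):
                _fail(path, row, f"expected {3 + len(wl)} fields, "
                                 f"got {len(parts)}")
            try:
                intens = np.array([float(v) for v in parts[3:]])
            except ValueError:
                _fail(path, row, "non-numeric intensity")
            records.append(SpectrumRecord(parts[0], int(parts[1]),
                                          int(parts[2]), intens))
    if not records:
        raise ValueError(f"{path}: no spectra")
    return _validated(path, wl, records)


def _validated(path, wl, records) -> SpectraDataset:
    if len(records) == 0:
        raise ValueError(f"{path}: no spectra")
    if len(wl) > 1 and np.any(np.diff(wl) <= 0):
        j = int(np.argmax(np.diff(wl) <= 0))
        raise ValueError(f"{path}: wavelengths not strictly increasing "
                         f"at column {j + 4}")
    seen = set()
    for i, r in enumerate(records):
        row = i + 2
        if r.point_index not in (1, 2, 3):
            _fail(path, row, f"point_index {r.point_index} not in 1..3")
        key = (r.seed_id, r.point_index)
        if key in seen:
            _fail(path, row, f"duplicate (seed_id, point_index) {key}")
        seen.add(key)
    return SpectraDataset(wavelengths=np.asarray(wl, dtype=float),
                          records=records)


# ----------------------------------------------------------------------
class SimBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_varieties: int = 10
    seeds_per_variety: int = 200
    spectra_per_seed: int = 3
    grid_start_nm: float = 230.0
    grid_end_nm: float = 904.0
    grid_step_nm: float = 0.05
    noise_sd: float = 0.01
    shot_fluctuation_sd: float = 0.10
    baseline_amplitude: float = 0.05
    profile_separation: float = 0.25
    rng_seed: int = 0

    def to_sim_config(self) -> SimConfig:
        d = self.model_dump()
        d.pop("profile_separation")
        return SimConfig(**d)


class PreprocessBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    crop_lo_nm: float = 242.0
    crop_hi_nm: float = 882.0
    rel_threshold: float = 1e-6
    ratio: tuple[int, int, int] = (3, 1, 1)
    rng_seed: int = 0


class ModelBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    dims: int = 2
    mode: str = "shared"        # fixed | per_block | shared
    rng_seed: int = 0


class TrainBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    stages: list[tuple[float, float]] = Field(
        default=[(0.25, 0.84), (0.124, 0.86), (0.05, 0.88), (0.01, 0.887)])
    max_epochs_per_stage: int = 100
    batch_size: int = 64
    rng_seed: int = 0


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    simulation: SimBlock = SimBlock()
    preprocessing: PreprocessBlock = PreprocessBlock()
    model: ModelBlock = ModelBlock()
    training: TrainBlock = TrainBlock()


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(raw)


def config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(cfg.model_dump(), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def write_result(path, payload: dict, cfg: Optional[RunConfig] = None,
                 seeds: Optional[dict] = None) -> None:
    """Machine-readable result file with full provenance."""
    out = {"timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
           "result": payload}
    if cfg is not None:
        out["config"] = cfg.model_dump()
        out["config_hash"] = config_hash(cfg)
    if seeds is not None:
        out["rng_seeds"] = seeds
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(out, fh, indent=2, default=_json_default)


def _json_default(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.integer, np.floating)):
        return o.item()
    raise TypeError(f"not JSON serializable: {type(o)}")
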