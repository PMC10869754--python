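"""File I/O and configuration.

Feature tables are the pipeline's interchange currency: trajectory
ensembles of feature vectors are serialized to HDF5 (one group per
trajectory) or CSV, model parameters and pipeline configuration to YAML,
and diagnostics to JSON.  Coordinate-level input (PDB topologies, DCD/XTC
trajectories) is read through MDAnalysis and only needed for the
featurization stage.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from .features import StructureFrame
from .synthetic import ShortTrajectoryEnsemble

__all__ = [
    "PipelineConfig",
    "load_config",
    "save_ensemble",
    "load_ensemble",
    "ensemble_to_csv",
    "ensemble_from_csv",
    "read_structure",
    "read_trajectory",
    "write_json",
]


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------


class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimulateConfig(_StrictModel):
    """Surrogate-data generation parameters."""

    n_traj: int = 900
    n_frames: int = 300
    kT: float = 1.0
    n_basins: int = 5
    n_features: int = 20
    noise_scale: float = 0.25
    charge_gap: float = 0.9
    timestep: float = 2e-4
    save_interval: int = 25
    start_jitter: float = 0.15


class StateConfig(_StrictModel):
    center: tuple[float, float]
    radii: tuple[float, float]


class StatesConfig(_StrictModel):
    down: StateConfig = StateConfig(center=(-4.24, -56.95), radii=(1.1, 8.0))
    up: StateConfig = StateConfig(center=(-0.506, 3.94), radii=(0.84, 7.6))


class BasisConfig(_StrictModel):
    whiten_tol: float = 1e-8
    k: int = 200
    ivac_dims: int = 10
    ivac_min_lag: int = 1
    ivac_max_lag: int = 5
    mini_batch: bool = True


class LassoConfig(_StrictModel):
    lambda_lower: float = 0.02
    lambda_upper: float = 0.03
    n_samples: int = 100_000


class PipelineConfig(_StrictModel):
    """Full pipeline configuration; every stochastic stage draws its seed
    from ``seed`` so reruns are bit-identical."""

    seed: int
    lag: int = 10
    kT: float = 1.0
    bins: int = 28
    voltages_mV: list[float] = Field(default_factory=lambda: [-50.0, 0.0, 50.0])
    tcf_lags: list[int] = Field(default_factory=lambda: [0, 1, 2, 4, 8, 16, 32, 64])
    simulate: SimulateConfig = SimulateConfig()
    states: StatesConfig = StatesConfig()
    basis: BasisConfig = BasisConfig()
    lasso: LassoConfig = LassoConfig()
    features_path: str | None = None


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return PipelineConfig(**raw)


def save_config(config: PipelineConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(json.loads(config.model_dump_json()), fh, sort_keys=False)


# --------------------------------------------------------------------------
# ensemble serialization
# --------------------------------------------------------------------------


def save_ensemble(path: str | Path, ensemble: ShortTrajectoryEnsemble,
                  column_names: list[str] | None = None) -> None:
    """HDF5 layout: datasets ``/traj_<k>/features``; file attributes
    ``save_interval`` and ``seed``."""
    with h5py.File(path, "w") as fh:
        fh.attrs["save_interval"] = ensemble.save_interval
        fh.attrs["seed"] = -1 if ensemble.seed is None else ensemble.seed
        fh.attrs["start_distribution_tag"] = ensemble.start_distribution_tag
        if column_names is not None:
            fh.attrs["column_names"] = column_names
        for k, traj in enumerate(ensemble.trajectories):
            fh.create_dataset(f"traj_{k}/features", data=np.asarray(traj, dtype=float))


def load_ensemble(path: str | Path) -> tuple[ShortTrajectoryEnsemble, list[str] | None]:
    with h5py.File(path, "r") as fh:
        keys = sorted((k for k in fh.keys() if k.startswith("traj_")),
                      key=lambda s: int(s.split("_")[1]))
        trajs = [fh[f"{k}/features"][...] for k in keys]
        seed = int(fh.attrs.get("seed", -1))
        cols = fh.attrs.get("column_names")
        ens = ShortTrajectoryEnsemble(
            trajectories=trajs,
            save_interval=float(fh.attrs["save_interval"]),
            start_distribution_tag=str(fh.attrs.get("start_distribution_tag", "")),
            seed=None if seed < 0 else seed,
        )
    return ens, None if cols is None else [str(c) for c in cols]


def ensemble_to_csv(path: str | Path, ensemble: ShortTrajectoryEnsemble,
                    column_names: list[str] | None = None) -> None:
    """One row per frame with ``traj_id``/``frame_id`` index columns."""
    frames = []
    for k, traj in enumerate(ensemble.trajectories):
        arr = np.atleast_2d(np.asarray(traj, dtype=float))
        cols = column_names or [f"f{i}" for i in range(arr.shape[1])]
        df = pd.DataFrame(arr, columns=cols)
        df.insert(0, "frame_id", np.arange(len(arr)))
        df.insert(0, "traj_id", k)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def ensemble_from_csv(path: str | Path, save_interval: float = 1.0) -> tuple[ShortTrajectoryEnsemble, list[str]]:
    df = pd.read_csv(path)
    cols = [c for c in df.columns if c not in ("traj_id", "frame_id")]
    trajs = [
        g.sort_values("frame_id")[cols].to_numpy(dtype=float)
        for _, g in df.groupby("traj_id", sort=True)
    ]
    return ShortTrajectoryEnsemble(trajectories=trajs, save_interval=save_interval), cols


# --------------------------------------------------------------------------
# coordinate-level readers (MDAnalysis)
# --------------------------------------------------------------------------


def _frame_from_universe(u) -> StructureFrame:
    atoms = u.atoms
    try:
        charges = atoms.charges.copy()
    except Exception:
        charges = None
    box = u.dimensions
    return StructureFrame(
        coords=atoms.positions.astype(float),
        atom_names=[str(n) for n in atoms.names],
        residue_ids=atoms.resids.astype(int),
        residue_names=[str(n) for n in atoms.resnames],
        charges=charges,
        box_length_z=float(box[2]) if box is not None and box[2] > 0 else None,
        unwrapped_z=None,
    )


def read_structure(path: str | Path) -> StructureFrame:
    """Read a PDB (or other MDAnalysis-supported) structure into a frame."""
    import MDAnalysis as mda

    u = mda.Universe(str(path))
    return _frame_from_universe(u)


def read_trajectory(paths: list[str | Path], topology: str | Path):
    """Iterate StructureFrames over one or more DCD/XTC trajectories.

    Raises a descriptive error when the trajectory atom count does not
    match the topology.
    """
    import MDAnalysis as mda

    top = mda.Universe(str(topology))
    n_top = len(top.atoms)
    for p in paths:
        try:
            u = mda.Universe(str(topology), str(p))
        except ValueError as err:
            raise ValueError(
                f"atom-count mismatch between topology ({n_top} atoms) and "
                f"trajectory {p}: {err}"
            ) from err
        for _ in u.trajectory:
            yield _frame_from_universe(u)


def write_json(path: str | Path, payload: dict) -> None:
    def _default(obj):
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        raise TypeError(f"not JSON serializable: {type(obj)}")

    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=_default, allow_nan=True)
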