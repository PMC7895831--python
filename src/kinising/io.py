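"""Serialisation of model parameters, ensembles and moment series.

ModelParameters go to JSON (H as list, J as nested list) or HDF5;
trajectory ensembles to HDF5 (``/spins`` as int8 with seed/shape attrs);
moment series to long-format CSV (columns t, i, k, statistic, value) or
HDF5.  Spin rasters read from file must already be in the {-1, +1}
convention; {0, 1} rasters are rejected unless an explicit conversion is
requested.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .core_model import ModelParameters, MomentSeries, TrajectoryEnsemble

__all__ = [
    "save_params_json",
    "load_params_json",
    "save_params_hdf5",
    "load_params_hdf5",
    "save_ensemble_hdf5",
    "load_ensemble_hdf5",
    "moment_series_to_frame",
    "save_moments_csv",
    "save_moments_hdf5",
    "load_moments_hdf5",
]


def save_params_json(params: ModelParameters, path) -> None:
    payload = {"H": params.H.tolist(), "J": params.J.tolist()}
    Path(path).write_text(json.dumps(payload))


def load_params_json(path) -> ModelParameters:
    payload = json.loads(Path(path).read_text())
    return ModelParameters(H=np.array(payload["H"]), J=np.array(payload["J"]))


def save_params_hdf5(params: ModelParameters, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("H", data=params.H)
        f.create_dataset("J", data=params.J)


def load_params_hdf5(path) -> ModelParameters:
    with h5py.File(path, "r") as f:
        return ModelParameters(H=f["H"][:], J=f["J"][:])


def save_ensemble_hdf5(ens: TrajectoryEnsemble, path) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("spins", data=ens.data, dtype="i1", compression="gzip")
        d.attrs["seed"] = -1 if ens.seed is None else ens.seed
        d.attrs["N"] = ens.N
        d.attrs["T"] = ens.T
        d.attrs["R"] = ens.R
        d.attrs["params_id"] = ens.params_id


def load_ensemble_hdf5(path, convert_01: bool = False) -> TrajectoryEnsemble:
    """Load a spin raster; set ``convert_01`` to map {0,1} data to {-1,+1}."""
    with h5py.File(path, "r") as f:
        d = f["spins"]
        data = d[:]
        seed = int(d.attrs.get("seed", -1))
        params_id = str(d.attrs.get("params_id", ""))
    vals = np.unique(data)
    if np.isin(vals, (0, 1)).all():
        if not convert_01:
            raise ValueError(
                "raster looks {0,1}-coded; pass convert_01=True to convert"
            )
        data = 2 * data.astype(np.int8) - 1
    return TrajectoryEnsemble(
        data=data, seed=None if seed < 0 else seed, params_id=params_id
    )


def moment_series_to_frame(series: MomentSeries) -> pd.DataFrame:
    """Long-format view: one row per (t, i, k, statistic)."""
    rows = []
    T, N = series.T, series.N
    for t in range(T + 1):
        for i in range(N):
            rows.append((t, i, -1, "m", series.m[t, i]))
        for i in range(N):
            for k in range(N):
                rows.append((t, i, k, "C", series.C[t, i, k]))
                rows.append((t, i, k, "D", series.D[t, i, k]))
    return pd.DataFrame(rows, columns=["t", "i", "k", "statistic", "value"])


def save_moments_csv(series: MomentSeries, path) -> None:
    moment_series_to_frame(series).to_csv(path, index=False)


def save_moments_hdf5(series: MomentSeries, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("m", data=series.m)
        f.create_dataset("C", data=series.C)
        f.create_dataset("D", data=series.D)


def load_moments_hdf5(path) -> MomentSeries:
    with h5py.File(path, "r") as f:
        return MomentSeries(m=f["m"][:], C=f["C"][:], D=f["D"][:])
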