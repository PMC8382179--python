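"""HDF5/CSV persistence and deterministic test fixtures.

Arrays (strain fields, spike rasters, feature matrices, sensor weights) go
to HDF5 with their parameters and seeds stored as attributes; tabular
results go to CSV.  Every artifact carries enough provenance (parameters,
seed, package version) to be regenerated exactly.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np

from .encoding import FirstSpikeMatrix, SpikeRaster
from .wing import (Axis, FlappingKinematics, RotationCondition, SensorGrid,
                   StrainField, SurrogateSpec, WingParams, surrogate_strain)

__all__ = ["save_strain", "load_strain", "save_raster", "load_raster",
           "save_features", "load_features", "features_to_csv",
           "save_weights", "make_fixtures"]


def _params_json(obj) -> str:
    def plain(o):
        if dataclasses.is_dataclass(o):
            return {f.name: plain(getattr(o, f.name))
                    for f in dataclasses.fields(o)}
        if isinstance(o, Axis):
            return o.value
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        return o
    return json.dumps(plain(obj))


def save_strain(field: StrainField, path) -> None:
    with h5py.File(path, "w") as h5:
        h5.create_dataset("strain", data=field.data, compression="gzip",
                          compression_opts=4)
        h5.create_dataset("coordinates", data=field.grid.coordinates())
        h5.attrs["dt"] = field.dt
        h5.attrs["direction"] = field.direction
        h5.attrs["grid"] = _params_json(field.grid)
        if field.wing is not None:
            h5.attrs["wing"] = _params_json(field.wing)
        if field.kinematics is not None:
            h5.attrs["kinematics"] = _params_json(field.kinematics)
        if field.condition is not None:
            h5.attrs["condition"] = _params_json(field.condition)
        if field.seed is not None:
            h5.attrs["seed"] = field.seed
        from . import __version__
        h5.attrs["wingsense_version"] = __version__


def load_strain(path) -> StrainField:
    with h5py.File(path, "r") as h5:
        data = h5["strain"][...]
        grid = SensorGrid(**json.loads(h5.attrs["grid"]))
        wing = (WingParams(**json.loads(h5.attrs["wing"]))
                if "wing" in h5.attrs else None)
        kin = (FlappingKinematics(**json.loads(h5.attrs["kinematics"]))
               if "kinematics" in h5.attrs else None)
        cond = (RotationCondition(**json.loads(h5.attrs["condition"]))
                if "condition" in h5.attrs else None)
        return StrainField(data=data, dt=float(h5.attrs["dt"]), grid=grid,
                           direction=str(h5.attrs["direction"]),
                           condition=cond, wing=wing, kinematics=kin,
                           seed=int(h5.attrs["seed"]) if "seed" in h5.attrs else None)


def save_raster(raster: SpikeRaster, path) -> None:
    with h5py.File(path, "w") as h5:
        h5.create_dataset("spikes", data=raster.data, compression="gzip",
                          compression_opts=4)
        h5.attrs["dt"] = raster.dt
        if raster.seed is not None:
            h5.attrs["seed"] = raster.seed


def load_raster(path) -> SpikeRaster:
    with h5py.File(path, "r") as h5:
        return SpikeRaster(data=h5["spikes"][...], dt=float(h5.attrs["dt"]),
                           seed=int(h5.attrs["seed"]) if "seed" in h5.attrs else None)


def save_features(features: FirstSpikeMatrix, path) -> None:
    with h5py.File(path, "w") as h5:
        h5.create_dataset("first_spike_ms", data=features.data,
                          compression="gzip", compression_opts=4)
        if features.labels is not None:
            h5.create_dataset("labels", data=np.asarray(features.labels))


def load_features(path) -> FirstSpikeMatrix:
    with h5py.File(path, "r") as h5:
        labels = h5["labels"][...] if "labels" in h5 else None
        return FirstSpikeMatrix(data=h5["first_spike_ms"][...], labels=labels)


def features_to_csv(features: FirstSpikeMatrix, path) -> None:
    """Observations x sensors table with a trailing label column."""
    import pandas as pd

    df = pd.DataFrame(features.data,
                      columns=[f"sensor_{i}" for i in range(features.n_locations)])
    if features.labels is not None:
        df["label"] = features.labels
    df.to_csv(path, index=False)


def save_weights(s: np.ndarray, selected: np.ndarray, grid: SensorGrid, path) -> None:
    import pandas as pd

    coords = grid.coordinates()
    agg = np.linalg.norm(np.atleast_2d(np.asarray(s).T).T, axis=1)
    df = pd.DataFrame({"sensor": np.arange(len(agg)),
                       "spanwise_m": coords[:, 0], "chordwise_m": coords[:, 1],
                       "weight": agg,
                       "selected": np.isin(np.arange(len(agg)), selected)})
    df.to_csv(path, index=False)


def make_fixtures(kind: str = "separable", seed: int = 0,
                  grid: SensorGrid | None = None):
    """Deterministic miniature surrogate data sets for tests and examples.

    ``kind``: "separable" (classes differ strongly in twist -> downstream
    accuracy ~1), "weak" (10% twist contrast), or "chance" (identical class
    parameters).  Returns (StrainField condition A, StrainField condition B).
    """
    grid = grid or SensorGrid(chordwise_count=6, spanwise_count=11)
    specs = {
        "separable": (SurrogateSpec(bend_amp=1.0, twist_amp=0.05, noise_sd=0.01),
                      SurrogateSpec(bend_amp=1.0, twist_amp=0.45, noise_sd=0.01)),
        "weak": (SurrogateSpec(bend_amp=1.0, twist_amp=0.30, noise_sd=0.02),
                 SurrogateSpec(bend_amp=1.0, twist_amp=0.33, noise_sd=0.02)),
        "chance": (SurrogateSpec(bend_amp=1.0, twist_amp=0.2, noise_sd=0.02),
                   SurrogateSpec(bend_amp=1.0, twist_amp=0.2, noise_sd=0.02)),
    }
    if kind not in specs:
        raise ValueError(f"unknown fixture kind {kind!r}")
    sa, sb = specs[kind]
    ss = np.random.SeedSequence(seed).generate_state(2)
    a = surrogate_strain(sa, grid=grid, duration=1.2, seed=int(ss[0] % (2**31)))
    b = surrogate_strain(sb, grid=grid, duration=1.2, seed=int(ss[1] % (2**31)))
    return a, b
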