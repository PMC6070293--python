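"""HDF5 persistence for sampled trajectories."""

from __future__ import annotations

import dataclasses
import json

import h5py

from .model import ModelParams, Trajectory

__all__ = ["save_trajectory", "load_trajectory"]

_ARRAYS = ("times", "crt", "max_crt", "argmax_crt", "tot_rt", "tot_rd",
           "tot_gap", "ec", "active_fraction", "crd_far")
_OPTIONAL = ("crd", "cgap", "cgef")


def save_trajectory(traj: Trajectory, path) -> None:
    """Write the trajectory's samples and parameter snapshot to HDF5.

    The mesh itself is not stored (rebuild it from its spec); snapshots
    are kept in float32 as sampled.
    """
    with h5py.File(path, "w") as fh:
        for name in _ARRAYS:
            fh.create_dataset(name, data=getattr(traj, name))
        for name in _OPTIONAL:
            value = getattr(traj, name)
            if value is not None:
                fh.create_dataset(name, data=value)
        fh.attrs["seed"] = traj.seed
        fh.attrs["clipped_mass"] = traj.clipped_mass
        fh.attrs["params"] = json.dumps(dataclasses.asdict(traj.params))


def load_trajectory(path, mesh=None) -> Trajectory:
    with h5py.File(path, "r") as fh:
        kw = {name: fh[name][...] for name in _ARRAYS}
        for name in _OPTIONAL:
            kw[name] = fh[name][...] if name in fh else None
        params = ModelParams(**json.loads(fh.attrs["params"]))
        return Trajectory(
            params=params, seed=int(fh.attrs["seed"]),
            clipped_mass=float(fh.attrs["clipped_mass"]), mesh=mesh, **kw,
        )
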