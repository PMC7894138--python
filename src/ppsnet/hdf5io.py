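"""HDF5 checkpoints and stream audit files.

A checkpoint stores /W, /b_u, /b_m (plus /W2... for stagewise networks),
the population slice table, and provenance attributes (epoch, seed,
config YAML and its hash).
"""

from __future__ import annotations

import json

import h5py
import numpy as np
import yaml

from .config import TrainingConfig
from .rbm import NetworkParams

__all__ = ["save_checkpoint", "load_checkpoint", "save_stream"]


def _write_params(g: h5py.Group, params: NetworkParams) -> None:
    g.create_dataset("W", data=params.W)
    g.create_dataset("b_u", data=params.b_u)
    g.create_dataset("b_m", data=params.b_m)
    g.attrs["slices"] = json.dumps(
        {k: [s.start, s.stop] for k, s in params.slices.items()})


def _read_params(g: h5py.Group) -> NetworkParams:
    slices = {k: slice(a, b)
              for k, (a, b) in json.loads(g.attrs["slices"]).items()}
    return NetworkParams(g["W"][()], g["b_u"][()], g["b_m"][()], slices)


def save_checkpoint(path, params: NetworkParams,
                    config: TrainingConfig | None = None,
                    epoch: int | None = None,
                    seed: int | None = None,
                    params2: NetworkParams | None = None) -> None:
    """Write a (possibly stagewise) checkpoint with provenance attributes."""
    with h5py.File(path, "w") as f:
        _write_params(f, params)
        if params2 is not None:
            _write_params(f.create_group("stage2"), params2)
        if epoch is not None:
            f.attrs["epoch"] = int(epoch)
        if seed is not None:
            f.attrs["seed"] = int(seed)
        if config is not None:
            f.attrs["config"] = yaml.safe_dump(config.to_dict(), sort_keys=True)
            f.attrs["config_hash"] = config.hash


def load_checkpoint(path):
    """Read a checkpoint; returns (params, params2 or None, meta dict)."""
    with h5py.File(path, "r") as f:
        params = _read_params(f)
        params2 = _read_params(f["stage2"]) if "stage2" in f else None
        meta = {k: f.attrs[k] for k in f.attrs if k != "slices"}
    if "config" in meta:
        meta["config"] = TrainingConfig.from_dict(yaml.safe_load(meta["config"]))
    return params, params2, meta


def save_stream(path, batch) -> None:
    """Audit dump of a world batch (positions, angles, gains, touch)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("hand_pos", data=batch.hand_pos)
        f.create_dataset("vis_pos", data=batch.vis_pos)
        f.create_dataset("touch", data=batch.touch.astype(np.uint8))
        g = f.create_group("gains")
        for k, v in batch.gains.items():
            g.create_dataset(k, data=v)
        for name in ("joint_angles", "gaze", "vis_pos_eye",
                     "handvis_pos", "handvis_category"):
            val = getattr(batch, name)
            if val is not None:
                f.create_dataset(name, data=val)
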