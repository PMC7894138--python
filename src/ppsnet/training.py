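"""Training orchestration: stimulus encoding, epoch loop, three-layer stage.

One epoch draws fresh world samples, encodes them into the visible layer
(tactile counts first, then proprioceptive, visual and any extra
populations) and applies one CD-1 update per batch.  Per-epoch metrics
(reconstruction error, optionally the visuo-proprioceptive overlap index)
are collected into a tidy table; parameter snapshots can be kept at named
epochs.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import popcode, rbm, worldgen
from .config import TrainingConfig
from .popcode import (N_TACTILE, PopulationLayout, encode_position,
                      encode_tactile, gaze_layout, proprioceptive_layout,
                      visual_layout)
from .rbm import NetworkParams, cd1_update, init_params, make_slices

logger = logging.getLogger(__name__)

__all__ = ["build_layouts", "encode_batch", "train", "train_stagewise",
           "TrainOutput", "sample_world"]


def build_layouts(config: TrainingConfig) -> dict[str, PopulationLayout | None]:
    """Ordered population layouts of the visible layer for this variant.

    The tactile population is homogeneous (no spatial layout) and maps to
    None.  Order fixes the slice layout: tactile, proprioceptive, visual,
    then hand-visual / gaze when present.
    """
    joint = config.variant in ("joint", "gaze")
    layouts: dict[str, PopulationLayout | None] = {
        "tactile": None,
        "proprioceptive": proprioceptive_layout(config.proprio_n, joint_angles=joint),
        "visual": visual_layout(config.visual_n),
    }
    if config.variant == "handvision":
        layouts["handvis"] = dataclasses.replace(
            visual_layout(config.visual_n), name="handvis")
    if config.variant == "gaze":
        layouts["gaze"] = gaze_layout(config.gaze_n)
    return layouts


def layer_slices(layouts: dict[str, PopulationLayout | None]) -> dict[str, slice]:
    sizes = {
        name: (N_TACTILE if lay is None else lay.n_units)
        for name, lay in layouts.items()
    }
    return make_slices(sizes)


def sample_world(config: TrainingConfig, n: int,
                 rng: np.random.Generator) -> worldgen.WorldBatch:
    """Draw one world batch for the configured variant."""
    variant = config.variant
    if variant in ("constrained", "deep3"):
        return worldgen.sample_constrained(n, rng)
    if variant == "unconstrained":
        return worldgen.sample_unconstrained(n, rng, config.p_touch_unconstrained)
    if variant == "handvision":
        return worldgen.sample_handvision(
            n, rng, config.p_occluded, config.p_dissociated)
    if variant == "joint":
        return worldgen.sample_joint(n, rng)
    if variant == "gaze":
        return worldgen.sample_gaze(n, rng)
    raise ValueError(f"unknown variant {variant!r}")


def encode_batch(
    batch: worldgen.WorldBatch,
    layouts: dict[str, PopulationLayout | None],
    rng: np.random.Generator | None = None,
    mean: bool = False,
) -> np.ndarray:
    """Encode a world batch into the concatenated visible layer.

    Population sources: the proprioceptive layout reads joint angles in
    the joint/gaze variants and Cartesian hand position otherwise; the
    visual layout reads the eye-centred position in the gaze variant and
    the body-centred one otherwise; the hand-visual population is silent
    (zero) on occluded trials.
    """
    n = len(batch)
    parts = []
    for name, lay in layouts.items():
        if name == "tactile":
            parts.append(encode_tactile(batch.touch, batch.gains["tactile"],
                                        rng, mean=mean))
        elif name.startswith("proprioceptive"):
            pos = (batch.joint_angles
                   if lay.name == "proprioceptive_joint" else batch.hand_pos)
            parts.append(encode_position(lay, pos, batch.gains["proprioceptive"],
                                         rng, mean=mean))
        elif name == "visual":
            pos = batch.vis_pos_eye if batch.vis_pos_eye is not None else batch.vis_pos
            parts.append(encode_position(lay, pos, batch.gains["visual"],
                                         rng, mean=mean))
        elif name == "handvis":
            pos = batch.handvis_pos
            visible = np.isfinite(pos).all(axis=-1)
            safe = np.where(visible[:, None], pos, 0.0)
            act = encode_position(lay, safe, batch.gains["handvis"], rng, mean=mean)
            act[~visible] = 0.0
            parts.append(act)
        elif name == "gaze":
            parts.append(encode_position(lay, batch.gaze[:, None],
                                         batch.gains["gaze"], rng, mean=mean))
        else:
            raise ValueError(f"unknown population {name!r}")
    return np.concatenate(parts, axis=-1)


@dataclass
class TrainOutput:
    """Parameters, per-epoch metrics and optional snapshots of one run."""

    params: NetworkParams
    history: pd.DataFrame
    snapshots: dict[int, NetworkParams] = field(default_factory=dict)
    config: TrainingConfig | None = None
    seed: int | None = None
    # second-stage RBM of the three-layer variant, when trained
    params2: NetworkParams | None = None


def _overlap_index(params, layouts):
    # local import: analyses depends on training for layouts
    from .analyses import overlap_index, rf_profile
    return overlap_index(rf_profile(params, layouts))


def train(
    config: TrainingConfig,
    seed: int | None = None,
    track_overlap: bool = False,
    callback=None,
) -> TrainOutput:
    """Run the CD-1 epoch loop for a two-layer network.

    Fresh samples are drawn every epoch.  ``track_overlap`` adds the
    visuo-proprioceptive overlap index to the metrics table each epoch.
    A divergence guard aborts when the reconstruction error grows by more
    than 50% in five consecutive epochs.
    """
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    layouts = build_layouts(config)
    slices = layer_slices(layouts)
    params = init_params(config.n_multi, slices, rng, config.w_init_sd)
    rows = []
    snapshots: dict[int, NetworkParams] = {}
    n_bad = 0
    prev_err = np.inf
    for epoch in range(1, config.epochs + 1):
        errs = []
        for _ in range(config.batches_per_epoch):
            batch = sample_world(config, config.batch_size, rng)
            if config.integer_gains:
                for k in batch.gains:
                    batch.gains[k] = np.floor(batch.gains[k])
            u0 = encode_batch(batch, layouts, rng)
            stats = cd1_update(params, u0, rng, config.eta,
                               config.use_mean_stats)
            errs.append(stats["recon_error"])
        err = float(np.mean(errs))
        row = {"epoch": epoch, "recon_error": err}
        if track_overlap:
            row["overlap_index"] = _overlap_index(params, layouts)
        rows.append(row)
        if epoch in config.snapshot_epochs:
            snapshots[epoch] = params.copy()
        logger.info("epoch %3d/%d recon_error=%.4f", epoch, config.epochs, err)
        if callback is not None:
            callback(epoch, params, row)
        n_bad = n_bad + 1 if err > 1.5 * prev_err else 0
        if n_bad >= 5:
            raise RuntimeError(
                f"training diverged: reconstruction error grew >50% for 5 "
                f"consecutive epochs (epoch {epoch}, error {err:.4g})"
            )
        prev_err = err
    history = pd.DataFrame(rows)
    return TrainOutput(params, history, snapshots, config, seed)


def train_stagewise(config: TrainingConfig, seed: int | None = None) -> TrainOutput:
    """Two-stage protocol for the three-layer network.

    Stage 1 trains the usual two-layer RBM on the constrained stream.
    Stage 2 freezes it and trains a second RBM whose visible layer is the
    concatenation of the (sampled) first multisensory layer activity,
    driven by freshly encoded stimuli, and the raw tactile counts.
    """
    seed = config.seed if seed is None else seed
    out1 = train(config, seed)
    rng = np.random.default_rng(seed + 1)
    layouts = build_layouts(config)
    slices2 = make_slices({"multi1": config.n_multi, "tactile": N_TACTILE})
    params2 = init_params(config.n_multi2, slices2, rng, config.w_init_sd)
    epochs2 = config.epochs2 or config.epochs
    batches2 = config.batches_per_epoch2 or config.batches_per_epoch
    rows = []
    for epoch in range(1, epochs2 + 1):
        errs = []
        for _ in range(batches2):
            batch = sample_world(config, config.batch_size, rng)
            u0 = encode_batch(batch, layouts, rng)
            _, m1 = rbm.up_pass(out1.params, u0, rng, sample=True)
            tact = u0[:, out1.params.slices["tactile"]]
            v0 = np.concatenate([m1, tact], axis=-1)
            stats = cd1_update(params2, v0, rng, config.eta,
                               config.use_mean_stats)
            errs.append(stats["recon_error"])
        rows.append({"epoch": epoch, "recon_error_stage2": float(np.mean(errs))})
        logger.info("stage2 epoch %3d/%d recon_error=%.4f",
                    epoch, epochs2, rows[-1]["recon_error_stage2"])
    out1.params2 = params2
    out1.history = out1.history.join(
        pd.DataFrame(rows).set_index("epoch"), on="epoch")
    return out1
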