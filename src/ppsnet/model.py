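"""Model / results interface over the training and analysis machinery.

``PeripersonalRBM`` describes the generative model (variant + scale +
hyperparameters); ``fit`` runs contrastive-divergence training and
returns a ``PPSFitResults`` carrying the learned parameters, per-epoch
diagnostics, and the simulated-experiment methods.

>>> model = PeripersonalRBM(variant="constrained", scale="reduced")
>>> res = model.fit(seed=0)
>>> print(res.summary())
>>> res.rf_profile().head()
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import analyses, training
from .config import TrainingConfig
from .hdf5io import load_checkpoint, save_checkpoint
from .rbm import NetworkParams

__all__ = ["PeripersonalRBM", "PPSFitResults"]


class PeripersonalRBM:
    """Two-layer (or stagewise three-layer) peripersonal-space network.

    Parameters
    ----------
    variant :
        Training-world variant: ``constrained`` (body-constrained touch
        statistics, the default), ``unconstrained`` control,
        ``handvision``, ``joint``, ``gaze`` or ``deep3``.
    scale :
        ``"full"`` (the reference recipe: 100 epochs x 400 batches,
        50 x 50 visual grid, 500 multisensory units) or ``"reduced"``.
    **overrides :
        Any :class:`~ppsnet.config.TrainingConfig` field.
    """

    def __init__(self, variant: str = "constrained", scale: str = "full",
                 config: TrainingConfig | None = None, **overrides):
        if config is not None:
            self.config = config.replace(**overrides) if overrides else config
        else:
            self.config = TrainingConfig.preset(variant, scale, **overrides)

    @classmethod
    def from_config(cls, config: TrainingConfig) -> "PeripersonalRBM":
        return cls(config=config)

    @property
    def layouts(self):
        return training.build_layouts(self.config)

    def fit(self, seed: int | None = None, track_overlap: bool = False,
            callback=None) -> "PPSFitResults":
        """Train the network; returns a results object.

        The ``deep3`` variant runs the two-stage protocol (stage 1: the
        usual two-layer RBM; stage 2: a second RBM over first-layer
        multisensory activity concatenated with raw tactile counts).
        """
        if self.config.variant == "deep3":
            out = training.train_stagewise(self.config, seed)
        else:
            out = training.train(self.config, seed,
                                 track_overlap=track_overlap,
                                 callback=callback)
        return PPSFitResults(self, out)


class PPSFitResults:
    """Learned parameters, training diagnostics and simulated experiments."""

    def __init__(self, model: PeripersonalRBM, out: training.TrainOutput):
        self.model = model
        self.config = out.config or model.config
        self.seed = out.seed
        self.params: NetworkParams = out.params
        self.params2: NetworkParams | None = out.params2
        self.history: pd.DataFrame = out.history
        self.snapshots = out.snapshots
        self.layouts = model.layouts

    # -- diagnostics ------------------------------------------------------

    @property
    def recon_error(self) -> float:
        """Reconstruction error of the final epoch."""
        return float(self.history["recon_error"].iloc[-1])

    def summary(self) -> str:
        cfg = self.config
        prof = self.rf_profile()
        lines = [
            "Peripersonal-space RBM fit",
            "=" * 60,
            f"variant: {cfg.variant:<14s} scale: {cfg.scale}",
            f"epochs: {cfg.epochs} x {cfg.batches_per_epoch} batches x "
            f"{cfg.batch_size} samples   eta: {cfg.eta}",
            f"visible units: {self.params.n_visible}   "
            f"multisensory units: {self.params.n_multi}",
            f"seed: {self.seed}   config hash: {cfg.hash}",
            "-" * 60,
            f"final reconstruction error: {self.recon_error:.4f} "
            f"(epoch 1: {self.history['recon_error'].iloc[0]:.4f})",
            f"tactile-excitatory units: "
            f"{analyses.excitatory_fraction(prof):.1f}%",
            f"visuo-proprioceptive overlap index: "
            f"{analyses.overlap_index(prof):.3f}",
            "=" * 60,
        ]
        return "\n".join(lines)

    # -- analyses ---------------------------------------------------------

    def rf_profile(self) -> pd.DataFrame:
        return analyses.rf_profile(self.params, self.layouts)

    def overlap_index(self) -> float:
        return analyses.overlap_index(self.rf_profile())

    def excitatory_fraction(self) -> float:
        return analyses.excitatory_fraction(self.rf_profile())

    def evoked_map(self, hand_grid, vis_grid, **kw) -> analyses.EvokedMap:
        return analyses.evoked_tactile_map(self.params, self.layouts,
                                           hand_grid, vis_grid, **kw)

    def rf_shift(self, **kw) -> pd.DataFrame:
        return analyses.population_rf_shift(self.params, self.layouts, **kw)

    def drift(self, protocol: str = "IHI", **kw) -> analyses.DriftCurve:
        return analyses.drift_experiment(self.params, self.layouts,
                                         protocol, **kw)

    def congruency(self, **kw) -> pd.DataFrame:
        return analyses.congruency_prediction(self.params, self.layouts, **kw)

    def rf_peak_hand_correlation(self, **kw) -> pd.DataFrame:
        if self.params2 is None:
            raise ValueError("requires a deep3 (stagewise) fit")
        return analyses.rf_peak_hand_correlation(
            self.params, self.params2, self.layouts, **kw)

    # -- persistence ------------------------------------------------------

    def save(self, path) -> None:
        save_checkpoint(path, self.params, self.config,
                        epoch=int(self.history["epoch"].iloc[-1]),
                        seed=self.seed, params2=self.params2)

    @classmethod
    def load(cls, path) -> "PPSFitResults":
        params, params2, meta = load_checkpoint(path)
        config = meta.get("config") or TrainingConfig()
        model = PeripersonalRBM(config=config)
        out = training.TrainOutput(
            params=params,
            history=pd.DataFrame({"epoch": [meta.get("epoch", 0)],
                                  "recon_error": [np.nan]}),
            config=config, seed=int(meta.get("seed", 0)), params2=params2)
        return cls(model, out)
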