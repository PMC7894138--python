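"""Run configuration: schema, defaults, YAML round-trip, scale presets.

Defaults are the full-scale recipe (100 epochs of 400 batches of 100
samples, learning rate 0.005, 500 multisensory units over a 50x50 visual
grid).  The ``reduced`` preset is a separate named profile that shrinks
the visual grid and multisensory layer and shortens the schedule so a
training run completes in a couple of minutes on one CPU; it is selected
explicitly and never silently alters the full configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field

import yaml

__all__ = ["TrainingConfig", "load_config", "save_config", "REDUCED_PRESET"]

VARIANTS = ("constrained", "unconstrained", "handvision", "joint", "gaze", "deep3")

#: reduced-scale overrides (applied on top of the full defaults): a
#: 40x40 visual grid with the full 500-unit multisensory layer, trained
#: on 4e5 samples (~2 min on one CPU)
REDUCED_PRESET = {
    "scale": "reduced",
    "epochs": 40,
    "batches_per_epoch": 100,
    "visual_n": 40,
    "n_multi": 500,
}


@dataclass
class TrainingConfig:
    """Complete description of one training run."""

    variant: str = "constrained"
    scale: str = "full"
    epochs: int = 100
    batches_per_epoch: int = 400
    batch_size: int = 100
    eta: float = 0.005
    n_multi: int = 500
    visual_n: int = 50
    proprio_n: tuple[int, int] = (15, 10)
    gaze_n: int = 120
    w_init_sd: float = 0.001
    seed: int = 0
    snapshot_epochs: tuple[int, ...] = ()
    use_mean_stats: bool = False
    integer_gains: bool = False
    p_touch_unconstrained: float = 0.05
    p_occluded: float = 0.25
    p_dissociated: float = 0.25
    # three-layer (deep3) second stage
    n_multi2: int = 100
    epochs2: int | None = None          # defaults to `epochs`
    batches_per_epoch2: int | None = None

    def __post_init__(self) -> None:
        errors = []
        if self.variant not in VARIANTS:
            errors.append(f"variant: {self.variant!r} not in {VARIANTS}")
        for key in ("epochs", "batches_per_epoch", "batch_size", "n_multi",
                    "visual_n", "gaze_n", "n_multi2"):
            if getattr(self, key) <= 0:
                errors.append(f"{key}: must be positive")
        if self.eta <= 0:
            errors.append("eta: must be positive")
        if self.w_init_sd <= 0:
            errors.append("w_init_sd: must be positive")
        if not (0 <= self.p_touch_unconstrained <= 1):
            errors.append("p_touch_unconstrained: must be in [0, 1]")
        if self.p_occluded + self.p_dissociated > 1:
            errors.append("p_occluded + p_dissociated: must be <= 1")
        if errors:
            raise ValueError("invalid configuration: " + "; ".join(errors))
        object.__setattr__(self, "proprio_n", tuple(self.proprio_n))
        object.__setattr__(self, "snapshot_epochs", tuple(self.snapshot_epochs))

    # -- serialisation ----------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["proprio_n"] = list(self.proprio_n)
        d["snapshot_epochs"] = list(self.snapshot_epochs)
        return d

    def replace(self, **kw) -> "TrainingConfig":
        return dataclasses.replace(self, **kw)

    @property
    def hash(self) -> str:
        """Stable short hash of the configuration (provenance tag)."""
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha1(blob).hexdigest()[:12]

    @classmethod
    def from_dict(cls, d: dict) -> "TrainingConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(d) - known)
        if unknown:
            raise ValueError(f"unknown configuration keys: {unknown}")
        return cls(**d)

    @classmethod
    def preset(cls, variant: str = "constrained", scale: str = "full",
               **overrides) -> "TrainingConfig":
        """Named profile: the reference full-scale recipe or the reduced preset."""
        kw: dict = {"variant": variant}
        if scale == "reduced":
            kw.update(REDUCED_PRESET)
        elif scale != "full":
            raise ValueError(f"unknown scale {scale!r}")
        kw.update(overrides)
        return cls(**kw)


def load_config(path) -> TrainingConfig:
    """Read a YAML config; an empty file yields the full default recipe."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return TrainingConfig.from_dict(data or {})


def save_config(config: TrainingConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
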