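"""Probabilistic population codes: Poisson spiking over Gaussian tuning curves.

A continuous physical quantity (stimulus position, hand position, gaze
angle) is represented by a population of neurons whose preferred values
tile the represented range on a regular grid.  Neuron *i* fires a Poisson
count with mean

    lambda_i = g * exp(-||x - xhat_i||^2 / (2 sigma^2))

where ``g`` is the stimulus gain (strength) and ``xhat_i`` the preferred
value.  Touch is encoded by a separate homogeneous population whose units
all fire Poisson(g) when contact occurs and stay silent otherwise.

Decoding goes through the activity barycentre (population vector); the
module also provides the posterior standard deviation of an optimal
decoder and a Monte-Carlo maximum-likelihood decoder used to cross-check
it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

__all__ = [
    "PopulationLayout",
    "visual_layout",
    "proprioceptive_layout",
    "gaze_layout",
    "N_TACTILE",
    "encode_position",
    "encode_tactile",
    "decode_barycentre",
    "theoretical_precision",
    "ml_decode",
    "grid_posterior_sd",
]

#: number of units in the homogeneous tactile population
N_TACTILE = 30


@dataclass(frozen=True)
class PopulationLayout:
    """Regular grid of Gaussian-tuned neurons covering a physical range.

    Parameters
    ----------
    name :
        Population label (``"visual"``, ``"proprioceptive"``, ...).
    n_grid :
        Number of neurons per dimension, e.g. ``(50, 50)`` or ``(120,)``.
    range_lo, range_hi :
        Physical span over which stimuli are actually delivered (m or rad).
    sigma_units :
        Tuning-curve SD expressed in grid spacings (per axis).
    margin :
        Physical safety margin added on each side of the stimulus range,
        per axis.  The float sentinel value produced by
        :func:`_self_consistent_margin` keeps ``margin == 3 * sigma``.
    spacing_rule :
        ``"span/n"`` (cell centres, default) or ``"span/(n-1)"``
        (endpoints included).
    """

    name: str
    n_grid: tuple[int, ...]
    range_lo: tuple[float, ...]
    range_hi: tuple[float, ...]
    sigma_units: float
    margin: tuple[float, ...]
    spacing_rule: str = "span/n"

    def __post_init__(self) -> None:
        ndim = len(self.n_grid)
        if not (len(self.range_lo) == len(self.range_hi) == len(self.margin) == ndim):
            raise ValueError("n_grid, range_lo, range_hi and margin must share length")
        if self.sigma_units <= 0:
            raise ValueError("sigma_units must be positive")
        if self.spacing_rule not in ("span/n", "span/(n-1)"):
            raise ValueError(f"unknown spacing rule {self.spacing_rule!r}")

    # -- derived geometry -------------------------------------------------

    @property
    def ndim(self) -> int:
        return len(self.n_grid)

    @property
    def n_units(self) -> int:
        return int(np.prod(self.n_grid))

    @property
    def span(self) -> np.ndarray:
        """Full physical span covered by the grid, margins included."""
        return (
            np.asarray(self.range_hi)
            - np.asarray(self.range_lo)
            + 2 * np.asarray(self.margin)
        )

    @property
    def spacing(self) -> np.ndarray:
        """Grid spacing per axis (physical units)."""
        n = np.asarray(self.n_grid, dtype=float)
        if self.spacing_rule == "span/n":
            return self.span / n
        return self.span / (n - 1)

    @property
    def sigma(self) -> np.ndarray:
        """Tuning-curve SD per axis in physical units."""
        return self.sigma_units * self.spacing

    @property
    def axes(self) -> list[np.ndarray]:
        """Preferred values along each axis."""
        lo = np.asarray(self.range_lo) - np.asarray(self.margin)
        out = []
        for d in range(self.ndim):
            if self.spacing_rule == "span/n":
                out.append(lo[d] + (np.arange(self.n_grid[d]) + 0.5) * self.spacing[d])
            else:
                out.append(lo[d] + np.arange(self.n_grid[d]) * self.spacing[d])
        return out

    @property
    def preferred(self) -> np.ndarray:
        """(n_units, ndim) array of preferred positions, x varying slowest."""
        mesh = np.meshgrid(*self.axes, indexing="ij")
        return np.stack([m.ravel() for m in mesh], axis=-1)

    # -- (de)serialisation -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "n_grid": list(self.n_grid),
            "range_lo": list(self.range_lo),
            "range_hi": list(self.range_hi),
            "sigma_units": self.sigma_units,
            "margin": list(self.margin),
            "spacing_rule": self.spacing_rule,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PopulationLayout":
        return cls(
            name=d["name"],
            n_grid=tuple(int(v) for v in d["n_grid"]),
            range_lo=tuple(float(v) for v in d["range_lo"]),
            range_hi=tuple(float(v) for v in d["range_hi"]),
            sigma_units=float(d["sigma_units"]),
            margin=tuple(float(v) for v in d["margin"]),
            spacing_rule=d.get("spacing_rule", "span/n"),
        )


def _self_consistent_margin(rng: float, n: int, sigma_units: float) -> float:
    """Margin m solving m = 3*sigma with sigma = sigma_units * spacing.

    With the cell-centre rule spacing = (range + 2m)/n, the fixed point is
    spacing = range / (n - 6*sigma_units).
    """
    denom = n - 6.0 * sigma_units
    if denom <= 0:
        raise ValueError("grid too small for a 3-sigma margin")
    return 3.0 * sigma_units * rng / denom


def visual_layout(n: int = 50, margin: float = 0.30) -> PopulationLayout:
    """Visual population: trunk-centred stimulus positions on 1.2 x 1.2 m.

    Tuning SD is 3 grid spacings; with the default 30 cm margins and a
    50 x 50 grid the physical width is ~10.8 cm.
    """
    return PopulationLayout(
        name="visual",
        n_grid=(n, n),
        range_lo=(-0.6, 0.0),
        range_hi=(0.6, 1.2),
        sigma_units=3.0,
        margin=(margin, margin),
    )


def proprioceptive_layout(
    n: tuple[int, int] = (15, 10), joint_angles: bool = False
) -> PopulationLayout:
    """Proprioceptive population: hand position on 1.2 x 0.6 m (or joint angles).

    Tuning SD is 1 grid spacing and the margins are fixed at exactly three
    times the tuning SD, which makes the medial-lateral spacing 13.3 cm
    (the "~13 cm" width) for the Cartesian 15 x 10 grid.  In the joint-angle
    variant the same grid covers shoulder [-pi/4, pi/2] and elbow
    [-pi/2, 0] angles.
    """
    if joint_angles:
        lo, hi = (-np.pi / 4, -np.pi / 2), (np.pi / 2, 0.0)
        name = "proprioceptive_joint"
    else:
        lo, hi = (-0.6, 0.0), (0.6, 0.6)
        name = "proprioceptive"
    margins = tuple(
        _self_consistent_margin(hi[d] - lo[d], n[d], 1.0) for d in range(2)
    )
    return PopulationLayout(
        name=name, n_grid=tuple(n), range_lo=lo, range_hi=hi,
        sigma_units=1.0, margin=margins,
    )


def gaze_layout(n: int = 120) -> PopulationLayout:
    """1D gaze-direction population over [-pi/4, pi/4], tuning SD 1 spacing."""
    lo, hi = -np.pi / 4, np.pi / 4
    m = _self_consistent_margin(hi - lo, n, 1.0)
    return PopulationLayout(
        name="gaze", n_grid=(n,), range_lo=(lo,), range_hi=(hi,),
        sigma_units=1.0, margin=(m,),
    )


# ---------------------------------------------------------------------------
# encoding


def tuning_means(layout: PopulationLayout, pos: np.ndarray, gain) -> np.ndarray:
    """Poisson means lambda_i for stimuli ``pos`` ((..., ndim)) at ``gain``."""
    pos = np.asarray(pos, dtype=float)
    if pos.shape[-1] != layout.ndim:
        raise ValueError(
            f"position dimension {pos.shape[-1]} != layout ndim {layout.ndim}"
        )
    if not np.all(np.isfinite(pos)):
        raise ValueError("non-finite stimulus position")
    gain = np.asarray(gain, dtype=float)
    if np.any(gain < 0):
        raise ValueError("gain must be nonnegative")
    if layout.ndim == 2:
        # separable Gaussian: evaluate per axis, combine by outer product
        ax, ay = layout.axes
        sx, sy = layout.sigma
        gx = np.exp(-0.5 * ((pos[..., 0, None] - ax) / sx) ** 2)
        gy = np.exp(-0.5 * ((pos[..., 1, None] - ay) / sy) ** 2)
        lam = (gx[..., :, None] * gy[..., None, :]).reshape(
            pos.shape[:-1] + (layout.n_units,))
    else:
        diff = pos[..., None, :] - layout.preferred  # (..., n_units, ndim)
        z = (diff / layout.sigma) ** 2
        lam = np.exp(-0.5 * z.sum(axis=-1))
    return gain[..., None] * lam if gain.ndim else gain * lam


def encode_position(
    layout: PopulationLayout,
    pos,
    gain,
    rng: np.random.Generator | None = None,
    mean: bool = False,
) -> np.ndarray:
    """Encode position(s) as Poisson spike counts (or their means).

    Parameters
    ----------
    pos : array_like, shape (..., ndim)
        Stimulus position(s); may lie inside the safety margin.
    gain : scalar or array broadcastable to the batch shape
        Stimulus strength g.
    rng :
        Random generator; required unless ``mean=True``.
    mean :
        If true, return the deterministic Poisson means lambda instead of
        sampled counts.
    """
    lam = tuning_means(layout, pos, gain)
    if mean:
        return lam
    if rng is None:
        raise ValueError("rng is required in sampling mode")
    return rng.poisson(lam).astype(float)


def encode_tactile(
    touch,
    gain,
    rng: np.random.Generator | None = None,
    n_units: int = N_TACTILE,
    mean: bool = False,
) -> np.ndarray:
    """Encode touch as i.i.d. Poisson(gain) counts on all tactile units.

    ``touch`` false gives an all-zero vector.  Scalars or batches accepted;
    output shape is ``touch.shape + (n_units,)``.
    """
    touch = np.asarray(touch, dtype=bool)
    gain = np.broadcast_to(np.asarray(gain, dtype=float), touch.shape)
    if np.any(gain < 0):
        raise ValueError("gain must be nonnegative")
    lam = np.where(touch, gain, 0.0)[..., None] * np.ones(n_units)
    if mean:
        return lam
    if rng is None:
        raise ValueError("rng is required in sampling mode")
    return rng.poisson(lam).astype(float)


# ---------------------------------------------------------------------------
# decoding


def decode_barycentre(layout: PopulationLayout, activity: np.ndarray) -> np.ndarray:
    """Activity-weighted mean of preferred positions.

    Rows with no positive activity are undecodable and come back as NaN
    (with a warning) rather than a silent zero.
    """
    act = np.asarray(activity, dtype=float)
    if act.shape[-1] != layout.n_units:
        raise ValueError(f"activity length {act.shape[-1]} != {layout.n_units} units")
    if np.any(act < 0):
        raise ValueError("activity must be nonnegative")
    total = act.sum(axis=-1)
    bad = total <= 0
    if np.any(bad):
        warnings.warn("all-zero activity: undecodable, returning NaN", stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = (act @ layout.preferred) / total[..., None]
    if np.any(bad):
        out = np.where(np.asarray(bad)[..., None], np.nan, out)
    return out


def theoretical_precision(layout: PopulationLayout, gain: float) -> np.ndarray:
    """Posterior SD per axis of an optimal decoder at the given gain.

    For Poisson spiking with Gaussian tuning the posterior over the
    stimulus is Gaussian with SD sigma/sqrt(N) per axis, where N is the
    expected total spike count,

        N = g * (2*pi)^(d/2) * prod_d (sigma_d / Delta_d).

    Returns the per-axis SD in the layout's physical units.
    """
    if gain <= 0:
        raise ValueError("gain must be positive")
    ratio = layout.sigma / layout.spacing
    if np.any(ratio < 0.5):
        warnings.warn(
            "tuning SD below half a grid spacing: dense-grid approximation "
            "may be poor",
            stacklevel=2,
        )
    n_expected = gain * (2 * np.pi) ** (layout.ndim / 2) * np.prod(ratio)
    return layout.sigma / np.sqrt(n_expected)


def _neg_loglik(layout, counts, pos, gain):
    lam = tuning_means(layout, pos, gain)
    with np.errstate(divide="ignore"):
        ll = counts * np.log(lam) - lam
    return -np.sum(np.where(counts > 0, ll, -lam))


def ml_decode(
    layout: PopulationLayout, counts: np.ndarray, gain: float
) -> np.ndarray:
    """Maximum-likelihood position estimate(s) from spike counts.

    A coarse search over the preferred-position grid is refined by
    Nelder-Mead on the continuous Poisson log-likelihood.
    """
    counts = np.atleast_2d(np.asarray(counts, dtype=float))
    # coarse: log-likelihood at every preferred position
    lam_grid = tuning_means(layout, layout.preferred, gain)  # (n, n)
    with np.errstate(divide="ignore"):
        loggrid = np.log(lam_grid)
    loggrid[~np.isfinite(loggrid)] = -745.0
    ll = counts @ loggrid.T - lam_grid.sum(axis=1)
    best = layout.preferred[np.argmax(ll, axis=1)]
    out = np.empty_like(best)
    for k, (c, x0) in enumerate(zip(counts, best)):
        res = optimize.minimize(
            lambda p: _neg_loglik(layout, c, p, gain),
            x0,
            method="Nelder-Mead",
            options={"xatol": 1e-5, "fatol": 1e-8},
        )
        out[k] = res.x
    return out.squeeze()


def grid_posterior_sd(
    layout: PopulationLayout,
    counts: np.ndarray,
    gain: float,
    n_cand: int = 201,
) -> np.ndarray:
    """Brute-force posterior SD on a dense candidate grid (flat prior).

    Independent oracle for :func:`theoretical_precision` on small layouts:
    evaluates the unnormalised Poisson posterior over a dense grid of
    candidate positions and returns its per-axis SD.
    """
    axes = [
        np.linspace(lo - m, hi + m, n_cand)
        for lo, hi, m in zip(layout.range_lo, layout.range_hi, layout.margin)
    ]
    mesh = np.meshgrid(*axes, indexing="ij")
    cands = np.stack([m.ravel() for m in mesh], axis=-1)
    lam = tuning_means(layout, cands, gain)  # (n_cand^d, n_units)
    with np.errstate(divide="ignore"):
        loglam = np.where(lam > 0, np.log(np.maximum(lam, 1e-300)), -745.0)
    ll = loglam @ np.asarray(counts, dtype=float) - lam.sum(axis=1)
    ll -= ll.max()
    w = np.exp(ll)
    w /= w.sum()
    mu = w @ cands
    var = w @ (cands - mu) ** 2
    return np.sqrt(var)
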