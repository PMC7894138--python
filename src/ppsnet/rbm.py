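"""Two-layer Restricted Boltzmann Machine with Poisson visible units.

The lower (visible) layer holds the concatenated unisensory spike-count
populations; the upper layer is a set of binary multisensory units.  The
same weight matrix serves the feedforward ("up") and feedback ("down")
pass, so the two directions are symmetric by construction:

    up:    mu  = sigmoid(W u + b_m),   m ~ Bernoulli(mu)
    down:  lam = exp(W^T m + b_u),     u ~ Poisson(lam)

Learning is one-step contrastive divergence (CD-1): a Hebbian term from
the data phase minus an anti-Hebbian term from the one-step
"confabulation" reconstruction, averaged over a batch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

logger = logging.getLogger(__name__)

__all__ = [
    "NetworkParams",
    "init_params",
    "up_pass",
    "down_pass",
    "cd1_update",
    "reconstruct",
    "reconstruction_error",
    "LAM_LOG_CEIL",
]

#: ceiling on W^T m + b_u before exponentiation (Poisson-mean clip at e^10)
LAM_LOG_CEIL = 10.0


@dataclass
class NetworkParams:
    """Weights and biases of one RBM layer pair.

    ``W`` has shape (n_multi, n_visible); ``slices`` names the index range
    of each unisensory population inside the visible layer.
    """

    W: np.ndarray
    b_u: np.ndarray
    b_m: np.ndarray
    slices: dict[str, slice] = field(default_factory=dict)

    @property
    def n_multi(self) -> int:
        return self.W.shape[0]

    @property
    def n_visible(self) -> int:
        return self.W.shape[1]

    def copy(self) -> "NetworkParams":
        return NetworkParams(
            self.W.copy(), self.b_u.copy(), self.b_m.copy(), dict(self.slices)
        )

    @property
    def hash(self) -> str:
        """Short content hash of the parameters (analysis provenance)."""
        import hashlib
        h = hashlib.sha1()
        for a in (self.W, self.b_u, self.b_m):
            h.update(np.ascontiguousarray(a).tobytes())
        return h.hexdigest()[:12]

    def _check_visible(self, u: np.ndarray) -> None:
        if u.shape[-1] != self.n_visible:
            sizes = {k: s.stop - s.start for k, s in self.slices.items()}
            raise ValueError(
                f"visible vector length {u.shape[-1]} != {self.n_visible} "
                f"(population slices: {sizes})"
            )


def make_slices(sizes: dict[str, int]) -> dict[str, slice]:
    """Contiguous named slices from ordered population sizes."""
    out, start = {}, 0
    for name, n in sizes.items():
        out[name] = slice(start, start + n)
        start += n
    return out


def init_params(
    n_multi: int,
    slices: dict[str, slice],
    rng: np.random.Generator,
    w_sd: float = 0.001,
    dtype=np.float32,
) -> NetworkParams:
    """Random initial connectivity: W ~ N(0, w_sd^2), zero biases.

    Single precision is the default: CD-1 updates are noisy by design and
    the weight scale stays O(1), so float32 loses nothing while doubling
    matmul throughput on one CPU.
    """
    n_visible = max(s.stop for s in slices.values())
    W = rng.normal(0.0, w_sd, size=(n_multi, n_visible)).astype(dtype)
    return NetworkParams(W, np.zeros(n_visible, dtype=dtype),
                         np.zeros(n_multi, dtype=dtype), dict(slices))


def up_pass(
    params: NetworkParams,
    u: np.ndarray,
    rng: np.random.Generator | None = None,
    sample: bool = True,
):
    """Multisensory activity from visible counts.

    Returns ``(mu, m)`` with ``mu = sigmoid(W u + b_m)``; ``m`` is a
    Bernoulli sample when ``sample`` else the mean-field ``mu`` itself.
    """
    u = np.asarray(u, dtype=params.W.dtype)
    params._check_visible(u)
    if not np.all(np.isfinite(u)) or np.any(u < 0):
        raise ValueError("visible activity must be finite and nonnegative")
    mu = expit(u @ params.W.T + params.b_m)
    if sample:
        if rng is None:
            raise ValueError("rng required when sample=True")
        m = (rng.random(mu.shape) < mu).astype(params.W.dtype)
    else:
        m = mu
    return mu, m


def down_pass(
    params: NetworkParams,
    m: np.ndarray,
    rng: np.random.Generator | None = None,
    sample: bool = True,
    lam_log_ceil: float = LAM_LOG_CEIL,
):
    """Visible activity from multisensory units.

    Returns ``(lam, u)`` with ``lam = exp(W^T m + b_u)``, clipped at
    ``exp(lam_log_ceil)`` for numerical safety (a warning is logged when
    the clip engages); ``u`` is Poisson-sampled when ``sample`` else equal
    to ``lam``.
    """
    m = np.asarray(m, dtype=params.W.dtype)
    if m.shape[-1] != params.n_multi:
        raise ValueError(f"multisensory length {m.shape[-1]} != {params.n_multi}")
    log_lam = m @ params.W + params.b_u
    n_clip = int(np.sum(log_lam > lam_log_ceil))
    if n_clip:
        logger.warning("down_pass: clipping %d Poisson log-means at %g",
                       n_clip, lam_log_ceil)
        log_lam = np.minimum(log_lam, lam_log_ceil)
    lam = np.exp(log_lam)
    if sample:
        if rng is None:
            raise ValueError("rng required when sample=True")
        u = rng.poisson(lam).astype(params.W.dtype)
    else:
        u = lam
    return lam, u


def cd1_update(
    params: NetworkParams,
    u0: np.ndarray,
    rng: np.random.Generator,
    eta: float = 0.005,
    use_mean_stats: bool = False,
) -> dict:
    """One contrastive-divergence step on a batch; updates params in place.

    Per sample: sampled up pass (m0), sampled down pass (u1), up pass from
    the reconstruction (m1).  Then

        dW   = eta * < u0 m0 - u1 m1 >_batch
        db_u = eta * < u0 - u1 >_batch
        db_m = eta * < m0 - m1 >_batch

    With ``use_mean_stats`` the Bernoulli means mu are used in the
    correlation statistics instead of the sampled binary states.

    Returns batch statistics including the reconstruction error
    (mean squared u0 - u1 difference).
    """
    if eta <= 0:
        raise ValueError("learning rate must be positive")
    u0 = np.atleast_2d(np.asarray(u0, dtype=params.W.dtype))
    if u0.shape[0] == 0:
        raise ValueError("empty batch")
    mu0, m0 = up_pass(params, u0, rng, sample=True)
    _, u1 = down_pass(params, m0, rng, sample=True)
    mu1, m1 = up_pass(params, u1, rng, sample=True)
    if use_mean_stats:
        m0_stat, m1_stat = mu0, mu1
    else:
        m0_stat, m1_stat = m0, m1
    B = u0.shape[0]
    dW = (m0_stat.T @ u0 - m1_stat.T @ u1) / B
    db_u = (u0 - u1).mean(axis=0)
    db_m = (m0_stat - m1_stat).mean(axis=0)
    if not (np.all(np.isfinite(dW)) and np.all(np.isfinite(db_u))
            and np.all(np.isfinite(db_m))):
        raise FloatingPointError(
            "NaN/inf in CD-1 update; state: "
            f"|W|max={np.abs(params.W).max():.3g}, "
            f"|b_u|max={np.abs(params.b_u).max():.3g}, "
            f"|b_m|max={np.abs(params.b_m).max():.3g}"
        )
    params.W += eta * dW
    params.b_u += eta * db_u
    params.b_m += eta * db_m
    return {
        "recon_error": float(np.mean((u0 - u1) ** 2)),
        "mean_abs_dW": float(np.abs(dW).mean()),
    }


def reconstruct(
    params: NetworkParams,
    u: np.ndarray,
    mask: list[str] | None = None,
    rng: np.random.Generator | None = None,
    sample_up: bool = False,
) -> np.ndarray:
    """One up pass followed by a mean-mode down pass: lambda read-out.

    ``mask`` names population slices zeroed in the input before the up
    pass (used for evoked-activity and illusion protocols).  With
    ``sample_up=False`` (default) the up pass is mean-field and the whole
    read-out is deterministic.
    """
    u = np.atleast_2d(np.asarray(u, dtype=float)).copy()
    for name in mask or ():
        if name not in params.slices:
            raise KeyError(
                f"unknown mask population {name!r}; have {sorted(params.slices)}"
            )
        u[..., params.slices[name]] = 0.0
    _, m = up_pass(params, u, rng, sample=sample_up)
    lam, _ = down_pass(params, m, sample=False)
    return lam


def reconstruction_error(
    params: NetworkParams, u0: np.ndarray, rng: np.random.Generator
) -> float:
    """Mean squared difference between a batch and its CD reconstruction.

    Uses the training-time stochastic pipeline (sampled up then sampled
    down), matching the quantity tracked across epochs.
    """
    u0 = np.atleast_2d(np.asarray(u0, dtype=float))
    _, m0 = up_pass(params, u0, rng, sample=True)
    _, u1 = down_pass(params, m0, rng, sample=True)
    return float(np.mean((u0 - u1) ** 2))
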