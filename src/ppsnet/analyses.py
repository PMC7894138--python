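"""Receptive-field characterisation and simulated behavioural experiments.

Everything here is a pure function of a trained parameter set and an
explicit protocol; in the default mean-field mode (Bernoulli means in the
up pass, Poisson means in the down pass) every analysis is deterministic
and exactly reproducible.

The central read-outs are:

* **RF profiles** -- per multisensory neuron, the mean incoming tactile
  weight (sign classifies the neuron as tactile-excitatory or
  -inhibitory), the preferred visual distance, and the visuo-proprioceptive
  overlap (spatial Pearson correlation of the incoming visual and
  interpolated proprioceptive weight maps).
* **Evoked tactile activity** -- the tactile read-out after encoding only
  visual + proprioceptive inputs, the model's proxy for multisensory
  facilitation of touch; displayed trunk-centred or re-binned into
  hand-centred coordinates.
* **Proprioceptive drift** -- displacement of the decoded hand position
  toward a visual stimulus under synchronous touch, simulating the
  invisible/rubber hand illusions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from scipy.interpolate import RegularGridInterpolator

from .popcode import PopulationLayout, decode_barycentre, encode_position, N_TACTILE
from .rbm import NetworkParams, reconstruct, up_pass
from .worldgen import GAIN_RANGE

__all__ = [
    "rf_profile", "excitatory_fraction", "overlap_index", "bimodality_delta_bic",
    "EvokedMap", "evoked_tactile_map", "hand_centred_curve",
    "population_rf_shift", "DriftCurve", "drift_experiment",
    "congruency_prediction", "rf_peak_hand_correlation",
]

#: default stimulus gain for test-time probes (maximal training gain)
TEST_GAIN = GAIN_RANGE[1]


# ---------------------------------------------------------------------------
# receptive-field profiles


def _interp_matrix_query(layout_p: PopulationLayout,
                         layout_v: PopulationLayout) -> np.ndarray:
    """Visual preferred positions lying inside the proprioceptive domain."""
    pts = layout_v.preferred
    lo = np.array(layout_p.range_lo) - np.array(layout_p.margin)
    hi = np.array(layout_p.range_hi) + np.array(layout_p.margin)
    # stay strictly inside the proprioceptive cell-centre hull
    pad = layout_p.spacing / 2
    keep = np.all((pts >= lo + pad) & (pts <= hi - pad), axis=1)
    return pts[keep]


def rf_profile(params: NetworkParams,
               layouts: dict[str, PopulationLayout | None],
               proprio: str = "proprioceptive",
               visual: str = "visual") -> pd.DataFrame:
    """Per-multisensory-neuron receptive-field table.

    Columns: ``tactile_strength`` (mean of the 30 incoming tactile
    weights), ``excitatory`` (its sign), ``preferred_visual_distance``
    (anterior-posterior preferred position of the visual neuron with the
    strongest excitatory synapse; ties broken by lowest index) and
    ``vp_overlap`` (Pearson r between the visual weight map and the
    proprioceptive weight map bilinearly interpolated onto points with
    the visual grid spacing).

    With near-zero (untrained) weights the overlap is numerically defined
    but meaningless; an ``overlap_reliable`` flag marks neurons whose
    weight maps have non-trivial structure.
    """
    lay_p = layouts[proprio]
    lay_v = layouts[visual]
    sl_t = params.slices["tactile"]
    sl_p = params.slices[proprio]
    sl_v = params.slices[visual]

    W_t = params.W[:, sl_t]
    W_p = params.W[:, sl_p]
    W_v = params.W[:, sl_v]
    tactile_strength = W_t.mean(axis=1)

    # preferred visual distance: anterior-posterior coordinate of argmax
    best = np.argmax(W_v, axis=1)
    preferred_visual_distance = lay_v.preferred[best, 1]

    # interpolate proprioceptive maps onto the visual grid spacing
    query = _interp_matrix_query(lay_p, lay_v)
    interp = RegularGridInterpolator(
        lay_p.axes, W_p.T.reshape(lay_p.n_grid + (params.n_multi,)),
        method="linear", bounds_error=False, fill_value=None)
    P_maps = interp(query)  # (n_query, n_multi)

    # visual weights at the same physical points (exact grid values)
    v_interp = RegularGridInterpolator(
        lay_v.axes, W_v.T.reshape(lay_v.n_grid + (params.n_multi,)),
        method="linear", bounds_error=False, fill_value=None)
    V_maps = v_interp(query)

    Pm = P_maps - P_maps.mean(axis=0)
    Vm = V_maps - V_maps.mean(axis=0)
    denom = np.sqrt((Pm ** 2).sum(axis=0) * (Vm ** 2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        vp_overlap = np.where(denom > 0, (Pm * Vm).sum(axis=0) / denom, 0.0)

    reliable = (np.abs(W_t).max(axis=1) > 10 * np.finfo(float).eps) & (denom > 0)
    return pd.DataFrame({
        "tactile_strength": tactile_strength,
        "excitatory": tactile_strength > 0,
        "preferred_visual_distance": preferred_visual_distance,
        "vp_overlap": vp_overlap,
        "overlap_reliable": reliable,
    })


def excitatory_fraction(profile: pd.DataFrame) -> float:
    """Percentage of multisensory neurons with positive mean tactile weight."""
    return 100.0 * float(profile["excitatory"].mean())


def overlap_index(profile: pd.DataFrame) -> float:
    """Mean vp-overlap of tactile-excitatory minus tactile-inhibitory neurons.

    Zero when either class is empty (untrained networks have no
    differentiated classes).
    """
    exc = profile.loc[profile["excitatory"], "vp_overlap"]
    inh = profile.loc[~profile["excitatory"], "vp_overlap"]
    if len(exc) == 0 or len(inh) == 0:
        return 0.0
    return float(exc.mean() - inh.mean())


def bimodality_delta_bic(values: np.ndarray) -> float:
    """BIC(one Gaussian) - BIC(two-Gaussian mixture): > 0 favours bimodality.

    Lightweight two-component EM on 1D data; returns the improvement in
    BIC of the two-component fit over the single Gaussian.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    # single component
    s1 = max(x.std(), 1e-12)
    ll1 = np.sum(stats.norm.logpdf(x, x.mean(), s1))
    bic1 = 2 * np.log(n) - 2 * ll1
    # two components, EM initialised by a median split
    med = np.median(x)
    w = np.array([0.5, 0.5])
    mu = np.array([x[x <= med].mean(), x[x > med].mean()])
    sd = np.array([max(x[x <= med].std(), 1e-6), max(x[x > med].std(), 1e-6)])
    for _ in range(200):
        pdf = w * stats.norm.pdf(x[:, None], mu, sd)
        tot = pdf.sum(axis=1, keepdims=True)
        tot[tot == 0] = 1e-300
        r = pdf / tot
        w = r.mean(axis=0)
        mu = (r * x[:, None]).sum(axis=0) / (r.sum(axis=0) + 1e-300)
        sd = np.sqrt((r * (x[:, None] - mu) ** 2).sum(axis=0)
                     / (r.sum(axis=0) + 1e-300))
        sd = np.maximum(sd, 1e-6)
    ll2 = np.sum(np.log((w * stats.norm.pdf(x[:, None], mu, sd)).sum(axis=1)
                        + 1e-300))
    bic2 = 5 * np.log(n) - 2 * ll2
    return float(bic1 - bic2)


# ---------------------------------------------------------------------------
# evoked tactile activity


@dataclass
class EvokedMap:
    """Evoked tactile activity over a (hand, visual) probe grid."""

    hand_grid: np.ndarray        # (n_h, 2)
    vis_grid: np.ndarray         # (n_v, 2)
    activity: np.ndarray         # (n_h, n_v) mean tactile lambda
    meta: dict = field(default_factory=dict)

    @property
    def offsets(self) -> np.ndarray:
        """(n_h, n_v, 2) visual-minus-hand offsets (hand-centred coords)."""
        return self.vis_grid[None, :, :] - self.hand_grid[:, None, :]


def _probe(params, layouts, hand_pos, vis_pos, gain, extra=None):
    """Visible vectors for probe trials: mean-mode encoding, tactile zero."""
    n = hand_pos.shape[0]
    u = np.zeros((n, params.n_visible))
    lay_p = layouts["proprioceptive"]
    lay_v = layouts["visual"]
    u[:, params.slices["proprioceptive"]] = encode_position(
        lay_p, hand_pos, gain, mean=True)
    u[:, params.slices["visual"]] = encode_position(
        lay_v, vis_pos, gain, mean=True)
    for name, act in (extra or {}).items():
        u[:, params.slices[name]] = act
    return u


def evoked_tactile_map(
    params: NetworkParams,
    layouts: dict[str, PopulationLayout | None],
    hand_grid: np.ndarray,
    vis_grid: np.ndarray,
    gain: float = TEST_GAIN,
    handvis_visible: bool = False,
) -> EvokedMap:
    """Evoked tactile activity for every (hand, visual stimulus) pair.

    Tactile input is suppressed; visual and proprioceptive inputs are
    encoded in mean mode; the mean Poisson rate over the 30 tactile units
    after a mean-field up pass and a mean-mode down pass is the map
    value.  In the hand-vision variant the visual hand population is
    zeroed (occluded hand) unless ``handvis_visible``.
    """
    hand_grid = np.atleast_2d(hand_grid)
    vis_grid = np.atleast_2d(vis_grid)
    if hand_grid.size == 0 or vis_grid.size == 0:
        raise ValueError("empty probe grid")
    H = np.repeat(hand_grid, vis_grid.shape[0], axis=0)
    V = np.tile(vis_grid, (hand_grid.shape[0], 1))
    extra = {}
    if "handvis" in params.slices and handvis_visible:
        extra["handvis"] = encode_position(layouts["handvis"], H, gain, mean=True)
    u = _probe(params, layouts, H, V, gain, extra)
    lam = reconstruct(params, u, mask=["tactile"])
    evoked = lam[:, params.slices["tactile"]].mean(axis=1)
    act = evoked.reshape(hand_grid.shape[0], vis_grid.shape[0])
    return EvokedMap(hand_grid, vis_grid, act,
                     meta={"gain": gain, "mode": "mean",
                           "handvis_visible": handvis_visible,
                           "n_hand": int(hand_grid.shape[0]),
                           "n_vis": int(vis_grid.shape[0]),
                           "checkpoint": params.hash})


def hand_centred_curve(emap: EvokedMap, bin_edges: np.ndarray) -> pd.DataFrame:
    """Mean evoked activity binned by hand-centred distance.

    Brute-force per-trial offset computation: every (hand, vis) pair
    contributes at its own |vis - hand| distance.
    """
    d = np.linalg.norm(emap.offsets, axis=-1).ravel()
    a = emap.activity.ravel()
    idx = np.digitize(d, bin_edges) - 1
    rows = []
    for b in range(len(bin_edges) - 1):
        sel = idx == b
        if np.any(sel):
            rows.append({
                "distance": 0.5 * (bin_edges[b] + bin_edges[b + 1]),
                "evoked": float(a[sel].mean()),
                "n": int(sel.sum()),
            })
    return pd.DataFrame(rows)


def population_rf_shift(
    params: NetworkParams,
    layouts: dict[str, PopulationLayout | None],
    hand_left=(-0.25, 0.3),
    hand_right=(0.25, 0.3),
    vis_y: float = 0.3,
    n_vis: int = 41,
    gain: float = TEST_GAIN,
) -> pd.DataFrame:
    """Mean tactile-excitatory response vs. visual x, for two hand placements.

    The population visual receptive field of the touch-positive neurons
    should shift with the proprioceptively specified hand side.
    Returns a tidy frame with columns hand ('left'/'right'), vis_x, response.
    """
    prof = rf_profile(params, layouts)
    exc = prof["excitatory"].to_numpy()
    lay_v = layouts["visual"]
    xs = np.linspace(lay_v.range_lo[0], lay_v.range_hi[0], n_vis)
    vis = np.stack([xs, np.full(n_vis, vis_y)], axis=-1)
    rows = []
    for label, hand in (("left", hand_left), ("right", hand_right)):
        H = np.tile(np.asarray(hand, dtype=float), (n_vis, 1))
        u = _probe(params, layouts, H, vis, gain)
        mu, _ = up_pass(params, u, sample=False)
        resp = mu[:, exc].mean(axis=1)
        rows += [{"hand": label, "vis_x": x, "response": r}
                 for x, r in zip(xs, resp)]
    return pd.DataFrame(rows)


def rf_shift_peaks(shift: pd.DataFrame, method: str = "centroid") -> dict[str, float]:
    """Peak visual-x of each hand condition's population response curve.

    The population-mean curve is broad and flat-topped, so the default
    estimator is the centroid of the above-baseline response; ``argmax``
    is available for sharply peaked curves.
    """
    out = {}
    for label, g in shift.groupby("hand"):
        if method == "argmax":
            out[label] = float(g.loc[g["response"].idxmax(), "vis_x"])
        else:
            w = g["response"] - g["response"].min()
            out[label] = float((w * g["vis_x"]).sum() / w.sum())
    return out


# ---------------------------------------------------------------------------
# illusion simulations


@dataclass
class DriftCurve:
    """Decoded proprioceptive position per visual offset and touch gain."""

    table: pd.DataFrame   # columns: offset, tactile_gain, decoded_x, drift, drift_pct
    hand: tuple[float, float]
    meta: dict = field(default_factory=dict)

    def max_drift_pct(self, touch_on: bool = True,
                      min_offset: float = 0.10) -> float:
        """Maximal drift as % of disparity.

        Offsets below ``min_offset`` (default one proprioceptive tuning
        width) are excluded: the ratio is ill-conditioned there.  The
        maximum is taken over |offset| of the drift averaged across
        sides and tactile intensities.
        """
        t = self.table
        sel = ((t["tactile_gain"] > 0 if touch_on else t["tactile_gain"] == 0)
               & (t["offset"].abs() >= min_offset))
        by = t[sel].groupby(t["offset"].abs())["drift_pct"].mean()
        return float(by.abs().max())


def drift_experiment(
    params: NetworkParams,
    layouts: dict[str, PopulationLayout | None],
    protocol: str = "IHI",
    offsets: np.ndarray | None = None,
    tactile_gains=(0.0, 2.0, 4.0, 6.0, 8.0, 10.0),
    hand=(0.0, 0.3),
    gain: float = TEST_GAIN,
) -> DriftCurve:
    """Simulated invisible / rubber hand illusion.

    The proprioceptive input is fixed at the midline hand position while
    the visual stimulus is placed at lateral offsets; tactile input is
    either absent (asynchronous control) or present at a positive gain
    (synchronous stroking).  The decoded proprioceptive barycentre after
    an up + mean-mode down pass gives the perceived hand position; drift
    is reported in metres and as a percentage of the visuo-proprioceptive
    disparity.

    ``protocol='RHI'`` additionally encodes the visual-hand population at
    the stimulus position (the rubber hand); it requires a hand-vision
    checkpoint.  ``protocol='IHI'`` zeroes that population when present.
    """
    if protocol not in ("IHI", "RHI"):
        raise ValueError("protocol must be 'IHI' or 'RHI'")
    if protocol == "RHI" and "handvis" not in params.slices:
        raise ValueError("RHI requires a checkpoint with a hand-visual population")
    if offsets is None:
        offsets = np.linspace(-0.40, 0.40, 17)
    offsets = np.round(np.asarray(offsets, dtype=float), 9)
    hand = np.asarray(hand, dtype=float)
    lay_p = layouts["proprioceptive"]
    sl_p = params.slices["proprioceptive"]
    sl_t = params.slices["tactile"]
    rows = []
    for gt in tactile_gains:
        V = hand + np.stack([offsets, np.zeros_like(offsets)], axis=-1)
        H = np.tile(hand, (len(offsets), 1))
        extra = {"tactile": np.full((len(offsets), N_TACTILE), float(gt))}
        if protocol == "RHI":
            extra["handvis"] = encode_position(layouts["handvis"], V, gain,
                                               mean=True)
        u = _probe(params, layouts, H, V, gain, extra)
        lam = reconstruct(params, u, mask=None)
        decoded = decode_barycentre(lay_p, lam[:, sl_p])
        for off, dec in zip(offsets, decoded):
            drift = dec[0] - hand[0]
            rows.append({
                "offset": off,
                "tactile_gain": float(gt),
                "decoded_x": dec[0],
                "drift": drift,
                "drift_pct": 100.0 * drift / off if abs(off) > 1e-9 else 0.0,
            })
    return DriftCurve(pd.DataFrame(rows), tuple(hand),
                      meta={"protocol": protocol, "gain": gain,
                            "tactile_gains": tuple(float(g) for g in
                                                   tactile_gains),
                            "checkpoint": params.hash})


# ---------------------------------------------------------------------------
# congruency prediction (in-silico counterpart of the VR tactile-RT setup)


def congruency_prediction(
    params: NetworkParams,
    layouts: dict[str, PopulationLayout | None],
    hand_dx: float = 0.25,
    hand_y: float = 0.30,
    fixation=(0.0, 0.80),
    traj_len: float = 0.50,
    n_points: int = 11,
    gain: float = TEST_GAIN,
) -> pd.DataFrame:
    """Predicted multisensory facilitation along three ball trajectories.

    The hand rests 25 cm left or right of the midline, 30 cm anterior.
    Trajectories start at a central fixation point and either approach
    the hand (congruent), approach the mirror position (incongruent), or
    recede from the body (receding).  The facilitation proxy is the
    evoked tactile activity averaged along the trajectory.
    """
    fixation = np.asarray(fixation, dtype=float)
    rows = []
    for side, hx in (("left", -hand_dx), ("right", hand_dx)):
        hand = np.array([hx, hand_y])
        mirror = np.array([-hx, hand_y])
        away = fixation + np.array([0.0, traj_len])
        for cond, target in (("congruent", hand), ("incongruent", mirror),
                             ("receding", away)):
            direction = target - fixation
            direction = direction / np.linalg.norm(direction)
            ts = np.linspace(0.0, traj_len, n_points)
            pts = fixation + ts[:, None] * direction
            emap = evoked_tactile_map(params, layouts, hand[None, :], pts, gain)
            rows.append({
                "hand": side,
                "condition": cond,
                "facilitation": float(emap.activity.mean()),
                "facilitation_end": float(emap.activity[0, -1]),
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# three-layer (shifting receptive fields)


def _smooth_argmax(grid_vals: np.ndarray, sigma: float = 1.0) -> tuple[int, int]:
    sm = ndimage.gaussian_filter(grid_vals, sigma=sigma, mode="nearest")
    return np.unravel_index(np.argmax(sm), grid_vals.shape)


def rf_peak_hand_correlation(
    params1: NetworkParams,
    params2: NetworkParams,
    layouts: dict[str, PopulationLayout | None],
    n_hand: int = 100,
    n_vis: int = 15,
    gain: float = TEST_GAIN,
    rng: np.random.Generator | None = None,
    smooth_sigma: float = 1.0,
) -> pd.DataFrame:
    """Hand-position tuning of third-layer neurons in the stagewise network.

    With tactile input zeroed, each third-layer neuron's visual receptive
    field is mapped on an ``n_vis x n_vis`` stimulus grid for ``n_hand``
    hand positions; the RF peak (argmax after Gaussian smoothing, sigma =
    1 grid cell) is correlated with the hand position along x and y and
    the two Pearson r averaged.  Returned together with each neuron's
    mean incoming weight from the 30 unisensory tactile units.
    """
    rng = rng or np.random.default_rng(0)
    lay_v = layouts["visual"]
    lo = np.array(lay_v.range_lo)
    hi = np.array(lay_v.range_hi)
    xs = np.linspace(lo[0], hi[0], n_vis)
    ys = np.linspace(lo[1], hi[1], n_vis)
    mesh = np.meshgrid(xs, ys, indexing="ij")
    vis = np.stack([m.ravel() for m in mesh], axis=-1)

    from .worldgen import HAND_RANGE
    hands = rng.uniform(np.array(HAND_RANGE[0]), np.array(HAND_RANGE[1]),
                        size=(n_hand, 2))

    n3 = params2.n_multi
    peaks = np.empty((n_hand, n3, 2))
    for h, hand in enumerate(hands):
        H = np.tile(hand, (vis.shape[0], 1))
        u = _probe(params1, layouts, H, vis, gain)
        mu1, _ = up_pass(params1, u, sample=False)
        v2 = np.concatenate([mu1, np.zeros((vis.shape[0], N_TACTILE))], axis=-1)
        mu2, _ = up_pass(params2, v2, sample=False)
        for j in range(n3):
            i, k = _smooth_argmax(mu2[:, j].reshape(n_vis, n_vis), smooth_sigma)
            peaks[h, j] = (xs[i], ys[k])

    tact_strength = params2.W[:, params2.slices["tactile"]].mean(axis=1)
    rows = []
    for j in range(n3):
        rx = _safe_pearson(hands[:, 0], peaks[:, j, 0])
        ry = _safe_pearson(hands[:, 1], peaks[:, j, 1])
        rows.append({
            "neuron": j,
            "corr_x": rx,
            "corr_y": ry,
            "correlation": 0.5 * (rx + ry),
            "tactile_input_strength": tact_strength[j],
        })
    return pd.DataFrame(rows)


def _safe_pearson(a: np.ndarray, b: np.ndarray) -> float:
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return 0.0
    return float(stats.pearsonr(a, b)[0])
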