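"""Synthetic stimulus streams: the physical world the network learns from.

Each trial is one simultaneous multisensory event: a hand position (drawn
directly or through two-joint arm kinematics), an external visual stimulus
position, independent per-population gains, and a touch flag.  In the
body-constrained condition touch occurs exactly when the visual stimulus
falls within 15 cm of the hand; in the unconstrained control touch is a
coin flip with the same marginal rate, destroying the geometric
contingency while keeping every marginal identical.

Variants:

``constrained``    hand and stimulus uniform, touch from geometry (default)
``unconstrained``  same marginals, touch ~ Bernoulli(0.05) independent
``handvision``     adds a second visual population coding hand position,
                   congruent 50% / occluded 25% / dissociated 25%
``joint``          proprioception as shoulder/elbow angles, touch via
                   forward kinematics
``gaze``           joint variant plus a gaze population; visual input is
                   eye-centred and rotated by -gaze into body coordinates
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "HAND_RANGE",
    "VIS_RANGE",
    "TOUCH_RADIUS",
    "GAIN_RANGE",
    "ARM_LENGTHS",
    "WorldBatch",
    "touch_rule",
    "forward_kinematics",
    "gaze_rotate",
    "sample_constrained",
    "sample_unconstrained",
    "sample_handvision",
    "sample_joint",
    "sample_gaze",
    "sample_variant",
    "CONGRUENT",
    "OCCLUDED",
    "DISSOCIATED",
]

#: hand workspace (1.2 x 0.6 m): x medial-lateral, y anterior-posterior
HAND_RANGE = ((-0.6, 0.0), (0.6, 0.6))
#: visual-stimulus workspace (1.2 x 1.2 m)
VIS_RANGE = ((-0.6, 0.0), (0.6, 1.2))
#: touch is delivered strictly below this hand-stimulus distance (m)
TOUCH_RADIUS = 0.15
#: per-population stimulus gains are uniform on this interval
GAIN_RANGE = (4.0, 10.0)
#: upper arm and forearm lengths (m), shoulder to hand centre
ARM_LENGTHS = (0.3, 0.35)

JOINT1_RANGE = (-np.pi / 4, np.pi / 2)
JOINT2_RANGE = (-np.pi / 2, 0.0)
GAZE_RANGE = (-np.pi / 4, np.pi / 4)

# hand-vision trial categories
CONGRUENT, OCCLUDED, DISSOCIATED = 0, 1, 2


@dataclass
class WorldBatch:
    """Ground-truth physical state for a batch of trials.

    ``gains`` maps population name -> per-trial gain.  Optional fields are
    None unless the variant provides them; ``handvis_pos`` is NaN on
    occluded trials.
    """

    hand_pos: np.ndarray                 # (n, 2) body-centred, m
    vis_pos: np.ndarray                  # (n, 2) body-centred, m
    gains: dict[str, np.ndarray]
    touch: np.ndarray                    # (n,) bool
    joint_angles: np.ndarray | None = None   # (n, 2) rad
    gaze: np.ndarray | None = None           # (n,) rad
    vis_pos_eye: np.ndarray | None = None    # (n, 2) eye-centred, m
    handvis_pos: np.ndarray | None = None    # (n, 2) m, NaN if occluded
    handvis_category: np.ndarray | None = None  # (n,) int

    def __len__(self) -> int:
        return self.hand_pos.shape[0]


def touch_rule(hand_pos, vis_pos) -> np.ndarray:
    """True iff the hand-stimulus Euclidean distance is strictly < 15 cm."""
    d = np.linalg.norm(np.asarray(vis_pos) - np.asarray(hand_pos), axis=-1)
    return d < TOUCH_RADIUS


def forward_kinematics(theta1, theta2):
    """Hand position from shoulder (theta1) and elbow (theta2) angles.

        x = 0.3 sin(t1) + 0.35 sin(t1 + t2)
        y = 0.3 cos(t1) + 0.35 cos(t1 + t2)

    theta1 = 0 points the arm straight ahead; theta2 = 0 is full extension.
    """
    l1, l2 = ARM_LENGTHS
    t1 = np.asarray(theta1, dtype=float)
    t2 = np.asarray(theta2, dtype=float)
    x = l1 * np.sin(t1) + l2 * np.sin(t1 + t2)
    y = l1 * np.cos(t1) + l2 * np.cos(t1 + t2)
    return np.stack([x, y], axis=-1)


def gaze_rotate(vis_pos_eye, gaze_angle) -> np.ndarray:
    """Eye-centred -> body-centred: rotate by the negative gaze angle.

    Planar rotation about the body's vertical axis; gaze 0 is the
    identity.
    """
    p = np.asarray(vis_pos_eye, dtype=float)
    a = -np.asarray(gaze_angle, dtype=float)
    c, s = np.cos(a), np.sin(a)
    x = c * p[..., 0] - s * p[..., 1]
    y = s * p[..., 0] + c * p[..., 1]
    return np.stack([x, y], axis=-1)


def _uniform(rng, lo, hi, n):
    lo = np.asarray(lo, dtype=float)
    hi = np.asarray(hi, dtype=float)
    return rng.uniform(lo, hi, size=(n,) + lo.shape)


def _gains(rng, n, names):
    lo, hi = GAIN_RANGE
    return {name: rng.uniform(lo, hi, n) for name in names}


def sample_constrained(n: int, rng: np.random.Generator) -> WorldBatch:
    """Body-constrained stream: touch tied to the 15 cm geometry (~5%)."""
    hand = _uniform(rng, *HAND_RANGE, n)
    vis = _uniform(rng, *VIS_RANGE, n)
    gains = _gains(rng, n, ("tactile", "proprioceptive", "visual"))
    return WorldBatch(hand, vis, gains, touch_rule(hand, vis))


def sample_unconstrained(
    n: int, rng: np.random.Generator, p_touch: float = 0.05
) -> WorldBatch:
    """Control stream: same marginals, touch ~ Bernoulli(p_touch)."""
    hand = _uniform(rng, *HAND_RANGE, n)
    vis = _uniform(rng, *VIS_RANGE, n)
    gains = _gains(rng, n, ("tactile", "proprioceptive", "visual"))
    return WorldBatch(hand, vis, gains, rng.random(n) < p_touch)


def sample_handvision(
    n: int,
    rng: np.random.Generator,
    p_occluded: float = 0.25,
    p_dissociated: float = 0.25,
) -> WorldBatch:
    """Constrained stream plus a visual population coding hand position.

    Per trial, one categorical draw: occluded (hand not visible, activity
    suppressed), dissociated (someone else's hand at an independent
    uniform position), otherwise congruent (visual hand = proprioceptive
    hand).  Touch is still driven by the proprioceptive hand.
    """
    if p_occluded + p_dissociated > 1:
        raise ValueError("category probabilities must sum to at most 1")
    b = sample_constrained(n, rng)
    b.gains["handvis"] = rng.uniform(*GAIN_RANGE, n)
    u = rng.random(n)
    cat = np.full(n, CONGRUENT)
    cat[u < p_occluded] = OCCLUDED
    cat[(u >= p_occluded) & (u < p_occluded + p_dissociated)] = DISSOCIATED
    hv = b.hand_pos.copy()
    hv[cat == OCCLUDED] = np.nan
    n_dis = int(np.sum(cat == DISSOCIATED))
    hv[cat == DISSOCIATED] = _uniform(rng, *HAND_RANGE, n_dis)
    b.handvis_pos = hv
    b.handvis_category = cat
    return b


def sample_joint(n: int, rng: np.random.Generator) -> WorldBatch:
    """Joint-angle stream: shoulder/elbow angles uniform, touch via kinematics."""
    th1 = rng.uniform(*JOINT1_RANGE, n)
    th2 = rng.uniform(*JOINT2_RANGE, n)
    hand = forward_kinematics(th1, th2)
    vis = _uniform(rng, *VIS_RANGE, n)
    gains = _gains(rng, n, ("tactile", "proprioceptive", "visual"))
    b = WorldBatch(hand, vis, gains, touch_rule(hand, vis))
    b.joint_angles = np.stack([th1, th2], axis=-1)
    return b


def sample_gaze(n: int, rng: np.random.Generator) -> WorldBatch:
    """Gaze stream: joint variant plus uniform gaze; visual input eye-centred.

    The eye-centred stimulus is rotated by the negative gaze angle into
    body-centred coordinates before the touch rule is applied.
    """
    b = sample_joint(n, rng)
    gaze = rng.uniform(*GAZE_RANGE, n)
    vis_eye = b.vis_pos
    vis_body = gaze_rotate(vis_eye, gaze)
    b.vis_pos_eye = vis_eye
    b.vis_pos = vis_body
    b.gaze = gaze
    b.gains["gaze"] = rng.uniform(*GAIN_RANGE, n)
    b.touch = touch_rule(b.hand_pos, vis_body)
    return b


_SAMPLERS = {
    "constrained": sample_constrained,
    "unconstrained": sample_unconstrained,
    "handvision": sample_handvision,
    "joint": sample_joint,
    "gaze": sample_gaze,
}


def sample_variant(variant: str, n: int, rng: np.random.Generator, **kw) -> WorldBatch:
    """Dispatch to the sampler for ``variant``."""
    try:
        sampler = _SAMPLERS[variant]
    except KeyError:
        raise ValueError(
            f"unknown variant {variant!r}; choose from {sorted(_SAMPLERS)}"
        ) from None
    return sampler(n, rng, **kw)
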