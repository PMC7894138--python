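"""Receptive-field profiling, evoked maps and illusion protocols (unit level)."""

import numpy as np
import pandas as pd
import pytest

from ppsnet import analyses
from ppsnet.config import TrainingConfig
from ppsnet.popcode import encode_position
from ppsnet.rbm import NetworkParams
from ppsnet.training import build_layouts, layer_slices


@pytest.fixture(scope="module")
def small_setup():
    cfg = TrainingConfig.preset(scale="reduced", visual_n=20, n_multi=16)
    layouts = build_layouts(cfg)
    slices = layer_slices(layouts)
    return cfg, layouts, slices


def crafted_params(layouts, slices, n_multi=16, seed=0):
    """Parameters whose visual and proprioceptive weight maps are Gaussians
    centred at known positions, so overlap values are controlled exactly."""
    rng = np.random.default_rng(seed)
    n_vis = max(s.stop for s in slices.values())
    W = 0.001 * rng.normal(size=(n_multi, n_vis))
    params = NetworkParams(W, np.zeros(n_vis), np.zeros(n_multi), dict(slices))
    lay_p, lay_v = layouts["proprioceptive"], layouts["visual"]

    def gauss(points, centre, sigma):
        z = ((points - centre) / sigma) ** 2
        return np.exp(-0.5 * z.sum(axis=-1))

    for j in range(n_multi):
        centre = np.array([0.3 * np.cos(j), 0.25 + 0.2 * (j % 3) / 2])
        # same spatial function sampled on both grids -> identical maps
        vmap = gauss(lay_v.preferred, centre, lay_p.sigma)
        pmap = gauss(lay_p.preferred, centre, lay_p.sigma)
        sign = 1.0 if j % 2 == 0 else -1.0
        W[j, slices["visual"]] = vmap
        # aligned proprio map for even neurons, inverted for odd ones
        W[j, slices["proprioceptive"]] = sign * pmap
        W[j, slices["tactile"]] = sign * 0.1
    return params


class TestRFProfile:
    def test_aligned_maps_give_overlap_near_one(self, small_setup):
        _, layouts, slices = small_setup
        params = crafted_params(layouts, slices)
        prof = analyses.rf_profile(params, layouts)
        aligned = prof[prof["excitatory"]]
        assert np.all(aligned["vp_overlap"] > 0.95)

    def test_negated_maps_give_overlap_near_minus_one(self, small_setup):
        _, layouts, slices = small_setup
        params = crafted_params(layouts, slices)
        prof = analyses.rf_profile(params, layouts)
        inverted = prof[~prof["excitatory"]]
        assert np.all(inverted["vp_overlap"] < -0.95)

    def test_tactile_strength_is_mean_of_tactile_columns(self, small_setup):
        _, layouts, slices = small_setup
        params = crafted_params(layouts, slices)
        prof = analyses.rf_profile(params, layouts)
        manual = params.W[:, slices["tactile"]].mean(axis=1)
        assert np.allclose(prof["tactile_strength"], manual)

    def test_preferred_visual_distance_tracks_map_centre(self, small_setup):
        _, layouts, slices = small_setup
        params = crafted_params(layouts, slices)
        prof = analyses.rf_profile(params, layouts)
        # neuron 0's visual map peaks at y = 0.25
        assert prof.loc[0, "preferred_visual_distance"] == pytest.approx(
            0.25, abs=layouts["visual"].spacing[1])

    def test_untrained_overlap_flagged_unreliable(self, small_setup):
        _, layouts, slices = small_setup
        n_vis = max(s.stop for s in slices.values())
        params = NetworkParams(np.zeros((4, n_vis)), np.zeros(n_vis),
                               np.zeros(4), dict(slices))
        prof = analyses.rf_profile(params, layouts)
        assert not prof["overlap_reliable"].any()


class TestScalarSummaries:
    def test_excitatory_fraction_all_positive(self):
        t = pd.DataFrame({"excitatory": [True] * 7})
        assert analyses.excitatory_fraction(t) == 100.0

    def test_overlap_index_matches_definition(self):
        t = pd.DataFrame({
            "excitatory": [True, True, False, False],
            "vp_overlap": [0.8, 0.6, -0.5, -0.3],
        })
        assert analyses.overlap_index(t) == pytest.approx(0.7 - (-0.4))

    def test_overlap_index_zero_when_one_class_empty(self):
        t = pd.DataFrame({"excitatory": [True, True],
                          "vp_overlap": [0.5, 0.7]})
        assert analyses.overlap_index(t) == 0.0

    def test_bimodality_score_separates_cases(self):
        rng = np.random.default_rng(0)
        bimodal = np.concatenate([rng.normal(-2, 0.5, 300),
                                  rng.normal(2, 0.5, 300)])
        unimodal = rng.normal(0, 1, 600)
        assert analyses.bimodality_delta_bic(bimodal) > 10
        assert analyses.bimodality_delta_bic(unimodal) < 10


class TestEvokedMap:
    def test_untrained_map_is_flat(self, tiny_untrained):
        res = tiny_untrained
        hands = np.array([[-0.3, 0.3], [0.0, 0.3], [0.3, 0.3]])
        vis = np.array([[-0.3, 0.3], [0.0, 0.3], [0.3, 0.3], [0.0, 0.9]])
        emap = res.evoked_map(hands, vis)
        cv = emap.activity.std() / emap.activity.mean()
        assert cv < 0.05

    def test_empty_grid_rejected(self, tiny_untrained):
        with pytest.raises(ValueError, match="empty"):
            tiny_untrained.evoked_map(np.empty((0, 2)), np.zeros((1, 2)))

    def test_offsets_are_vis_minus_hand(self, tiny_untrained):
        hands = np.array([[0.1, 0.2]])
        vis = np.array([[0.3, 0.5]])
        emap = tiny_untrained.evoked_map(hands, vis)
        assert np.allclose(emap.offsets[0, 0], [0.2, 0.3])

    def test_hand_centred_rebinning_matches_brute_force(self, tiny_untrained):
        rng = np.random.default_rng(3)
        hands = rng.uniform([-0.4, 0.1], [0.4, 0.5], (4, 2))
        vis = rng.uniform([-0.5, 0.1], [0.5, 1.1], (9, 2))
        emap = tiny_untrained.evoked_map(hands, vis)
        edges = np.array([0.0, 0.2, 0.4, 0.8, 1.5])
        curve = analyses.hand_centred_curve(emap, edges)
        # brute force over every (hand, vis) pair
        for _, row in curve.iterrows():
            lo = row["distance"] - np.diff(edges)[
                np.searchsorted(edges, row["distance"]) - 1] / 2
            vals = []
            for i, h in enumerate(hands):
                for j, v in enumerate(vis):
                    d = np.linalg.norm(v - h)
                    e_idx = np.digitize(d, edges) - 1
                    if edges[e_idx] == pytest.approx(lo):
                        vals.append(emap.activity[i, j])
            assert row["evoked"] == pytest.approx(np.mean(vals))
            assert row["n"] == len(vals)


class TestDrift:
    def test_rhi_requires_handvis_population(self, tiny_trained):
        with pytest.raises(ValueError, match="hand-visual"):
            tiny_trained.drift(protocol="RHI")

    def test_unknown_protocol_rejected(self, tiny_trained):
        with pytest.raises(ValueError, match="protocol"):
            tiny_trained.drift(protocol="XHI")

    def test_table_layout_and_zero_offset_handling(self, tiny_trained):
        curve = tiny_trained.drift(offsets=np.linspace(-0.2, 0.2, 5),
                                   tactile_gains=(0.0, 6.0))
        t = curve.table
        assert set(t.columns) >= {"offset", "tactile_gain", "decoded_x",
                                  "drift", "drift_pct"}
        assert len(t) == 10
        zero = t[np.abs(t.offset) < 1e-12]
        assert np.all(zero["drift_pct"] == 0.0)

    def test_identical_hand_inputs_give_identical_curves(self, tiny_trained):
        shift = tiny_trained.rf_shift(hand_left=(0.1, 0.3),
                                      hand_right=(0.1, 0.3), n_vis=11)
        left = shift[shift.hand == "left"]["response"].to_numpy()
        right = shift[shift.hand == "right"]["response"].to_numpy()
        assert np.allclose(left, right)


class TestCongruency:
    def test_geometry_and_output_shape(self, tiny_trained):
        tab = tiny_trained.congruency(n_points=5)
        assert len(tab) == 6  # 2 hands x 3 conditions
        assert set(tab["condition"]) == {"congruent", "incongruent",
                                         "receding"}

    def test_analyses_are_deterministic(self, tiny_trained):
        a = tiny_trained.congruency(n_points=5)
        b = tiny_trained.congruency(n_points=5)
        pd.testing.assert_frame_equal(a, b)


class TestProvenance:
    def test_outputs_carry_checkpoint_hash_and_protocol(self, tiny_trained):
        emap = tiny_trained.evoked_map(np.array([[0.0, 0.3]]),
                                       np.array([[0.1, 0.3]]))
        assert emap.meta["checkpoint"] == tiny_trained.params.hash
        curve = tiny_trained.drift(offsets=np.array([-0.1, 0.1]),
                                   tactile_gains=(0.0, 6.0))
        assert curve.meta["checkpoint"] == tiny_trained.params.hash
        assert curve.meta["protocol"] == "IHI"
        # hash tracks content
        other = tiny_trained.params.copy()
        other.W[0, 0] += 1.0
        assert other.hash != tiny_trained.params.hash
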