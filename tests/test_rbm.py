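"""RBM passes, CD-1 learning rule, and the likelihood-improvement oracle."""

import itertools

import numpy as np
import pytest
from scipy.special import expit

from ppsnet import rbm
from ppsnet.rbm import (NetworkParams, cd1_update, down_pass, init_params,
                        make_slices, reconstruct, reconstruction_error,
                        up_pass)


def toy_params(W, b_u=None, b_m=None):
    W = np.atleast_2d(np.asarray(W, dtype=float))
    n_m, n_v = W.shape
    return NetworkParams(
        W,
        np.zeros(n_v) if b_u is None else np.asarray(b_u, dtype=float),
        np.zeros(n_m) if b_m is None else np.asarray(b_m, dtype=float),
        {"all": slice(0, n_v)},
    )


class _RiggedRng:
    """Deterministic stand-in: Poisson returns the mean rounded, Bernoulli
    thresholds at 0.5."""

    def poisson(self, lam):
        return np.round(lam).astype(int)

    def random(self, shape=None):
        return np.full(shape, 0.5) if shape else 0.5


class TestUpPass:
    def test_zero_weights_give_half(self):
        p = toy_params(np.zeros((4, 3)))
        mu, m = up_pass(p, np.array([1.0, 2.0, 3.0]), sample=False)
        assert np.allclose(mu, 0.5)
        assert np.allclose(m, mu)

    def test_scalar_logistic_oracle(self):
        w, u0 = 0.7, 3.0
        p = toy_params([[w]])
        mu, _ = up_pass(p, np.array([u0]), sample=False)
        assert mu[0] == pytest.approx(1.0 / (1.0 + np.exp(-w * u0)))

    def test_large_negative_bias_saturates(self):
        p = toy_params(np.zeros((2, 2)), b_m=[-50.0, -50.0])
        mu, _ = up_pass(p, np.zeros(2), sample=False)
        assert np.all(mu < 1e-20)

    def test_dimension_mismatch_names_slices(self):
        p = toy_params(np.zeros((2, 3)))
        with pytest.raises(ValueError, match="all"):
            up_pass(p, np.zeros(5), sample=False)

    def test_sampling_is_binary(self):
        p = toy_params(np.zeros((10, 3)))
        _, m = up_pass(p, np.ones(3), np.random.default_rng(0), sample=True)
        assert set(np.unique(m)) <= {0.0, 1.0}


class TestDownPass:
    def test_zero_weights_give_unit_rate(self):
        p = toy_params(np.zeros((2, 3)))
        lam, u = down_pass(p, np.array([1.0, 0.0]), sample=False)
        assert np.allclose(lam, 1.0)
        assert np.allclose(u, lam)

    def test_bias_sets_rate(self):
        c = 4.2
        p = toy_params(np.zeros((2, 3)), b_u=np.log(c) * np.ones(3))
        lam, _ = down_pass(p, np.zeros(2), sample=False)
        assert np.allclose(lam, c)

    def test_scalar_exponential_oracle(self):
        w, b = 0.3, -0.2
        p = toy_params([[w]], b_u=[b])
        lam, _ = down_pass(p, np.array([1.0]), sample=False)
        assert lam[0] == pytest.approx(np.exp(w + b))

    def test_rate_ceiling_is_clipped_and_logged(self, caplog):
        p = toy_params([[20.0]])
        with caplog.at_level("WARNING"):
            lam, _ = down_pass(p, np.array([1.0]), sample=False)
        assert lam[0] == pytest.approx(np.exp(10.0))
        assert "clipping" in caplog.text


class TestCD1:
    def test_identical_phases_give_zero_update(self):
        # rigged generator reproduces u0 exactly: lam rounds back to u0
        rng = np.random.default_rng(3)
        p = init_params(3, {"all": slice(0, 4)}, rng, w_sd=0.001)
        W0, bu0, bm0 = p.W.copy(), p.b_u.copy(), p.b_m.copy()

        class _Identity(_RiggedRng):
            def __init__(self, u0):
                self.u0 = u0

            def poisson(self, lam):
                return np.broadcast_to(self.u0, lam.shape).astype(int)

        u0 = np.array([[1.0, 2.0, 0.0, 1.0]])
        cd1_update(p, u0, _Identity(u0[0]), eta=0.1)
        # m0 and m1 come from the same thresholded mean on identical inputs
        assert np.allclose(p.W, W0)
        assert np.allclose(p.b_u, bu0)
        assert np.allclose(p.b_m, bm0)

    def test_batch_of_identical_samples_equals_single(self):
        u = np.array([2.0, 1.0, 3.0])
        for batch in (u[None, :], np.tile(u, (8, 1))):
            rng = _RiggedRng()
            p = toy_params(0.01 * np.arange(6).reshape(2, 3))
            cd1_update(p, batch, rng, eta=0.05)
            if batch.shape[0] == 1:
                single = p.W.copy()
            else:
                assert np.allclose(p.W, single)

    def test_two_unit_step_matches_hand_computation(self):
        # 1 visible, 1 hidden; every stochastic step made deterministic
        w0, bu0, bm0, eta = 0.5, 0.1, -0.2, 0.01
        u0 = 2.0
        p = toy_params([[w0]], b_u=[bu0], b_m=[bm0])
        rng = _RiggedRng()
        cd1_update(p, np.array([[u0]]), rng, eta=eta)
        # hand computation with the same rigging:
        mu0 = expit(w0 * u0 + bm0)            # = sigmoid(0.9) > 0.5 -> m0 = 1
        m0 = 1.0
        lam1 = np.exp(w0 * m0 + bu0)          # = e^0.6 = 1.822 -> u1 = 2
        u1 = np.round(lam1)
        mu1 = expit(w0 * u1 + bm0)
        m1 = 1.0 if mu1 > 0.5 else 0.0
        dW = eta * (u0 * m0 - u1 * m1)
        assert p.W[0, 0] == pytest.approx(w0 + dW)
        assert p.b_u[0] == pytest.approx(bu0 + eta * (u0 - u1))
        assert p.b_m[0] == pytest.approx(bm0 + eta * (m0 - m1))

    def test_empty_batch_rejected(self):
        p = toy_params(np.zeros((2, 3)))
        with pytest.raises(ValueError, match="empty"):
            cd1_update(p, np.empty((0, 3)), np.random.default_rng(0))

    def test_weight_symmetry_is_structural(self):
        # one shared matrix serves both passes: no second copy exists to drift
        rng = np.random.default_rng(0)
        p = init_params(4, {"all": slice(0, 6)}, rng)
        W_id = id(p.W)
        for _ in range(5):
            cd1_update(p, rng.poisson(2.0, size=(10, 6)).astype(float), rng)
        assert id(p.W) == W_id


class TestReconstruction:
    def test_untrained_reconstruction_is_bias_dominated(self):
        rng = np.random.default_rng(1)
        p = init_params(20, {"all": slice(0, 10)}, rng, w_sd=0.001)
        lam = reconstruct(p, np.full(10, 5.0))
        assert np.allclose(lam, np.exp(p.b_u), rtol=0.05)

    def test_unknown_mask_rejected(self):
        p = toy_params(np.zeros((2, 3)))
        with pytest.raises(KeyError, match="nope"):
            reconstruct(p, np.ones(3), mask=["nope"])

    def test_mask_all_populations_leaves_only_biases(self):
        rng = np.random.default_rng(2)
        p = init_params(5, {"all": slice(0, 4)}, rng, w_sd=0.5)
        lam = reconstruct(p, np.full(4, 9.0), mask=["all"])
        # masked input -> up pass sees zeros -> mu = sigmoid(b_m) = 0.5
        expected = np.exp(0.5 * p.W.sum(axis=0) + p.b_u)
        assert np.allclose(lam, expected)

    def test_error_zero_for_perfect_reconstruction(self):
        p = toy_params(np.zeros((2, 3)))

        class _Copy(_RiggedRng):
            def poisson(self, lam):
                return np.ones_like(lam, dtype=int)

        err = reconstruction_error(p, np.ones((4, 3)), _Copy())
        assert err == 0.0

    def test_error_nonnegative_and_trained_below_untrained(
            self, tiny_trained, tiny_untrained):
        from ppsnet.training import build_layouts, encode_batch, sample_world
        rng = np.random.default_rng(5)
        cfg = tiny_trained.config
        batch = sample_world(cfg, 200, rng)
        u0 = encode_batch(batch, build_layouts(cfg), rng)
        e_tr = reconstruction_error(tiny_trained.params, u0,
                                    np.random.default_rng(0))
        e_un = reconstruction_error(tiny_untrained.params, u0,
                                    np.random.default_rng(0))
        assert 0.0 <= e_tr < e_un


class TestDeterminism:
    def test_mean_mode_pipeline_is_deterministic(self):
        rng = np.random.default_rng(4)
        p = init_params(6, {"all": slice(0, 5)}, rng, w_sd=0.1)
        u = np.arange(5.0)
        a = reconstruct(p, u)
        b = reconstruct(p, u)
        assert np.array_equal(a, b)


def exact_log_likelihood(p: NetworkParams, patterns: np.ndarray) -> float:
    """Exact mean log p(u) by enumerating hidden states (oracle).

    For the Poisson-visible RBM, summing the joint over all visible counts
    at fixed hidden state m gives exp(b_m.m + sum_i lambda_i(m)), so the
    partition function is a finite sum over hidden configurations.
    """
    n_m = p.n_multi
    hidden = np.array(list(itertools.product([0.0, 1.0], repeat=n_m)))
    log_lam = hidden @ p.W + p.b_u                # (2^n_m, n_v)
    lam = np.exp(log_lam)
    log_z_terms = hidden @ p.b_m + lam.sum(axis=1)
    log_z = np.logaddexp.reduce(log_z_terms)
    total = 0.0
    from scipy.special import gammaln
    for u in patterns:
        joint = (hidden @ (p.W @ u) + p.b_u @ u + hidden @ p.b_m
                 - gammaln(u + 1).sum())
        total += np.logaddexp.reduce(joint) - log_z
    return total / len(patterns)


def test_cd1_raises_exact_likelihood_on_toy_problem():
    """On a 3-visible/2-hidden RBM, CD-1 training increases the exact data
    log-likelihood computed by partition-function enumeration."""
    rng = np.random.default_rng(8)
    patterns = np.array([[4.0, 0.0, 4.0], [0.0, 4.0, 0.0]])
    p = init_params(2, {"all": slice(0, 3)}, rng, w_sd=0.001)
    ll0 = exact_log_likelihood(p, patterns)
    for _ in range(300):
        batch = patterns[rng.integers(0, 2, size=20)]
        cd1_update(p, batch, rng, eta=0.02)
    ll1 = exact_log_likelihood(p, patterns)
    assert ll1 > ll0 + 0.5
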