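"""Learning-rule correctness: hand examples, identities, and gradient oracles."""

import numpy as np
import pytest

import perturbrnn as pr
from perturbrnn.model import NoisyTrajectory, Trajectory, forward_clean, loss_record
from perturbrnn.rules import decorrelation_update

from conftest import scalar_params


def make_scalar_pair(u, xi, nu, ell, ell_noisy, params=None):
    """Hand-build a clean/noisy trajectory pair for a 1-unit network.

    The trajectories carry exactly the fields the rules read: inputs,
    pre-activations, states and the injected node noise.
    """
    params = params or scalar_params(0, 0, 0)
    u = np.asarray(u, float).reshape(-1, 1)
    clean = forward_clean(params, u)
    T = u.shape[0]
    xi = np.asarray(xi, float).reshape(T, 1)
    nu = np.asarray(nu, float).reshape(T, 1)
    noisy = NoisyTrajectory(
        u=u, alpha=clean.alpha + xi, x=np.tanh(clean.alpha + xi),
        beta=clean.beta + nu, y=clean.beta + nu,
        node_noise={"xi": xi, "nu": nu},
    )
    losses = pr.LossRecord(
        ell=np.asarray(ell, float), ell_noisy=np.asarray(ell_noisy, float)
    )
    return clean, noisy, losses


def finite_difference_gradient(params, u, y_star, x0=None, h=1e-6):
    """Central finite differences of the sequence loss — the gradient oracle."""
    def loss_of(p):
        traj = forward_clean(p, u, x0)
        return pr.sequence_loss(traj.y, y_star).L

    grads = {}
    for name in ("A", "B", "R"):
        W = getattr(params, name)
        G = np.empty_like(W)
        for i in range(W.shape[0]):
            for j in range(W.shape[1]):
                p_hi, p_lo = params.copy(), params.copy()
                getattr(p_hi, name)[i, j] += h
                getattr(p_lo, name)[i, j] -= h
                G[i, j] = (loss_of(p_hi) - loss_of(p_lo)) / (2 * h)
        grads["d" + name] = G
    return grads


def max_rel_error(analytic, numeric):
    scale = np.maximum(np.abs(numeric), 1e-8)
    return float(np.max(np.abs(analytic - numeric) / scale))


class TestNodePerturbation:
    def test_zero_loss_difference_gives_zero_update(self):
        clean, noisy, losses = make_scalar_pair([1.0], [0.5], [0.1], [0.3], [0.3])
        for fn in (pr.np_update_local, pr.np_update_global):
            upd = fn(clean, noisy, losses, pr.RuleConfig("np_local", sigma=1.0))
            assert np.all(upd.flat() == 0)

    def test_scalar_hand_example(self):
        # sigma=1, delta_ell=2, xi=0.5, u=1 -> dA = 2*0.5*1 = 1
        clean, noisy, losses = make_scalar_pair([1.0], [0.5], [0.0], [0.0], [2.0])
        upd = pr.np_update_local(clean, noisy, losses, pr.RuleConfig("np_local", sigma=1.0))
        assert upd.dA[0, 0] == pytest.approx(1.0)

    def test_T1_local_equals_global(self):
        clean, noisy, losses = make_scalar_pair([0.8], [0.3], [0.2], [0.5], [1.7],
                                                params=scalar_params(1, 0.5, 1))
        cfg = pr.RuleConfig("np_local", sigma=0.7)
        loc = pr.np_update_local(clean, noisy, losses, cfg)
        glob = pr.np_update_global(clean, noisy, losses, cfg)
        assert np.allclose(loc.flat(), glob.flat())

    def test_T2_cancelling_signal_separates_variants(self):
        # delta_ell = (1, -1): global signal delta_L = 0, local is not
        clean, noisy, losses = make_scalar_pair(
            [1.0, 1.0], [0.5, 0.4], [0.0, 0.0], [0.0, 0.0], [1.0, -1.0]
        )
        cfg = pr.RuleConfig("np_local", sigma=1.0)
        assert np.all(pr.np_update_global(clean, noisy, losses, cfg).flat() == 0)
        loc = pr.np_update_local(clean, noisy, losses, cfg)
        assert loc.dA[0, 0] == pytest.approx(0.5 - 0.4)

    def test_requires_node_noise(self, small_instance, rng):
        params, u, y_star = small_instance
        clean = forward_clean(params, u)
        noisy = pr.forward_noisy_weight(params, u, sigma=0.1, rng=rng)
        losses = loss_record(clean, noisy, y_star)
        with pytest.raises(ValueError, match="node-noise"):
            pr.np_update_local(clean, noisy, losses, pr.RuleConfig("np_local"))

    def test_as_printed_convention_swaps_pairings(self, rng):
        # square net so the literal pairing is shape-consistent
        params = pr.init_params(3, 3, 3, rng=rng)
        u = rng.normal(size=(4, 3))
        y_star = rng.normal(size=(4, 3))
        clean = forward_clean(params, u)
        noisy = pr.forward_noisy_node(params, u, sigma=0.1, rng=rng)
        losses = loss_record(clean, noisy, y_star)
        cor = pr.np_update_local(clean, noisy, losses, pr.RuleConfig("np_local", sigma=0.1))
        lit = pr.np_update_local(
            clean, noisy, losses,
            pr.RuleConfig("np_local", sigma=0.1, presynaptic_convention="as_printed"),
        )
        w = losses.delta_ell / 0.1**2
        xi, nu = noisy.node_noise["xi"], noisy.node_noise["nu"]
        assert np.allclose(cor.dA, (xi * w[:, None]).T @ u)
        assert np.allclose(lit.dA, (xi * w[:, None]).T @ clean.x)
        assert np.allclose(lit.dB, (nu * w[:, None]).T @ u)
        assert np.allclose(cor.dR, lit.dR)


class TestActivityBasedNP:
    def test_identical_passes_give_zero_update(self, small_instance):
        params, u, y_star = small_instance
        clean = forward_clean(params, u)
        noisy = NoisyTrajectory(
            u=u, alpha=clean.alpha.copy(), x=clean.x.copy(),
            beta=clean.beta.copy(), y=clean.y.copy(),
            node_noise={"xi": np.zeros_like(clean.alpha),
                        "nu": np.zeros_like(clean.beta)},
        )
        losses = loss_record(clean, noisy, y_star)
        upd = pr.anp_update(clean, noisy, losses, pr.RuleConfig("anp"))
        assert np.all(upd.flat() == 0)

    def test_scalar_hand_example(self):
        # N=2, delta_ell=0.1, d_alpha=0.5, d_beta=0, u=1 -> dA = 2*0.1*(0.5/0.25) = 0.4
        clean, noisy, losses = make_scalar_pair([1.0], [0.5], [0.0], [0.1], [0.2])
        upd = pr.anp_update(clean, noisy, losses, pr.RuleConfig("anp", N=2))
        assert upd.dA[0, 0] == pytest.approx(0.4)
        assert upd.dB[0, 0] == pytest.approx(0.0)

    def test_literal_loss_signal_flag(self):
        clean, noisy, losses = make_scalar_pair([1.0], [0.5], [0.0], [0.1], [0.2])
        upd = pr.anp_update(
            clean, noisy, losses,
            pr.RuleConfig("anp", N=2, anp_uses_delta_loss=False),
        )
        # literal ell_1 = 0.1 equals delta_ell here by construction
        assert upd.dA[0, 0] == pytest.approx(0.4)
        _, _, losses2 = make_scalar_pair([1.0], [0.5], [0.0], [0.4], [0.5])
        upd2 = pr.anp_update(clean, noisy, losses2,
                             pr.RuleConfig("anp", N=2, anp_uses_delta_loss=False))
        assert upd2.dA[0, 0] == pytest.approx(1.6)  # uses ell=0.4, not delta=0.1


class TestWeightPerturbation:
    def _pair(self, delta_ell, xi):
        params = scalar_params(0, 0, 0)
        T = len(delta_ell)
        u = np.zeros((T, 1))
        clean = forward_clean(params, u)
        noise = {
            "xi": np.asarray(xi, float).reshape(T, 1, 1),
            "nu": np.zeros((T, 1, 1)),
            "zeta": np.zeros((T, 1, 1)),
        }
        noisy = NoisyTrajectory(
            u=u, alpha=clean.alpha.copy(), x=clean.x.copy(),
            beta=clean.beta.copy(), y=clean.y.copy(), weight_noise=noise,
        )
        losses = pr.LossRecord(ell=np.zeros(T),
                               ell_noisy=np.asarray(delta_ell, float))
        return clean, noisy, losses

    def test_zero_signal_gives_zero(self):
        clean, noisy, losses = self._pair([0.0, 0.0], [0.1, -0.1])
        upd = pr.wp_update_local(clean, noisy, losses, pr.RuleConfig("wp_local", sigma=1.0))
        assert np.all(upd.flat() == 0)

    def test_scalar_hand_example(self):
        # delta_ell=(1,2), xi=(0.1,-0.1) -> dA = 1*0.1 + 2*(-0.1) = -0.1
        clean, noisy, losses = self._pair([1.0, 2.0], [0.1, -0.1])
        upd = pr.wp_update_local(clean, noisy, losses, pr.RuleConfig("wp_local", sigma=1.0))
        assert upd.dA[0, 0] == pytest.approx(-0.1)

    def test_T1_local_equals_global(self):
        clean, noisy, losses = self._pair([1.3], [0.2])
        cfg = pr.RuleConfig("wp_local", sigma=0.5)
        loc = pr.wp_update_local(clean, noisy, losses, cfg)
        glob = pr.wp_update_global(clean, noisy, losses, cfg)
        assert np.allclose(loc.flat(), glob.flat())

    def test_cancelling_signal_separates_variants(self):
        clean, noisy, losses = self._pair([1.0, -1.0], [0.1, 0.3])
        cfg = pr.RuleConfig("wp_local", sigma=1.0)
        assert np.all(pr.wp_update_global(clean, noisy, losses, cfg).flat() == 0)
        loc = pr.wp_update_local(clean, noisy, losses, cfg)
        assert loc.dA[0, 0] == pytest.approx(0.1 - 0.3)

    def test_requires_weight_noise(self, small_instance, rng):
        params, u, y_star = small_instance
        clean = forward_clean(params, u)
        noisy = pr.forward_noisy_node(params, u, sigma=0.1, rng=rng)
        losses = loss_record(clean, noisy, y_star)
        with pytest.raises(ValueError, match="weight-noise"):
            pr.wp_update_local(clean, noisy, losses, pr.RuleConfig("wp_local"))


class TestBPTTGradient:
    def test_zero_residual_zero_gradient(self, small_params, rng):
        u = rng.normal(size=(4, 2))
        traj = forward_clean(small_params, u)
        g = pr.bptt_gradient(small_params, u, traj.y)
        assert np.all(g.flat() == 0)

    def test_T1_no_recurrence_closed_form(self, rng):
        params = pr.init_params(2, 3, 2, rng=rng)
        params.R = np.zeros_like(params.R)
        u = rng.normal(size=(1, 2))
        y_star = rng.normal(size=(1, 2))
        traj = forward_clean(params, u)
        g = pr.bptt_gradient(params, u, y_star)
        expected_dB = 2.0 * np.outer(traj.y[0] - y_star[0], traj.x[0])
        assert np.allclose(g.dB, expected_dB)

    @pytest.mark.parametrize("decorrelate", [False, True])
    def test_matches_finite_differences(self, decorrelate, rng):
        params = pr.init_params(2, 3, 2, decorrelate=decorrelate, rng=rng)
        if decorrelate:
            params.D = params.D + 0.1 * rng.normal(size=params.D.shape)
        u = rng.normal(size=(5, 2))
        y_star = rng.normal(size=(5, 2))
        g = pr.bptt_gradient(params, u, y_star)
        fd = finite_difference_gradient(params, u, y_star)
        for name in ("dA", "dB", "dR"):
            assert max_rel_error(getattr(g, name), fd[name]) < 1e-5


class TestDecorrelationRule:
    def test_axis_aligned_sample_is_fixed_point(self):
        dD = decorrelation_update(np.array([[1.0, 0.0]]), np.eye(2))
        assert np.all(dD == 0)

    def test_correlated_sample_hand_example(self):
        dD = decorrelation_update(np.array([[1.0, 1.0]]), np.eye(2))
        assert np.allclose(dD, [[0.0, 1.0], [1.0, 0.0]])

    def test_diagonal_covariance_zero_expected_update(self, rng):
        # large sample from independent channels: mean update ~ 0
        X = rng.normal(size=(200_000, 2)) * np.array([1.0, 2.0])
        dD = decorrelation_update(X, np.eye(2)) / X.shape[0]
        assert np.max(np.abs(dD)) < 0.02

    def test_iterated_updates_decorrelate_gaussian(self, rng):
        C = np.array([[1.0, 0.8], [0.8, 1.0]])
        samples = rng.normal(size=(1000, 2)) @ np.linalg.cholesky(C).T
        D = np.eye(2)
        before = pr.decorrelation_loss(samples @ D.T)
        for i in range(1000):
            xs = D @ samples[i % 1000]
            D = D - 0.01 * decorrelation_update(xs[None, :], D)
        after = pr.decorrelation_loss(samples @ D.T)
        assert after < before / 10

    def test_missing_D_rejected(self):
        with pytest.raises(ValueError):
            decorrelation_update(np.ones((3, 2)), None)


class TestApplyUpdates:
    def test_zero_rates_leave_params_unchanged(self, small_params):
        upd = pr.UpdateSet.zeros_like(small_params)
        upd.dA += 1.0
        out = pr.apply_updates(small_params, upd, eta=0.0)
        assert np.array_equal(out.A, small_params.A)

    def test_single_sgd_step(self):
        p = scalar_params(1.0, 0, 0)
        upd = pr.UpdateSet(dA=np.array([[0.5]]), dB=np.zeros((1, 1)),
                           dR=np.zeros((1, 1)))
        out = pr.apply_updates(p, upd, eta=0.1)
        assert out.A[0, 0] == pytest.approx(0.95)

    def test_adam_zero_gradient_no_motion(self, small_params):
        upd = pr.UpdateSet.zeros_like(small_params)
        state = pr.AdamState()
        out = pr.apply_updates(small_params, upd, eta=0.1, optimizer_state=state)
        assert np.array_equal(out.A, small_params.A)
        assert state.step == 1

    def test_D_updated_with_epsilon(self, rng):
        p = pr.init_params(1, 2, 1, decorrelate=True, rng=rng)
        upd = pr.UpdateSet.zeros_like(p)
        upd.dD = np.ones_like(p.D)
        out = pr.apply_updates(p, upd, eta=0.0, epsilon=0.5)
        assert np.allclose(out.D, p.D - 0.5)

    def test_negative_rate_rejected(self, small_params):
        with pytest.raises(ValueError):
            pr.apply_updates(small_params, pr.UpdateSet.zeros_like(small_params), eta=-1)


class TestStatisticalAlignment:
    """Monte-Carlo mean updates approximate the exact gradient."""

    def test_mean_updates_align_with_gradient(self, mc_tallies):
        grad = mc_tallies["grad"]
        for rule, blocks in mc_tallies["means"].items():
            for name in ("dA", "dB", "dR"):
                m, g = blocks[name].ravel(), getattr(grad, name).ravel()
                cos = m @ g / (np.linalg.norm(m) * np.linalg.norm(g))
                assert cos > 0.5, f"{rule}.{name} cosine {cos:.3f}"

    def test_anp_variance_below_np(self, mc_tallies):
        n = mc_tallies["n_draws"]
        var = {}
        for rule in ("np_local", "anp"):
            mean = np.concatenate(
                [mc_tallies["means"][rule][b].ravel() for b in ("dA", "dB", "dR")]
            )
            var[rule] = mc_tallies["sq"][rule] / n - float(np.sum(mean**2))
        assert var["anp"] < var["np_local"]

    def test_anp_aligns_at_least_as_well_as_np(self, mc_tallies):
        grad = mc_tallies["grad"].flat()
        cos = {}
        for rule in ("np_local", "anp"):
            m = np.concatenate(
                [mc_tallies["means"][rule][b].ravel() for b in ("dA", "dB", "dR")]
            )
            cos[rule] = m @ grad / (np.linalg.norm(m) * np.linalg.norm(grad))
        assert cos["anp"] >= cos["np_local"] - 0.02

    def test_sign_property(self):
        # a perturbation that strictly increases every per-step loss pushes
        # the update in the +noise direction (weights then move opposite)
        clean, noisy, losses = make_scalar_pair(
            [1.0, 1.0], [0.5, 0.2], [0.0, 0.0], [0.0, 0.0], [1.0, 2.0]
        )
        upd = pr.np_update_local(clean, noisy, losses, pr.RuleConfig("np_local", sigma=1.0))
        xi = noisy.node_noise["xi"]
        assert np.sum(upd.dA * (xi.T @ clean.u)) > 0
        p = scalar_params(1.0, 0, 0)
        after = pr.apply_updates(p, upd, eta=0.1)
        assert after.A[0, 0] < p.A[0, 0]  # moves opposite to the noise direction
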