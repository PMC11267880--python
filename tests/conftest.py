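"""Shared fixtures: small fixed network instances and Monte-Carlo tallies."""

import numpy as np
import pytest

import perturbrnn as pr
from perturbrnn.model import forward_clean, forward_noisy_node, forward_noisy_weight, loss_record


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_params(rng):
    """A 2-in / 3-hidden / 2-out network with random weights."""
    return pr.init_params(2, 3, 2, rng=rng)


@pytest.fixture
def small_instance(small_params, rng):
    """Fixed (params, inputs, targets) triple for oracle comparisons."""
    u = rng.normal(size=(3, 2))
    y_star = rng.normal(size=(3, 2))
    return small_params, u, y_star


def scalar_params(a=0.0, r=0.0, b=0.0):
    """1-unit network with hand-set scalar weights."""
    return pr.RNNParams(A=[[a]], R=[[r]], B=[[b]])


@pytest.fixture(scope="session")
def mc_tallies():
    """Monte-Carlo tallies of NP/ANP/WP updates on one fixed 3-unit, T=3
    instance at sigma=1e-3: per-rule mean update, per-rule mean squared
    entry, and the exact gradient, over 10^4 independent draws."""
    rng = np.random.default_rng(777)
    params = pr.init_params(2, 3, 2, rng=rng)
    u = rng.normal(size=(3, 2))
    y_star = rng.normal(size=(3, 2))
    sigma = 1e-3
    n_draws = 10_000
    grad = pr.bptt_gradient(params, u, y_star)
    clean = forward_clean(params, u)
    cfgs = {
        "np_local": pr.RuleConfig("np_local", sigma=sigma),
        "anp": pr.RuleConfig("anp", sigma=sigma),
        "wp_local": pr.RuleConfig("wp_local", sigma=sigma),
    }
    blocks = ("dA", "dB", "dR")
    sums = {r: {b: 0.0 for b in blocks} for r in cfgs}
    sq = {r: 0.0 for r in cfgs}
    ss = np.random.SeedSequence(202)
    node_rng, weight_rng = (np.random.default_rng(s) for s in ss.spawn(2))
    for _ in range(n_draws):
        noisy_n = forward_noisy_node(params, u, sigma=sigma, rng=node_rng)
        noisy_w = forward_noisy_weight(params, u, sigma=sigma, rng=weight_rng)
        lr_n = loss_record(clean, noisy_n, y_star)
        lr_w = loss_record(clean, noisy_w, y_star)
        ups = {
            "np_local": pr.np_update_local(clean, noisy_n, lr_n, cfgs["np_local"]),
            "anp": pr.anp_update(clean, noisy_n, lr_n, cfgs["anp"]),
            "wp_local": pr.wp_update_local(clean, noisy_w, lr_w, cfgs["wp_local"]),
        }
        for name, upd in ups.items():
            for b in blocks:
                sums[name][b] = sums[name][b] + getattr(upd, b)
            sq[name] += float(np.sum(upd.flat() ** 2))
    means = {r: {b: sums[r][b] / n_draws for b in blocks} for r in cfgs}
    return {
        "params": params, "u": u, "y_star": y_star, "sigma": sigma,
        "n_draws": n_draws, "grad": grad, "means": means, "sq": sq,
    }


@pytest.fixture(scope="session")
def mackey_glass_runs():
    """Scaled-down Mackey-Glass protocol: ANP and local NP, five seeds each.

    Five chronological 500-step windows (four train, one test), 64 hidden
    units, 200 epochs, default sigma and eta.
    """
    ds = pr.gen_mackey_glass(n_steps=500, n_sequences=5, seed=0)
    train, test = pr.train_test_split(ds, 0.8)
    train, test = pr.standardize(train, test)
    out = {}
    for rule in ("anp", "np_local"):
        histories = []
        for seed in (1, 2, 3, 4, 5):
            cfg = pr.RunConfig(
                train_data=train, test_data=test, hidden_dim=64,
                rule=pr.RuleConfig(rule), eta=1e-4, epochs=200, seeds=[seed],
            )
            histories.append(pr.train_model(cfg, seed=seed))
        out[rule] = histories
    return out
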