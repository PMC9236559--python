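"""Sampler correctness: enumeration oracles, prior-only chains, diagnostics."""

import numpy as np
import pytest
from scipy.special import expit

from notreached.model_core import Dataset, QMatrix
from notreached.sampler import (
    FitConfig,
    PriorSpec,
    _PreparedData,
    _gate_loglik_matrices,
    adapt_proposals,
    init_state,
    psrf,
    run_chain,
    update_alpha,
)


def _alpha_full_conditional_oracle(state, dataset, i, k):
    """P(alpha_ik = 1 | everything else) by direct enumeration of the two
    candidate profiles, using only scalar model equations."""
    from notreached.model_core import response_prob

    logpóst = []
    for v in (0, 1):
        a = state.alpha[i].copy()
        a[k] = v
        ll = 0.0
        for j in range(dataset.J):
            if dataset.D[i, j] == 1:
                continue
            p = response_prob(a, dataset.Q.entries[j],
                              state.beta[j], state.delta[j])
            ll += np.log(p if dataset.Y[i, j] == 1 else 1 - p)
        prior = expit(state.theta_h[i] * state.gamma[k] - state.lam[k])
        ll += np.log(prior if v == 1 else 1 - prior)
        logpóst.append(ll)
    m = max(logpóst)
    w = np.exp(np.array(logpóst) - m)
    return w[1] / w.sum()


class TestInitState:
    def test_protocol_values(self, toy_dataset):
        cfg = FitConfig(chain_length=10, burn_in=5)
        state = init_state(toy_dataset, cfg, np.random.default_rng(0))
        assert (state.beta == 0).all() and (state.delta == 0).all()
        assert (state.gamma == 1).all() and (state.lam == 0).all()
        assert state.eta0 == 0 and state.eta1 == 0
        assert state.sigma_hd == 0 and state.sigma_d2 == 1
        assert (state.Sigma_I == np.eye(2)).all()
        assert set(np.unique(state.alpha)) <= {0, 1}

    def test_seeded_alpha_init(self, toy_dataset):
        cfg = FitConfig(chain_length=10, burn_in=5)
        a = init_state(toy_dataset, cfg, np.random.default_rng(3)).alpha
        b = init_state(toy_dataset, cfg, np.random.default_rng(3)).alpha
        assert (a == b).all()


class TestAlphaGibbs:
    def test_full_conditional_matches_enumeration(self, toy_dataset):
        """The vectorized Gibbs probabilities equal brute-force enumeration
        to 1e-12 on a toy dataset."""
        cfg = FitConfig(chain_length=10, burn_in=5)
        rng = np.random.default_rng(8)
        state = init_state(toy_dataset, cfg, rng)
        state.beta = np.array([-1.0, 0.5, -2.0])
        state.delta = np.array([2.5, 1.5, 4.0])
        state.theta_h = np.array([0.4, -1.0, 0.2])
        state.gamma = np.array([1.5, 1.2])
        state.lam = np.array([-0.5, 0.5])
        prep = _PreparedData(toy_dataset, "sequential")
        gate = _gate_loglik_matrices(prep, state.beta, state.delta)
        # reproduce the sweep's internal probability for attribute k given
        # the current alpha, then compare against the oracle person by person
        for k in range(2):
            qk = prep.Q[:, k]
            cols = np.nonzero(qk)[0]
            a_k = state.alpha[:, k].astype(float)
            M_others = state.M[:, cols] - a_k[:, None] * qk[cols][None, :]
            on = M_others + 1.0 >= prep.req[cols][None, :]
            ll0 = gate[0][:, cols].sum(axis=1)
            ll1 = np.where(on, gate[1][:, cols], gate[0][:, cols]).sum(axis=1)
            p1 = expit(state.theta_h * state.gamma[k] - state.lam[k] + ll1 - ll0)
            for i in range(toy_dataset.N):
                oracle = _alpha_full_conditional_oracle(state, toy_dataset, i, k)
                assert p1[i] == pytest.approx(oracle, abs=1e-12)

    def test_no_observed_items_reduces_to_prior(self, tiny_q):
        ds = Dataset(Y=np.full((400, 3), np.nan), D=np.ones((400, 3), int), Q=tiny_q)
        cfg = FitConfig(chain_length=10, burn_in=5)
        rng = np.random.default_rng(5)
        state = init_state(ds, cfg, rng)
        state.theta_h = np.zeros(400)
        state.gamma = np.array([1.5, 1.5])
        state.lam = np.array([-1.0, 1.0])
        prep = _PreparedData(ds, "sequential")
        draws = np.zeros((400, 2))
        for _ in range(200):
            update_alpha(state, prep, rng)
            draws += state.alpha
        rates = draws.mean(axis=0) / 200
        assert rates[0] == pytest.approx(expit(1.0), abs=0.03)
        assert rates[1] == pytest.approx(expit(-1.0), abs=0.03)

    def test_perfect_items_force_profile(self, tiny_q):
        """Near-deterministic items pin alpha to the unique consistent profile."""
        Y = np.array([[1.0, 0.0, 0.0]])
        ds = Dataset(Y=Y, D=np.zeros((1, 3), int), Q=tiny_q)
        cfg = FitConfig(chain_length=10, burn_in=5)
        rng = np.random.default_rng(0)
        state = init_state(ds, cfg, rng)
        state.beta = np.full(3, -20.0)   # g ~ 0
        state.delta = np.full(3, 40.0)   # s ~ 0
        prep = _PreparedData(ds, "sequential")
        for _ in range(20):
            update_alpha(state, prep, rng)
            assert (state.alpha[0] == [1, 0]).all()


@pytest.fixture(scope="module")
def prior_draws():
    Q = QMatrix(np.eye(3, dtype=int))
    ds = Dataset(Y=np.zeros((0, 3)), D=np.zeros((0, 3), int), Q=Q)
    cfg = FitConfig(model="mar", chain_length=6000, burn_in=1000,
                    n_chains=1, seed=13)
    return run_chain(ds, cfg)[0], cfg


class TestPriorOnlyChains:
    """An empty dataset turns every full conditional into its prior."""

    def test_eta_prior_moments(self, prior_draws):
        d, cfg = prior_draws
        b = cfg.burn_in
        assert d.eta0[b:].mean() == pytest.approx(0.0, abs=0.15)
        assert d.eta0[b:].var() == pytest.approx(2.0, rel=0.25)
        assert d.eta1[b:].var() == pytest.approx(2.0, rel=0.25)

    def test_structure_prior_moments(self, prior_draws):
        d, cfg = prior_draws
        b = cfg.burn_in
        assert d.lam[b:].mean() == pytest.approx(0.0, abs=0.2)
        assert d.lam[b:].var() == pytest.approx(4.0, rel=0.25)
        # gamma ~ half-normal with sigma = 2: mean 2 sqrt(2/pi)
        assert d.gamma[b:].mean() == pytest.approx(2 * np.sqrt(2 / np.pi), rel=0.1)
        assert (d.gamma > 0).all()

    def test_hyper_prior_moments(self, prior_draws):
        d, cfg = prior_draws
        b = cfg.burn_in
        assert d.mu_beta[b:].mean() == pytest.approx(-2.197, abs=0.25)
        assert d.mu_delta[b:].mean() == pytest.approx(4.394, abs=0.3)
        assert (d.mu_delta > 0).all()
        # sigma_d2 prior: inverse-gamma shape 2, scale 1/2 -> mean 1/2
        assert d.sigma_d2[b:].mean() == pytest.approx(0.5, rel=0.3)
        # inverse-Wishart(I, df 4) marginal mean of diagonals is 1; heavy
        # tails make the Monte-Carlo average noisy, hence the wide band
        assert 0.4 < d.sigma_b2[b:].mean() < 2.5

    def test_mar_keeps_covariance_at_zero(self, prior_draws):
        d, _ = prior_draws
        assert (d.sigma_hd == 0).all()


class TestConstraintAudit:
    def test_constraints_hold_at_every_iteration(self, study1_fit):
        est, _, _ = study1_fit
        d = est.chains_[0]
        assert (d.gamma > 0).all()
        assert (d.mu_delta > 0).all()
        assert (np.abs(d.sigma_hd) < 1).all()
        assert (d.sigma_hd**2 < d.sigma_d2).all()
        assert (d.sigma_b2 > 0).all() and (d.sigma_d2_item > 0).all()
        assert (d.sigma_b2 * d.sigma_d2_item > d.sigma_bd**2).all()

    def test_acceptance_rates_in_band_after_adaptation(self, study1_fit):
        est, _, _ = study1_fit
        for block, rate in est.acceptance_.items():
            assert 0.15 < rate < 0.55, (block, rate)


class TestAdaptation:
    def test_adaptation_directions(self):
        scales = {"a": 1.0, "b": 1.0, "c": 1.0}
        counters = {"a": 90.0, "b": 5.0, "c": 30.0}
        adapt_proposals(counters, scales, window=100)
        assert scales["a"] > 1.0 and scales["b"] < 1.0 and scales["c"] == 1.0
        assert all(v == 0.0 for v in counters.values())


class TestDeterminism:
    def test_fixed_seed_bit_identical(self, tiny_q):
        rngd = np.random.default_rng(0)
        Y = (rngd.random((30, 3)) < 0.5).astype(float)
        ds = Dataset(Y=Y, D=np.zeros((30, 3), int), Q=tiny_q)
        cfg = FitConfig(chain_length=50, burn_in=10, n_chains=1, seed=21)
        a = run_chain(ds, cfg)[0]
        b = run_chain(ds, cfg)[0]
        assert (a.beta == b.beta).all()
        assert (a.alpha_mean == b.alpha_mean).all()

    def test_single_person_runs(self, tiny_q):
        ds = Dataset(Y=np.array([[1.0, np.nan, np.nan]]),
                     D=np.array([[0, 1, 1]]), Q=tiny_q)
        cfg = FitConfig(chain_length=50, burn_in=10, n_chains=1, seed=2)
        d = run_chain(ds, cfg)[0]
        assert np.isfinite(d.beta).all()


class TestPsrf:
    def test_identical_chains_give_one(self):
        # B = 0, so the estimator reduces to sqrt((n-1)/n) ~ 1
        x = np.sin(np.arange(500.0))
        assert psrf(np.stack([x, x])) == pytest.approx(np.sqrt(499 / 500), abs=1e-12)
        assert psrf(np.stack([x, x])) == pytest.approx(1.0, abs=2e-3)

    def test_separated_chains_flagged(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 2000)
        b = rng.normal(5, 1, 2000)
        # closed form: W = 1, B/n = var of means -> psrf ~ sqrt(1 + 12.5)
        assert psrf(np.stack([a, b])) > 3.0

    def test_iid_chains_near_one(self):
        rng = np.random.default_rng(4)
        chains = rng.normal(0, 1, (2, 5000))
        assert psrf(chains) < 1.05

    def test_needs_two_sequences(self):
        with pytest.raises(ValueError):
            psrf(np.zeros((1, 100)))

    def test_agrees_with_arviz_on_well_mixed_chains(self):
        az = pytest.importorskip("arviz")
        rng = np.random.default_rng(9)
        chains = rng.normal(0, 1, (2, 4000))
        ours = psrf(chains)
        theirs = float(az.rhat(az.convert_to_dataset(chains[..., None]))["x"].values[0])
        assert ours == pytest.approx(theirs, abs=0.05)
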