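import itertools

import numpy as np
import pytest
from scipy.special import logsumexp

from batseg import (
    HmmInit,
    forward_loglik,
    generate_trip,
    hmm_decode,
    hmm_fit,
    hmm_init,
    hmm_pseudo_residuals,
    hmm_subsampling_experiment,
    simulate_hmm,
)
from batseg.hmm import _emission_logprobs, _stationary, _viterbi
from batseg.simulate import SimConfig

# two-state truth used across recovery tests: short-step/uniform-turn
# foraging vs long-step/concentrated-turn commuting
TRUE_MEANS = (46.7, 83.6)
TRUE_SDS = (26.9, 21.1)
TRUE_KAPPAS = (0.23, 11.01)
TRUE_TRANS = np.array([[0.961, 0.039], [0.072, 0.928]])


def brute_force_loglik(logB, trans, init):
    """Sum the path likelihood over all K^T state paths."""
    T, K = logB.shape
    log_trans = np.log(trans)
    log_init = np.log(init)
    terms = []
    for path in itertools.product(range(K), repeat=T):
        ll = log_init[path[0]] + logB[0, path[0]]
        for t in range(1, T):
            ll += log_trans[path[t - 1], path[t]] + logB[t, path[t]]
        terms.append(ll)
    return logsumexp(terms)


class TestForward:
    @pytest.mark.parametrize("T,K", [(1, 2), (5, 2), (8, 3), (10, 2)])
    def test_equals_brute_force_path_sum(self, T, K, rng):
        logB = rng.normal(0, 2, (T, K))
        trans = rng.dirichlet(np.ones(K), size=K)
        init = rng.dirichlet(np.ones(K))
        got = forward_loglik(logB, trans, init)
        want = brute_force_loglik(logB, trans, init)
        assert got == pytest.approx(want, abs=1e-10)


class TestInit:
    def test_bimodal_steps_bracket_truth(self, rng):
        x = np.concatenate([rng.gamma(4, 12, 3000), rng.gamma(16, 10, 3000)])
        init = hmm_init(x, seed=0)
        assert init.step_means[0] < init.step_means[1]
        assert 30 < init.step_means[0] < 70
        assert 120 < init.step_means[1] < 200

    def test_unimodal_falls_back_to_quantiles(self, rng):
        x = rng.normal(90.0, 10.0, 2000)
        with pytest.warns(UserWarning, match="unimodal"):
            init = hmm_init(x, seed=0)
        assert init.fallback_used
        q30, q70 = np.percentile(x, [30, 70])
        assert init.step_means == pytest.approx([q30, q70])

    def test_components_ordered(self):
        init = HmmInit(
            step_means=np.array([160.0, 70.0]),
            step_sds=np.array([23.0, 27.6]),
            turn_kappas=np.array([0.1, 0.1]),
        )
        assert init.step_means[0] == 70.0 and init.step_sds[0] == 27.6

    def test_needs_enough_steps(self):
        with pytest.raises(ValueError):
            hmm_init(np.arange(10.0))


@pytest.fixture(scope="module")
def fitted():
    steps, turns, states = simulate_hmm(
        TRUE_MEANS, TRUE_SDS, TRUE_KAPPAS, TRUE_TRANS, n=3000, seed=5
    )
    model = hmm_fit([(steps, turns)])
    return steps, turns, states, model


class TestFitDecode:
    def test_emission_recovery(self, fitted):
        _, _, _, model = fitted
        assert np.all(np.abs(model.step_means - TRUE_MEANS) / TRUE_MEANS < 0.10)
        assert np.all(np.abs(model.step_sds - TRUE_SDS) / TRUE_SDS < 0.25)
        assert np.all(np.abs(model.turn_kappas - TRUE_KAPPAS) / TRUE_KAPPAS < 0.25)

    def test_viterbi_accuracy(self, fitted):
        steps, turns, states, model = fitted
        seq = hmm_decode(model, [(steps, turns)])[0]
        # state 0 of the simulation is the short-step (foraging) state
        acc = np.mean((seq.labels[1:] == 1) == (states == 0))
        assert acc >= 0.90

    def test_final_loglik_not_below_initial(self, fitted):
        steps, turns, _, model = fitted
        assert np.isfinite(model.loglik)
        # likelihood of the optimizer's own starting point: mixture init
        # emissions with the default sticky transition matrix
        init = hmm_init(steps, seed=0)
        trans0 = np.array([[0.9, 0.1], [0.1, 0.9]])
        logB = _emission_logprobs(
            steps, turns, (init.step_means, init.step_sds, init.turn_kappas)
        )
        ll0 = forward_loglik(logB, trans0, _stationary(trans0))
        assert model.loglik >= ll0

    def test_loglik_invariant_to_trip_order(self):
        a = simulate_hmm(TRUE_MEANS, TRUE_SDS, TRUE_KAPPAS, TRUE_TRANS, 400, seed=1)[:2]
        b = simulate_hmm(TRUE_MEANS, TRUE_SDS, TRUE_KAPPAS, TRUE_TRANS, 400, seed=2)[:2]
        m1 = hmm_fit([a, b])
        m2 = hmm_fit([b, a])
        assert m1.loglik == pytest.approx(m2.loglik, rel=1e-6)

    def test_single_state_data_flagged(self, rng):
        steps = rng.gamma(9.0, 10.0, 600)
        turns = rng.vonmises(0.0, 5.0, 600)
        with pytest.warns(UserWarning):
            hmm_fit([(steps, turns)])

    def test_overwhelming_emissions_give_constant_path(self):
        logB = np.tile([0.0, -50.0], (20, 1))
        trans = np.array([[0.5, 0.5], [0.5, 0.5]])
        path = _viterbi(logB, trans, np.array([0.5, 0.5]))
        assert np.all(path == 0)

    def test_viterbi_no_worse_than_constant_paths(self, fitted):
        steps, turns, _, model = fitted
        logB = _emission_logprobs(
            steps, turns, (model.step_means, model.step_sds, model.turn_kappas)
        )
        log_trans = np.log(model.trans)
        path = _viterbi(logB, model.trans, model.init_probs)

        def path_ll(p):
            ll = np.log(model.init_probs[p[0]]) + logB[0, p[0]]
            for t in range(1, len(p)):
                ll += log_trans[p[t - 1], p[t]] + logB[t, p[t]]
            return ll

        best = path_ll(path)
        for k in range(model.n_states):
            assert best >= path_ll(np.full(len(steps), k)) - 1e-9


class TestPseudoResiduals:
    def test_jb_matches_hand_formula(self, rng):
        from scipy.stats import jarque_bera

        z = rng.normal(0, 1, 500) ** 3  # heavy-tailed
        n = len(z)
        s = np.mean((z - z.mean()) ** 3) / np.std(z) ** 3
        k = np.mean((z - z.mean()) ** 4) / np.std(z) ** 4
        want = n / 6.0 * (s**2 + (k - 3.0) ** 2 / 4.0)
        got, _ = jarque_bera(z)
        assert got == pytest.approx(want, rel=1e-10)

    def test_well_specified_model_residuals_near_normal(self):
        steps, turns, _ = simulate_hmm(
            TRUE_MEANS, TRUE_SDS, TRUE_KAPPAS, TRUE_TRANS, n=1500, seed=11
        )
        model = hmm_fit([(steps, turns)])
        res = hmm_pseudo_residuals(model, [(steps, turns)])
        stat, df, p = res["step_jb"]
        assert df == 2
        assert abs(np.mean(res["step_residuals"])) < 0.15
        assert abs(np.std(res["step_residuals"]) - 1.0) < 0.15

    def test_misspecified_steps_rejected(self, rng):
        # lognormal steps with a gamma emission model: strong JB signal
        steps = rng.lognormal(3.5, 1.2, 1500)
        turns = rng.vonmises(0.0, 1.0, 1500)
        model = hmm_fit([(steps, turns)])
        res = hmm_pseudo_residuals(model, [(steps, turns)])
        assert res["step_jb"][0] > res["turn_jb"][0]


class TestSubsampling:
    def test_slope_nonpositive_and_base_interval_first(self):
        cfg = SimConfig()
        trips, buzz = [], []
        for k in range(3):
            trip, truth = generate_trip(cfg, seed=40 + k, n_fix=500)
            trips.append(trip)
            buzz.append(truth.buzz_times)
        table, slope = hmm_subsampling_experiment(
            trips, buzz, intervals=np.array([15.0, 60.0, 120.0]), seed=0
        )
        assert table["interval_s"].iloc[0] == 15.0
        assert len(table) == 3
        assert np.isfinite(slope)
        # closed-form least squares on the returned table
        x, y = table["interval_s"], table["median_ba"]
        want = np.sum((x - x.mean()) * (y - y.mean())) / np.sum((x - x.mean()) ** 2)
        assert slope == pytest.approx(want)


def test_stationary_distribution():
    trans = np.array([[0.9, 0.1], [0.3, 0.7]])
    pi = _stationary(trans)
    assert np.allclose(pi @ trans, pi)
    assert pi.sum() == pytest.approx(1.0)
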