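import itertools

import numpy as np
import pandas as pd
import pytest

from batseg import (
    COMMUTING,
    FORAGING,
    OMITTED,
    StateSequence,
    compare_foraging_params,
    friedman_test,
    score_trip,
    summarize_segments,
    wilcoxon_paired,
)


def seq(labels, dt=15.0):
    return StateSequence(np.asarray(labels, dtype=np.int8), dt=dt, trip_id="t", method="m")


def friedman_rank_oracle(X):
    """Tie-corrected Friedman statistic from first principles."""
    n, k = X.shape
    ranks = np.empty_like(X, dtype=float)
    tie_term = 0.0
    for i in range(n):
        row = X[i]
        order = np.argsort(row)
        r = np.empty(k)
        j = 0
        while j < k:
            m = j
            while m + 1 < k and row[order[m + 1]] == row[order[j]]:
                m += 1
            r[order[j : m + 1]] = (j + m) / 2.0 + 1.0
            t = m - j + 1
            tie_term += t**3 - t
            j = m + 1
        ranks[i] = r
    Rj = ranks.sum(axis=0)
    chi = 12.0 * np.sum(Rj**2) / (n * k * (k + 1)) - 3.0 * n * (k + 1)
    correction = 1.0 - tie_term / (n * k * (k**2 - 1))
    return chi / correction


def wilcoxon_exact_oracle(d):
    """Two-sided exact signed-rank p by enumerating all 2^n sign patterns."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    n = len(d)
    ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
    v_obs = float(np.sum(ranks[d > 0]))
    vs = []
    for signs in itertools.product((0, 1), repeat=n):
        vs.append(float(np.sum(ranks[np.array(signs, bool)])))
    vs = np.array(vs)
    mean_v = n * (n + 1) / 4.0
    # two-sided: mass at least as extreme (as far from the mean) as observed
    p = np.mean(np.abs(vs - mean_v) >= abs(v_obs - mean_v) - 1e-12)
    return min(1.0, p)


class TestScoreTrip:
    def test_perfect_separation_is_100(self):
        labels = seq([FORAGING] * 4 + [COMMUTING] * 6)
        r = score_trip(labels, buzz_fixes={0, 1, 2, 3})
        assert (r.tpr, r.tnr) == (1.0, 1.0)
        assert r.balanced_accuracy == 1.0

    def test_all_foraging_degenerate_classifier(self):
        labels = seq([FORAGING] * 10)
        r = score_trip(labels, buzz_fixes={2, 5})
        assert r.tpr == 1.0 and r.tnr == 0.0 and r.balanced_accuracy == 0.5

    def test_random_labels_average_half(self, rng):
        n = 200
        buzz = set(rng.choice(n, size=25, replace=False).tolist())
        bas = []
        for _ in range(2000):
            labels = seq(rng.integers(0, 2, n))
            bas.append(score_trip(labels, buzz).balanced_accuracy)
        assert np.mean(bas) == pytest.approx(0.5, abs=0.01)

    def test_omitted_excluded_from_both_denominators(self):
        labels = seq([OMITTED, FORAGING, COMMUTING, OMITTED])
        r = score_trip(labels, buzz_fixes={0, 1})
        assert r.n_buzz_fixes == 1 and r.n_nonbuzz_fixes == 1
        assert r.balanced_accuracy == 1.0
        assert r.omitted == 2

    def test_per_buzz_weighting(self):
        # fix 0 (foraging) has 3 buzzes, fix 2 (commuting) has 1
        labels = seq([FORAGING, COMMUTING, COMMUTING])
        counts = {0: 3, 2: 1}
        r_once = score_trip(labels, {0, 2})
        r_weighted = score_trip(labels, {0, 2}, buzz_counts=counts)
        assert r_once.tpr == 0.5
        assert r_weighted.tpr == pytest.approx(3 / 4)

    def test_no_buzz_fixes_flagged(self):
        with pytest.raises(ValueError, match="TPR undefined"):
            score_trip(seq([FORAGING, COMMUTING]), buzz_fixes=set())


class TestSummarizeSegments:
    def test_hand_counted_runs(self):
        F, C = FORAGING, COMMUTING
        s = summarize_segments(seq([F, F, F, C, C, F, F]))
        assert s.n_segments == 2
        assert s.percent_foraging == pytest.approx(100 * 5 / 7)
        assert s.mean_segment_duration == pytest.approx((45.0 + 30.0) / 2)

    def test_all_commuting(self):
        s = summarize_segments(seq([COMMUTING] * 5))
        assert s.n_segments == 0 and s.percent_foraging == 0.0

    def test_omitted_ends_do_not_break_segments(self):
        F, C, O = FORAGING, COMMUTING, OMITTED
        s = summarize_segments(seq([O, F, F, O, F, C, O]))
        # the interior omitted point bridges one foraging run of 3
        assert s.n_segments == 1
        assert s.mean_segment_duration == pytest.approx(3 * 15.0)


class TestFriedman:
    def test_identical_columns_no_signal(self):
        X = np.tile([[0.5], [0.6], [0.7]], (1, 4))
        chi2, df, p = friedman_test(X)
        assert chi2 == 0.0 and p == 1.0 and df == 3

    def test_df_for_five_methods(self, rng):
        X = rng.uniform(size=(10, 5))
        _, df, _ = friedman_test(X)
        assert df == 4

    @pytest.mark.parametrize("trial", range(5))
    def test_matches_rank_formula_oracle(self, trial, rng):
        X = np.round(rng.uniform(size=(8, 4)), 1)  # rounding induces ties
        chi2, _, _ = friedman_test(X)
        assert chi2 == pytest.approx(friedman_rank_oracle(X), rel=1e-10)

    def test_uniformly_best_method_detected(self, rng):
        X = rng.uniform(size=(10, 3))
        X[:, 0] += 2.0
        chi2, df, p = friedman_test(X)
        assert chi2 == pytest.approx(friedman_rank_oracle(X), rel=1e-10)
        assert p < 0.01

    def test_missing_cells_rejected(self):
        X = np.array([[1.0, 2.0], [np.nan, 1.0]])
        with pytest.raises(ValueError, match="missing"):
            friedman_test(X)


class TestWilcoxon:
    def test_equal_samples_p1(self):
        x = np.arange(5.0)
        V, p_raw, p_adj = wilcoxon_paired(x, x)
        assert p_raw == 1.0 and p_adj == 1.0

    def test_five_positive_differences_exact(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = x - np.array([0.1, 0.2, 0.3, 0.4, 0.5])
        _, p_raw, _ = wilcoxon_paired(x, y)
        assert p_raw == pytest.approx(2 / 32)  # two-sided 1/16

    @pytest.mark.parametrize("n", [6, 8, 12])
    def test_matches_sign_enumeration_oracle(self, n, rng):
        d = rng.normal(0.3, 1.0, n)
        d = np.where(np.abs(d) < 1e-6, 0.1, d)
        _, p_raw, _ = wilcoxon_paired(d, np.zeros(n))
        assert p_raw == pytest.approx(wilcoxon_exact_oracle(d), rel=1e-9)

    def test_bonferroni_adjustment_caps_at_one(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.5])
        y = x - 1.0
        _, p_raw, p_adj = wilcoxon_paired(x, y, m_comparisons=4)
        assert p_adj == min(1.0, 4 * p_raw)
        _, _, p_cap = wilcoxon_paired(x, y, m_comparisons=1000)
        assert p_cap == 1.0

    def test_exact_pmf_sums_to_one(self):
        # the enumeration oracle's null distribution is a proper pmf
        n = 8
        ranks = np.arange(1, n + 1, dtype=float)
        vs = [
            np.sum(ranks[np.array(signs, bool)])
            for signs in itertools.product((0, 1), repeat=n)
        ]
        values, counts = np.unique(vs, return_counts=True)
        assert np.sum(counts / 2.0**n) == pytest.approx(1.0)


class TestCompareForagingParams:
    def test_identical_params_p1(self):
        trips = [f"t{i}" for i in range(6)]
        bp = pd.DataFrame({"trip_id": trips, "speed": np.linspace(3, 4, 6),
                           "turn": np.linspace(60, 90, 6)})
        rows = []
        for t, sp, tu in zip(trips, bp["speed"], bp["turn"]):
            rows.append({"trip_id": t, "method": "HMM", "state": "foraging",
                         "speed": sp, "turn": tu})
            rows.append({"trip_id": t, "method": "HMM", "state": "commuting",
                         "speed": 5.3, "turn": 20.0})
        table = compare_foraging_params(bp, pd.DataFrame(rows))
        hmm = table[table["method"] == "HMM"].iloc[0]
        assert hmm["p_speed_vs_buzz"] == 1.0 and hmm["p_turn_vs_buzz"] == 1.0
        assert table.iloc[-1]["method"] == "Buzz"

    def test_buzz_speed_tracks_true_foraging_speed(self, sim_cfg):
        # buzzes are emitted while foraging, so buzz-fix speeds sit near
        # the configured foraging speed
        from batseg import BuzzEvent, assign_buzzes_to_fixes, buzz_positive_fixes
        from batseg import compute_steps, generate_trip
        from batseg.evaluate import buzz_movement_params

        speeds = []
        for k in range(5):
            trip, truth = generate_trip(sim_cfg, seed=70 + k, n_fix=500)
            ev = [BuzzEvent(time=float(t), n_calls=3) for t in truth.buzz_times]
            fixes = buzz_positive_fixes(assign_buzzes_to_fixes(ev, trip))
            sp, _ = buzz_movement_params(compute_steps(trip), fixes)
            speeds.append(sp)
        assert np.mean(speeds) == pytest.approx(sim_cfg.forage_speed_mean, abs=0.3)
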