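"""First-principles survival machinery checked against hand computations,
brute-force likelihood search, known identities, and lifelines."""
import numpy as np
import pandas as pd
import pytest

from irscore import (
    GroupAssignment,
    dichotomize_by_median,
    fit_cox_binary,
    k_group_test,
    km_estimate,
    logrank_test,
    rank_correlation,
    two_group_test,
)
from conftest import make_survival


def make_groups(labels, ids=None) -> GroupAssignment:
    ids = ids or [f"s{i}" for i in range(len(labels))]
    g = pd.Series(["high" if x else "low" for x in labels], index=ids)
    return GroupAssignment(group=g, threshold=0.0)


# ---------------------------------------------------------------------------
# dichotomization

class TestDichotomize:
    def test_even_split(self):
        v = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        g = dichotomize_by_median(v)
        assert g.threshold == 2.5
        assert set(g.group[g.group == "high"].index) == {"c", "d"}

    def test_ties_at_median_go_low(self):
        v = pd.Series([1.0, 2.0, 2.0, 3.0], index=list("abcd"))
        g = dichotomize_by_median(v)
        assert g.group.tolist() == ["low", "low", "low", "high"]

    def test_constant_vector_is_error(self):
        with pytest.raises(ValueError):
            dichotomize_by_median(pd.Series([5.0] * 6))


# ---------------------------------------------------------------------------
# Cox

def bruteforce_partial_loglik(beta, time, event, x):
    """Independent tie-free partial likelihood, direct from the definition."""
    ll = 0.0
    for i in range(len(time)):
        if event[i] == 1:
            risk = [j for j in range(len(time)) if time[j] >= time[i]]
            ll += beta * x[i] - np.log(sum(np.exp(beta * x[j]) for j in risk))
    return ll


class TestCox:
    toy_time = [2.0, 5.0, 7.0, 9.0, 12.0, 14.0, 17.0, 20.0]
    toy_event = [1, 1, 0, 1, 1, 0, 1, 1]
    toy_x = [1, 0, 1, 1, 0, 0, 1, 0]

    def _toy(self):
        surv = make_survival(self.toy_time, self.toy_event)
        groups = make_groups(self.toy_x)
        return groups, surv

    def test_exchangeable_arms_give_null(self):
        time = [1.0, 2.0, 3.0, 4.0]
        surv = make_survival(time * 2, [1, 1, 0, 1] * 2)
        groups = make_groups([1, 1, 1, 1, 0, 0, 0, 0])
        res = fit_cox_binary(groups, surv)
        assert res.log_hr == pytest.approx(0.0, abs=1e-10)
        assert res.p == pytest.approx(1.0, abs=1e-10)

    def test_estimate_matches_dense_grid_search(self):
        groups, surv = self._toy()
        res = fit_cox_binary(groups, surv)
        # three-stage refining grid over the brute-force likelihood
        lo, hi = -5.0, 5.0
        for _ in range(6):
            grid = np.linspace(lo, hi, 401)
            ll = [bruteforce_partial_loglik(b, self.toy_time, self.toy_event,
                                            self.toy_x) for b in grid]
            best = grid[int(np.argmax(ll))]
            span = (hi - lo) / 400
            lo, hi = best - 2 * span, best + 2 * span
        assert res.log_hr == pytest.approx(best, abs=1e-6)
        assert res.converged

    def test_score_test_equals_logrank_tiefree(self, rng):
        n = 30
        time = np.sort(rng.exponential(10, size=n)) + np.arange(n) * 1e-6  # tie-free
        event = rng.integers(0, 2, size=n)
        event[:3] = 1
        x = rng.integers(0, 2, size=n)
        surv = make_survival(list(time), list(event))
        groups = make_groups(list(x))
        from irscore.survival import _cox_derivatives, _event_time_tables
        _, d, m1, n1, n0 = _event_time_tables(np.array(time), np.array(event),
                                              np.array(x))
        _, U, I = _cox_derivatives(0.0, d, m1, n1, n0, "breslow")
        chi2, _ = logrank_test(groups, surv)
        assert U**2 / I == pytest.approx(chi2, abs=1e-8)

    def test_matches_lifelines(self):
        lifelines = pytest.importorskip("lifelines")
        groups, surv = self._toy()
        res = fit_cox_binary(groups, surv, ties="efron")
        df = pd.DataFrame({"t": self.toy_time, "e": self.toy_event, "x": self.toy_x})
        cph = lifelines.CoxPHFitter().fit(df, duration_col="t", event_col="e")
        assert res.log_hr == pytest.approx(cph.params_["x"], abs=1e-6)
        assert res.se == pytest.approx(cph.standard_errors_["x"], abs=1e-6)

    def test_group_relabel_flips_sign(self):
        groups, surv = self._toy()
        flipped = make_groups([1 - v for v in self.toy_x])
        a = fit_cox_binary(groups, surv)
        b = fit_cox_binary(flipped, surv)
        assert a.log_hr == pytest.approx(-b.log_hr, abs=1e-8)
        assert a.p == pytest.approx(b.p, abs=1e-10)

    def test_monotone_likelihood_flagged_with_score_p(self):
        # all events early in arm 1, arm 0 all censored late: beta -> +inf
        surv = make_survival([1.0, 2.0, 3.0, 10.0, 11.0, 12.0],
                             [1, 1, 1, 0, 0, 0])
        groups = make_groups([1, 1, 1, 0, 0, 0])
        res = fit_cox_binary(groups, surv)
        assert not res.converged
        assert np.isinf(res.log_hr) and res.log_hr > 0
        assert 0 <= res.p <= 1

    def test_no_events_is_error(self):
        surv = make_survival([1.0, 2.0, 3.0, 4.0], [0, 0, 0, 0])
        with pytest.raises(ValueError, match="no events"):
            fit_cox_binary(make_groups([1, 0, 1, 0]), surv)


# ---------------------------------------------------------------------------
# log-rank

class TestLogrank:
    def test_identical_groups_null(self):
        surv = make_survival([1.0, 2.0, 3.0] * 2, [1, 1, 0] * 2)
        chi2, p = logrank_test(make_groups([1, 1, 1, 0, 0, 0]), surv)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_six_subject_hand_computation(self):
        # arm A: 1(e), 3(e), 5(c); arm B: 2(e), 4(e), 6(e)
        surv = make_survival([1.0, 3.0, 5.0, 2.0, 4.0, 6.0], [1, 1, 0, 1, 1, 1])
        groups = make_groups([1, 1, 1, 0, 0, 0])
        # hand-computed O-E and hypergeometric variances per event time:
        # t=1: O=1 E=3/6 V=(3/6)(3/6)(5-1... d=1 -> (nA/n)(nB/n)(n-d)/(n-1)=1/4
        # t=2: O=0 E=2/5 V=(2/5)(3/5)(3/4)... n=5 -> (2/5)(3/5)*4/4=6/25
        # t=3: O=1 E=2/4 V=(2/4)(2/4)=1/4
        # t=4: O=0 E=1/3 V=(1/3)(2/3)=2/9
        # t=6: O=0 E=0   V=0 (single subject at risk)
        O = 1 + 0 + 1 + 0 + 0
        E = 3 / 6 + 2 / 5 + 2 / 4 + 1 / 3 + 0
        V = 1 / 4 + 6 / 25 + 1 / 4 + 2 / 9 + 0
        chi2, p = logrank_test(groups, surv)
        assert chi2 == pytest.approx((O - E) ** 2 / V, abs=1e-12)
        assert 0 < p < 1

    def test_matches_lifelines(self, rng):
        lifelines = pytest.importorskip("lifelines")
        n = 50
        time = rng.exponential(10, size=n)
        event = rng.integers(0, 2, size=n)
        event[0] = 1
        x = rng.integers(0, 2, size=n)
        chi2, p = logrank_test(make_groups(list(x)), make_survival(list(time), list(event)))
        ref = lifelines.statistics.logrank_test(time[x == 1], time[x == 0],
                                                event[x == 1], event[x == 0])
        assert chi2 == pytest.approx(ref.test_statistic, abs=1e-8)
        assert p == pytest.approx(ref.p_value, abs=1e-10)

    def test_invariant_under_monotone_time_transform(self, rng):
        n = 30
        time = rng.exponential(5, size=n)
        event = rng.integers(0, 2, size=n)
        event[:2] = 1
        x = list(rng.integers(0, 2, size=n))
        a = logrank_test(make_groups(x), make_survival(list(time), list(event)))
        b = logrank_test(make_groups(x), make_survival(list(np.sqrt(time)), list(event)))
        assert a == pytest.approx(b, abs=1e-12)

    def test_zero_events_is_error(self):
        surv = make_survival([1.0, 2.0, 3.0, 4.0], [0, 0, 0, 0])
        with pytest.raises(ValueError):
            logrank_test(make_groups([1, 0, 1, 0]), surv)


# ---------------------------------------------------------------------------
# Kaplan-Meier

class TestKM:
    def test_no_censoring_closed_form(self):
        curve = km_estimate(make_survival([1.0, 2.0, 3.0], [1, 1, 1]))
        np.testing.assert_allclose(curve.survival, [1.0, 2 / 3, 1 / 3, 0.0])
        np.testing.assert_allclose(curve.times, [0.0, 1.0, 2.0, 3.0])

    def test_all_censored_flat_at_one(self):
        curve = km_estimate(make_survival([1.0, 2.0], [0, 0]))
        np.testing.assert_allclose(curve.survival, [1.0])

    def test_mixed_five_subject_hand_products(self):
        # times 1(e), 2(c), 3(e), 3(e), 4(c):
        # S(1) = 4/5; at t=3 risk set {3,3,4}, 2 events -> S = 4/5 * 1/3
        curve = km_estimate(make_survival([1.0, 2.0, 3.0, 3.0, 4.0], [1, 0, 1, 1, 0]))
        np.testing.assert_allclose(curve.survival, [1.0, 4 / 5, 4 / 15])
        np.testing.assert_allclose(curve.times, [0.0, 1.0, 3.0])
        np.testing.assert_allclose(curve.at_risk, [5, 5, 3])

    def test_random_curve_contract(self, rng):
        for _ in range(10):
            n = int(rng.integers(1, 30))
            time = rng.exponential(3, size=n)
            event = rng.integers(0, 2, size=n)
            curve = km_estimate(make_survival(list(time), list(event)))
            assert (np.diff(curve.survival) <= 1e-12).all()
            assert ((curve.survival >= -1e-12) & (curve.survival <= 1 + 1e-12)).all()
            assert curve.survival[0] == 1.0

    def test_matches_lifelines(self, rng):
        lifelines = pytest.importorskip("lifelines")
        time = rng.exponential(5, size=25)
        event = rng.integers(0, 2, size=25)
        event[0] = 1
        curve = km_estimate(make_survival(list(time), list(event)))
        kmf = lifelines.KaplanMeierFitter().fit(time, event)
        ref = kmf.survival_function_at_times(curve.times).to_numpy()
        np.testing.assert_allclose(curve.survival, ref, atol=1e-10)


# ---------------------------------------------------------------------------
# rank-based tests

class TestRankStats:
    def test_spearman_extremes_and_bruteforce(self, rng):
        x = rng.normal(size=10)
        assert rank_correlation(x, x)[0] == pytest.approx(1.0)
        assert rank_correlation(x, -x)[0] == pytest.approx(-1.0)
        y = rng.normal(size=10)
        rho, _ = rank_correlation(x, y)
        # brute-force rank formula (no ties): 1 - 6*sum d^2 / (n(n^2-1))
        import scipy.stats
        rx, ry = scipy.stats.rankdata(x), scipy.stats.rankdata(y)
        expected = 1 - 6 * np.sum((rx - ry) ** 2) / (10 * 99)
        assert rho == pytest.approx(expected, abs=1e-12)

    def test_constant_vector_is_error(self):
        with pytest.raises(ValueError):
            rank_correlation([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])

    def test_separated_groups_tiny_p(self, rng):
        a = rng.normal(0, 1, size=20)
        b = rng.normal(10, 1, size=20)
        assert two_group_test(a, b) < 1e-6

    def test_small_instance_matches_permutation_oracle(self, rng):
        from itertools import combinations
        a = [1.3, 2.7, 0.2, 4.1]
        b = [3.3, 5.9, 4.8, 2.2]
        p = two_group_test(a, b)
        pooled = np.array(a + b)
        ranks = np.argsort(np.argsort(pooled)) + 1
        obs = ranks[:4].sum()
        mu = ranks.sum() * 4 / 8
        stats = [ranks[list(c)].sum() for c in combinations(range(8), 4)]
        exact = np.mean([abs(s - mu) >= abs(obs - mu) - 1e-12 for s in stats])
        assert p == pytest.approx(exact, abs=0.01)

    def test_kruskal_groups(self, rng):
        v = np.concatenate([rng.normal(0, 1, 10), rng.normal(5, 1, 10),
                            rng.normal(10, 1, 10)])
        labels = np.repeat(["a", "b", "c"], 10)
        assert k_group_test(v, labels) < 1e-4
        with pytest.raises(ValueError):
            k_group_test([1.0, 2.0, 3.0], ["a", "a", "b"])
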