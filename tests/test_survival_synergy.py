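"""Kaplan-Meier, log-rank, Bliss independence and combination index."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from epireprog import (
    bliss_scores,
    combination_index,
    fit_median_effect,
    km_curve,
    logrank_test,
    stratify_by_expression,
)
from epireprog.survival import expression_stratified_logrank


def brute_force_logrank(times, events, groups):
    """Independent hypergeometric accumulation with explicit loops."""
    o1 = sum(1 for t, e, g in zip(times, events, groups) if e == 1 and g == 0)
    e1 = 0.0
    v = 0.0
    for t in sorted({t for t, e in zip(times, events) if e == 1}):
        at_risk = [(ti, gi) for ti, ei, gi in zip(times, events, groups) if ti >= t]
        n = len(at_risk)
        n1 = sum(1 for _, gi in at_risk if gi == 0)
        d = sum(1 for ti, ei in zip(times, events) if ti == t and ei == 1)
        e1 += d * n1 / n
        if n > 1:
            v += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if v == 0:
        return 0.0, 1.0
    chi2 = (o1 - e1) ** 2 / v
    return chi2, float(stats.chi2.sf(chi2, 1))


def random_table(rng, n=40):
    times = rng.exponential(100, size=n).round(1) + 0.1
    events = (rng.random(n) < 0.7).astype(int)
    groups = rng.integers(0, 2, size=n)
    if groups.sum() in (0, n):
        groups[0] = 1 - groups[0]
    return pd.DataFrame({"time": times, "event": events}), groups


class TestKaplanMeier:
    def test_no_events_flat_curve(self):
        tab = pd.DataFrame({"time": [5.0, 8.0, 9.0], "event": [0, 0, 0]})
        curve = km_curve(tab)
        assert np.allclose(curve["survival"], 1.0)

    def test_two_subject_hand_example(self):
        tab = pd.DataFrame({"time": [1.0, 2.0], "event": [1, 1]})
        curve = km_curve(tab)
        assert curve["survival"].tolist() == [1.0, 0.5, 0.0]

    def test_nonincreasing_and_matches_lifelines(self, rng):
        from lifelines import KaplanMeierFitter

        for _ in range(25):
            tab, _ = random_table(rng)
            curve = km_curve(tab)
            assert (np.diff(curve["survival"]) <= 1e-12).all()
            kmf = KaplanMeierFitter().fit(tab["time"], tab["event"])
            ours = curve.set_index("time")["survival"]
            theirs = kmf.survival_function_["KM_estimate"]
            for t, s in ours.items():
                assert s == pytest.approx(theirs.loc[t], abs=1e-10)


class TestLogRank:
    def test_worked_example_exact(self):
        tab = pd.DataFrame({"time": [1.0, 2.0, 3.0, 4.0], "event": [1, 1, 1, 1]})
        groups = np.array([0, 0, 1, 1])
        res = logrank_test(tab, groups)
        assert res.chi2 == pytest.approx(2.882, abs=1e-3)
        assert res.p == pytest.approx(0.0896, abs=1e-3)
        assert res.expected[0] == pytest.approx(0.5 + 1 / 3, abs=1e-9)
        assert res.variance == pytest.approx(0.25 + 2 / 9, abs=1e-9)
        # O - E sums to zero across groups
        assert (res.observed - res.expected).sum() == pytest.approx(0.0, abs=1e-9)
        chi2, p = brute_force_logrank(tab["time"], tab["event"], groups)
        assert res.chi2 == pytest.approx(chi2, abs=1e-9)

    def test_matches_brute_force_and_lifelines_on_random_tables(self, rng):
        from lifelines.statistics import logrank_test as ll_logrank

        for _ in range(100):
            tab, groups = random_table(rng, n=30)
            res = logrank_test(tab, groups)
            chi2, p = brute_force_logrank(tab["time"].values, tab["event"].values, groups)
            assert res.chi2 == pytest.approx(chi2, abs=1e-9)
            ll = ll_logrank(
                tab["time"][groups == 0],
                tab["time"][groups == 1],
                tab["event"][groups == 0],
                tab["event"][groups == 1],
            )
            assert res.chi2 == pytest.approx(ll.test_statistic, abs=1e-8)

    def test_label_swap_symmetric(self, rng):
        tab, groups = random_table(rng)
        a = logrank_test(tab, groups)
        b = logrank_test(tab, 1 - groups)
        assert a.chi2 == pytest.approx(b.chi2) and a.p == pytest.approx(b.p)

    def test_null_p_uniform_over_seeds(self):
        """Identical survival distributions: p approximately uniform
        over 200 simulated tables."""
        pvals = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            times = rng.exponential(500, size=60)
            censor = rng.uniform(100, 1500, size=60)
            tab = pd.DataFrame(
                {"time": np.minimum(times, censor), "event": (times <= censor).astype(int)}
            )
            groups = np.arange(60) % 2
            pvals.append(logrank_test(tab, groups).p)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_power_under_planted_hazard_ratio(self):
        """Hazard ratio 2 with 100 per group: power > 0.8 at 0.05."""
        hits = 0
        n_sim = 50
        for seed in range(n_sim):
            rng = np.random.default_rng(10_000 + seed)
            t0 = rng.exponential(1000, size=100)
            t1 = rng.exponential(500, size=100)
            times = np.concatenate([t0, t1])
            censor = rng.uniform(200, 3000, size=200)
            tab = pd.DataFrame(
                {"time": np.minimum(times, censor), "event": (times <= censor).astype(int)}
            )
            groups = np.repeat([0, 1], 100)
            hits += logrank_test(tab, groups).p < 0.05
        assert hits / n_sim > 0.8


class TestStratification:
    def test_median_split_with_tie_to_high(self):
        tab = pd.DataFrame(
            {"time": [1, 2, 3, 4], "event": [1, 1, 1, 1], "expression": [1.0, 2.0, 3.0, 4.0]}
        )
        labels = stratify_by_expression(tab)
        assert labels.tolist() == [1, 1, 0, 0]  # low = strictly below median 2.5
        tab["expression"] = [1.0, 2.0, 2.0, 4.0]  # median 2.0: ties go high
        assert stratify_by_expression(tab).tolist() == [1, 0, 0, 0]

    def test_constant_expression_rejected(self):
        tab = pd.DataFrame({"time": [1, 2], "event": [1, 1], "expression": [3.0, 3.0]})
        with pytest.raises(ValueError, match="identical"):
            stratify_by_expression(tab)


class TestBliss:
    def grid(self, e_a, e_b, excess=0.0):
        va = 1 - np.asarray(e_a)
        vb = 1 - np.asarray(e_b)
        v = np.outer(va, vb) - excess
        return pd.DataFrame(v, index=[0, 1, 2], columns=[0, 1, 2])

    def test_exact_independence_zero_excess(self):
        g = self.grid([0.0, 0.3, 0.6], [0.0, 0.2, 0.5])
        res = bliss_scores(g)
        assert np.abs(res.excess.values).max() < 1e-12

    def test_direct_arithmetic_example(self):
        # E_A = E_B = 0.5, E_AB = 0.9 -> expected 0.75, excess +0.15
        v = pd.DataFrame([[1.0, 0.5], [0.5, 0.1]])
        res = bliss_scores(v)
        assert res.expected.iloc[1, 1] == pytest.approx(0.75)
        assert res.excess.iloc[1, 1] == pytest.approx(0.15)

    def test_zero_effect_row_reduces_to_single_agent(self):
        g = self.grid([0.0, 0.0, 0.0], [0.0, 0.2, 0.5])
        res = bliss_scores(g)
        assert np.allclose(res.expected.values[0], res.effect_b)

    def test_planted_excess_recovered_exactly(self, small_experiment):
        res = bliss_scores(small_experiment.viability)
        planted = small_experiment.truth.synergy_excess
        assert np.abs(res.excess.values - planted.values).max() < 1e-12

    def test_clipping_warns(self):
        v = pd.DataFrame([[1.0, 0.5], [0.5, 1.2]])
        with pytest.warns(UserWarning, match="clip"):
            bliss_scores(v)


class TestCombinationIndex:
    def median_effect_fa(self, d, m, dm):
        r = (d / dm) ** m
        return r / (1 + r)

    def test_fit_recovers_planted_parameters(self):
        doses = np.array([0.1, 0.3, 1.0, 3.0, 10.0])
        for m, dm in [(1.0, 10.0), (1.7, 0.5), (0.8, 2.0)]:
            fa = self.median_effect_fa(doses, m, dm)
            fit = fit_median_effect(doses, fa)
            assert fit.m == pytest.approx(m, rel=1e-6)
            assert fit.dm == pytest.approx(dm, rel=1e-6)
            assert fit.fa_at_dose(dm) == pytest.approx(0.5, abs=1e-9)

    def test_sham_self_combination_ci_is_one(self):
        doses = np.array([0.5, 1.0, 2.0, 4.0])
        fa = self.median_effect_fa(doses, 1.3, 1.5)
        combo_dose = 2.0
        combo = pd.DataFrame(
            {
                "dose_a": [combo_dose / 2],
                "dose_b": [combo_dose / 2],
                "fa": [self.median_effect_fa(combo_dose, 1.3, 1.5)],
            }
        )
        out = combination_index(doses, fa, doses, fa, combo)
        assert out["ci"].iloc[0] == pytest.approx(1.0, abs=1e-6)

    def test_uninformative_doses_rejected(self):
        doses = np.array([1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match=">= 3"):
            fit_median_effect(doses, np.array([0.0, 0.5, 1.0]))


def test_flagship_survival_separates_groups(small_experiment):
    """Planted hazard ratio 2 for low expression yields significant
    log-rank stratification for the flagship genes."""
    for gid, tab in small_experiment.survival.items():
        res = expression_stratified_logrank(tab)
        assert res.p < 0.05
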