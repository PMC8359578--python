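"""AUC estimation and DeLong inference."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bioage import (
    auc_mann_whitney,
    delong_paired,
    delong_unpaired,
    incidence_rate,
    stratified_evaluation,
)


def brute_force_auc(scores, labels):
    """All event/non-event pairs, ties counted one half."""
    labels = np.asarray(labels, bool)
    x = np.asarray(scores, float)[labels]
    y = np.asarray(scores, float)[~labels]
    total = 0.0
    for xi in x:
        for yj in y:
            total += 1.0 if xi > yj else (0.5 if xi == yj else 0.0)
    return total / (len(x) * len(y))


def trapezoid_auc(scores, labels):
    """Area under the empirical ROC curve by the trapezoidal rule."""
    labels = np.asarray(labels, bool)
    scores = np.asarray(scores, float)
    thresholds = np.unique(scores)[::-1]
    tpr = [0.0]
    fpr = [0.0]
    for t in thresholds:
        pred = scores >= t
        tpr.append((pred & labels).sum() / labels.sum())
        fpr.append((pred & ~labels).sum() / (~labels).sum())
    return float(np.trapezoid(tpr, fpr))


class TestAUC:
    def test_four_patient_fixture(self):
        scores = np.array([3.0, 1.0, 2.0, 0.0])
        labels = np.array([1, 1, 0, 0])
        comp = auc_mann_whitney(scores, labels)
        assert comp.auc == pytest.approx(3 / 4)
        assert comp.auc == pytest.approx(brute_force_auc(scores, labels))

    def test_all_ties_give_half(self):
        comp = auc_mann_whitney(np.ones(10), np.array([1] * 4 + [0] * 6))
        assert comp.auc == pytest.approx(0.5)

    def test_perfect_separation(self):
        comp = auc_mann_whitney(np.array([5, 6, 1, 2.0]), np.array([1, 1, 0, 0]))
        assert comp.auc == pytest.approx(1.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc_mann_whitney(np.array([1.0, 2.0]), np.array([1, 1]))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_matches_brute_force_and_trapezoid(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 30))
        scores = rng.integers(0, 6, n).astype(float)  # many ties
        labels = np.zeros(n, int)
        labels[: max(1, n // 3)] = 1
        rng.shuffle(labels)
        if labels.sum() in (0, n):
            return
        comp = auc_mann_whitney(scores, labels)
        assert comp.auc == pytest.approx(brute_force_auc(scores, labels))
        assert comp.auc == pytest.approx(trapezoid_auc(scores, labels))

    def test_complementarity_on_tie_free_data(self, rng):
        scores = rng.normal(size=50)
        labels = (rng.random(50) < 0.4).astype(int)
        a = auc_mann_whitney(scores, labels).auc
        b = auc_mann_whitney(-scores, labels).auc
        assert a + b == pytest.approx(1.0)

    def test_ci_contains_auc_and_ordered(self, rng):
        scores = rng.normal(size=100) + np.r_[np.ones(30), np.zeros(70)]
        labels = np.r_[np.ones(30, int), np.zeros(70, int)]
        comp = auc_mann_whitney(scores, labels)
        lo, hi = comp.ci()
        assert 0 <= lo <= comp.auc <= hi <= 1


class TestPairedDeLong:
    def test_self_comparison(self, rng):
        scores = rng.normal(size=40)
        labels = (rng.random(40) < 0.3).astype(int)
        delta, z, p = delong_paired(scores, scores, labels)
        assert delta == 0.0 and p == 1.0

    def test_antisymmetry(self, rng):
        a = rng.normal(size=60)
        b = rng.normal(size=60)
        labels = (rng.random(60) < 0.4).astype(int)
        d1, z1, p1 = delong_paired(a, b, labels)
        d2, z2, p2 = delong_paired(b, a, labels)
        assert d1 == pytest.approx(-d2)
        assert z1 == pytest.approx(-z2)
        assert p1 == pytest.approx(p2)

    def test_p_matches_bootstrap_oracle(self):
        # 40-patient fixture: compare the analytic p with a label-stratified
        # bootstrap of the AUC difference under the observed data.
        rng = np.random.default_rng(314)
        n = 40
        latent = rng.normal(size=n)
        labels = (latent + rng.normal(0, 1, n) > 0.8).astype(int)
        if labels.sum() < 5:
            labels[:5] = 1
        a = latent + rng.normal(0, 0.8, n)
        b = latent + rng.normal(0, 1.5, n)
        delta, z, p = delong_paired(a, b, labels)

        events = np.flatnonzero(labels == 1)
        controls = np.flatnonzero(labels == 0)
        reps = 20_000
        deltas = np.empty(reps)
        for i in range(reps):
            idx = np.r_[rng.choice(events, len(events)), rng.choice(controls, len(controls))]
            la = labels[idx]
            deltas[i] = auc_mann_whitney(a[idx], la).auc - auc_mann_whitney(b[idx], la).auc
        se_boot = deltas.std(ddof=1)
        se_analytic = abs(delta / z)
        assert se_analytic == pytest.approx(se_boot, rel=0.25)
        # p implied by the bootstrap SE agrees within Monte-Carlo tolerance
        from scipy import stats

        p_boot = 2 * stats.norm.sf(abs(delta) / se_boot)
        assert p == pytest.approx(p_boot, abs=0.1)

    def test_zero_variance_identical_scores_convention(self):
        scores = np.array([1.0, 1.0, 1.0, 1.0])
        labels = np.array([1, 1, 0, 0])
        delta, z, p = delong_paired(scores, scores, labels)
        assert p == 1.0


class TestUnpairedDeLong:
    def test_null_large_n(self, rng):
        n = 2000
        s1 = rng.normal(size=n) + np.r_[np.ones(n // 2), np.zeros(n // 2)]
        s2 = rng.normal(size=n) + np.r_[np.ones(n // 2), np.zeros(n // 2)]
        labels = np.r_[np.ones(n // 2, int), np.zeros(n // 2, int)]
        delta, z, p = delong_unpaired(s1, labels, s2, labels)
        assert abs(z) < 3

    def test_extreme_alternative(self, rng):
        n = 200
        labels = np.r_[np.ones(n // 2, int), np.zeros(n // 2, int)]
        chance = rng.normal(size=n)
        separated = np.r_[np.ones(n // 2), np.zeros(n // 2)] + rng.normal(0, 0.01, n)
        delta, z, p = delong_unpaired(separated, labels, chance, labels)
        assert abs(z) > 5 and p < 1e-6

    def test_p_matches_two_sample_bootstrap_oracle(self):
        rng = np.random.default_rng(2718)
        n = 50
        labels1 = np.r_[np.ones(15, int), np.zeros(35, int)]
        labels2 = np.r_[np.ones(20, int), np.zeros(30, int)]
        s1 = rng.normal(size=n) + 0.9 * labels1
        s2 = rng.normal(size=n) + 0.3 * labels2
        delta, z, p = delong_unpaired(s1, labels1, s2, labels2)

        reps = 20_000
        deltas = np.empty(reps)
        for i in range(reps):

            def resample(s, la):
                ev = np.flatnonzero(la == 1)
                co = np.flatnonzero(la == 0)
                idx = np.r_[rng.choice(ev, len(ev)), rng.choice(co, len(co))]
                return auc_mann_whitney(s[idx], la[idx]).auc

            deltas[i] = resample(s1, labels1) - resample(s2, labels2)
        se_boot = deltas.std(ddof=1)
        se_analytic = abs(delta / z)
        assert se_analytic == pytest.approx(se_boot, rel=0.25)


class TestStratifiedEvaluation:
    def _tables(self, rng, n=4000, signal=1.2):
        ca = rng.uniform(20, 90, n)
        frail = rng.normal(size=n)
        risk = 0.04 * (ca - 55) + signal * frail
        dead = rng.random(n) < 1 / (1 + np.exp(-(risk - 4)))
        cv = dead & (rng.random(n) < 0.4)
        ages = pd.DataFrame(
            {
                "ca": ca,
                "ba": ca + 5 * frail + rng.normal(0, 2, n),
                "ba_e": ca + 6 * frail + rng.normal(0, 3, n),
                "ba_ec": ca + 4 * frail + rng.normal(0, 2, n),
            }
        )
        outcomes = pd.DataFrame(
            {"all_cause_death": dead.astype(int), "cardiovascular_death": cv.astype(int)}
        )
        return ages, outcomes

    def test_stratum_without_events_not_evaluable(self, rng):
        ages, outcomes = self._tables(rng)
        young = ages["ca"] < 40
        outcomes.loc[young, :] = 0
        with pytest.warns(UserWarning, match="not evaluable"):
            comparison = stratified_evaluation(ages, outcomes)
        young_strata = [
            s for s in comparison.strata if s.stratum == "20-39" and s.outcome == "all_cause_death"
        ]
        assert len(young_strata) == 1 and not young_strata[0].evaluable
        assert young_strata[0].auc == {}

    def test_informative_predictor_beats_chance(self, rng):
        ages, outcomes = self._tables(rng, signal=1.5)
        comparison = stratified_evaluation(ages, outcomes)
        total = next(
            s for s in comparison.strata if s.stratum == "total" and s.outcome == "all_cause_death"
        )
        d = total.auc["ba_e"]
        assert d["auc"] > 0.5 and d["ci"][0] > 0.5 and d["p"] < 0.05

    def test_total_stratum_equals_direct_pooled_auc(self, rng):
        ages, outcomes = self._tables(rng)
        comparison = stratified_evaluation(ages, outcomes)
        total = next(
            s for s in comparison.strata if s.stratum == "total" and s.outcome == "all_cause_death"
        )
        direct = auc_mann_whitney(
            ages["ba"].to_numpy(), outcomes["all_cause_death"].to_numpy()
        ).auc
        assert total.auc["ba"]["auc"] == pytest.approx(direct)

    def test_paired_and_cross_stratum_tables_populated(self, rng):
        ages, outcomes = self._tables(rng)
        comparison = stratified_evaluation(ages, outcomes)
        total = next(
            s for s in comparison.strata if s.stratum == "total" and s.outcome == "all_cause_death"
        )
        assert set(total.paired_p) == {
            "ca_vs_ba", "ca_vs_ba_e", "ca_vs_ba_ec", "ba_vs_ba_e", "ba_vs_ba_ec", "ba_e_vs_ba_ec",
        }
        assert all(0 <= p <= 1 for p in total.paired_p.values())
        assert any(k.startswith("all_cause_death:") for k in comparison.cross_stratum_p)


class TestIncidenceRate:
    def test_registry_scale_rate(self):
        # 55 events over 12,837 patients followed a mean 320.4 days.
        rate = incidence_rate(55, 12_837, 320.4)
        assert rate == pytest.approx(0.5, abs=0.05)

    def test_zero_events(self):
        assert incidence_rate(0, 1000, 365.25) == 0.0

    def test_exact_thousand_patient_years(self):
        assert incidence_rate(10, 1000, 365.25) == pytest.approx(1.0)

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            incidence_rate(1, 0, 100.0)


def test_paired_delong_type_i_error():
    """Under the null (two correlated chance predictors), rejection at
    alpha = 0.05 should be close to nominal."""
    rng = np.random.default_rng(40_000)
    n, reps = 200, 2000
    rejections = 0
    for _ in range(reps):
        latent = rng.normal(size=n)
        labels = (rng.random(n) < 0.25).astype(int)  # independent of scores
        a = latent + rng.normal(0, 1, n)
        b = latent + rng.normal(0, 1, n)
        _, _, p = delong_paired(a, b, labels)
        rejections += p < 0.05
    rate = rejections / reps
    assert 0.04 <= rate <= 0.07
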