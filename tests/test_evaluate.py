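"""ROC/AUC, DeLong comparison, cutoffs, exact CIs — against brute-force oracles."""

import numpy as np
import pytest
from scipy import stats

from pescreen.evaluate import (
    best_cutoff,
    clopper_pearson,
    compare_auc,
    dr_at_fpr,
    mann_whitney,
    roc_auc,
    summarize_group_moms,
)


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------

def auc_by_pair_counting(scores, labels):
    pos = scores[labels]
    neg = scores[~labels]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def best_cutoff_by_scan(scores, labels):
    best = (-1.0, None, None, None)
    for t in [*np.unique(scores), np.inf]:  # inf = nothing screens positive
        sens = np.mean(scores[labels] >= t)
        spec = np.mean(scores[~labels] < t)
        fpr = 1 - spec
        avg = (sens + spec) / 2
        if avg > best[0] + 1e-12 or (abs(avg - best[0]) <= 1e-12 and fpr < best[3]):
            best = (avg, t, sens, fpr)
    return best[1], best[2] * 100, best[3] * 100


def dr_at_fpr_by_scan(scores, labels, target):
    feasible = []
    for t in np.unique(scores):
        fpr = np.mean(scores[~labels] >= t)
        if fpr <= target / 100:
            dr = np.mean(scores[labels] >= t)
            feasible.append((dr, -t))
    if not feasible:
        return 0.0
    return max(feasible)[0] * 100


def _random_instance(rng, n_max=50):
    n = int(rng.integers(4, n_max))
    scores = rng.choice(rng.uniform(0, 1, max(2, n // 2)), n)  # force ties
    labels = rng.random(n) < 0.5
    if labels.all():
        labels[0] = False
    if not labels.any():
        labels[0] = True
    return scores, labels


class TestROC:
    def test_perfect_and_random_extremes(self):
        scores = np.array([0.9, 0.8, 0.2, 0.1])
        labels = np.array([True, True, False, False])
        assert roc_auc(scores, labels).auc == pytest.approx(1.0)
        assert roc_auc(np.full(4, 0.5), labels).auc == pytest.approx(0.5)

    def test_hand_example(self):
        roc = roc_auc(np.array([0.9, 0.8, 0.7, 0.6]), np.array([1, 0, 1, 0], bool))
        assert roc.auc == pytest.approx(0.75)

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            roc_auc(np.array([0.1, 0.2]), np.array([True, True]))

    def test_matches_pair_counting_oracle(self, rng):
        for _ in range(200):
            scores, labels = _random_instance(rng)
            assert roc_auc(scores, labels).auc == pytest.approx(
                auc_by_pair_counting(scores, labels)
            )

    def test_result_invariants(self, rng):
        scores, labels = _random_instance(rng, n_max=40)
        roc = roc_auc(scores, labels)
        assert np.all(np.diff(roc.thresholds) > 0)
        assert np.all(np.diff(roc.sensitivity) <= 0)  # non-increasing in threshold
        lo, hi = roc.auc_ci
        assert lo <= roc.auc <= hi
        assert 0.0 <= roc.auc <= 1.0


class TestCompareAUC:
    def test_identical_scores_delta_zero_p_one(self, rng):
        scores, labels = _random_instance(rng)
        delta, p = compare_auc(scores, scores, labels)
        assert delta == 0.0
        assert p == 1.0

    def test_antisymmetry(self, rng):
        a, labels = _random_instance(rng, n_max=40)
        b = rng.uniform(0, 1, len(a))
        d1, p1 = compare_auc(a, b, labels)
        d2, p2 = compare_auc(b, a, labels)
        assert d1 == pytest.approx(-d2)
        assert p1 == pytest.approx(p2)

    def test_informative_beats_random_score(self, rng):
        n = 500
        labels = np.arange(n) < 100
        informative = np.where(labels, rng.normal(1.5, 1, n), rng.normal(0, 1, n))
        noise = rng.uniform(0, 1, n)
        _, p = compare_auc(informative, noise, labels)
        assert p < 0.05

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            compare_auc(np.ones(3), np.ones(4), np.array([True, False, True]))


class TestBestCutoff:
    def test_perfect_classifier(self):
        roc = roc_auc(np.array([0.9, 0.8, 0.2, 0.1]), np.array([1, 1, 0, 0], bool))
        cut = best_cutoff(roc)
        assert cut.dr_pct == 100.0
        assert cut.fpr_pct == 0.0

    def test_matches_exhaustive_scan(self, rng):
        for _ in range(200):
            scores, labels = _random_instance(rng)
            cut = best_cutoff(roc_auc(scores, labels))
            t_oracle, dr_oracle, fpr_oracle = best_cutoff_by_scan(scores, labels)
            assert cut.dr_pct == pytest.approx(dr_oracle)
            assert cut.fpr_pct == pytest.approx(fpr_oracle)

    def test_tie_broken_toward_lower_fpr(self):
        # two thresholds reach the same (sens+spec)/2; lower FPR must win
        scores = np.array([0.9, 0.7, 0.7, 0.5, 0.3, 0.1])
        labels = np.array([1, 1, 0, 0, 1, 0], bool)
        cut = best_cutoff(roc_auc(scores, labels))
        t, dr, fpr = best_cutoff_by_scan(scores, labels)
        assert cut.fpr_pct == pytest.approx(fpr)


class TestDrAtFPR:
    def test_full_fpr_budget_gives_full_dr(self, rng):
        scores, labels = _random_instance(rng)
        assert dr_at_fpr(scores, labels, 100.0).dr_pct == 100.0

    def test_hand_built_example(self):
        scores = np.array([0.9, 0.8, 0.7, 0.6, 0.5, 0.4, 0.3, 0.2, 0.1, 0.05])
        labels = np.array([1, 1, 0, 1, 0, 0, 0, 0, 0, 0], bool)
        res = dr_at_fpr(scores, labels, 15.0)
        # threshold 0.6 keeps FPR at 1/7 (14.3%) <= 15% and catches all 3
        # positives: DR 100%, PPV 3/4
        assert res.dr_pct == pytest.approx(100.0)
        assert res.ppv_pct == pytest.approx(75.0)
        assert res.threshold == pytest.approx(0.6)

    def test_matches_exhaustive_scan(self, rng):
        for _ in range(200):
            scores, labels = _random_instance(rng, n_max=100)
            target = float(rng.choice([5.0, 10.0, 25.0, 50.0]))
            assert dr_at_fpr(scores, labels, target).dr_pct == pytest.approx(
                dr_at_fpr_by_scan(scores, labels, target)
            )

    def test_dr_monotone_in_target(self, rng):
        scores, labels = _random_instance(rng, n_max=80)
        drs = [dr_at_fpr(scores, labels, t).dr_pct for t in (5, 10, 15, 30, 60, 100)]
        assert np.all(np.diff(drs) >= 0)

    def test_invalid_target_errors(self, rng):
        scores, labels = _random_instance(rng)
        with pytest.raises(ValueError):
            dr_at_fpr(scores, labels, 0.0)
        with pytest.raises(ValueError):
            dr_at_fpr(scores, labels, 120.0)


class TestClopperPearson:
    @pytest.mark.parametrize(
        "s,n,lo,hi",
        [
            (7, 8, 47.35, 99.68),
            (5, 5, 47.82, 100.00),
            (6, 10, 26.24, 87.84),
            (0, 10, 0.00, 30.85),
        ],
    )
    def test_published_style_intervals(self, s, n, lo, hi):
        got_lo, got_hi = clopper_pearson(s, n)
        assert got_lo == pytest.approx(lo, abs=0.005)
        assert got_hi == pytest.approx(hi, abs=0.005)

    def test_agrees_with_statsmodels(self):
        from statsmodels.stats.proportion import proportion_confint

        for s, n in [(3, 17), (12, 40), (1, 1), (0, 9)]:
            lo, hi = clopper_pearson(s, n)
            sm_lo, sm_hi = proportion_confint(s, n, alpha=0.05, method="beta")
            assert lo == pytest.approx(sm_lo * 100, abs=1e-9)
            assert hi == pytest.approx(sm_hi * 100, abs=1e-9)

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            clopper_pearson(5, 4)
        with pytest.raises(ValueError):
            clopper_pearson(-1, 4)

    def test_coverage_at_least_nominal(self, rng):
        """Exact intervals cover the true p at >= 95% over simulated draws."""
        n, reps = 25, 10000
        for p in (0.1, 0.5, 0.9):
            draws = rng.binomial(n, p, reps)
            uniq, counts = np.unique(draws, return_counts=True)
            cover = 0
            for s, c in zip(uniq, counts):
                lo, hi = clopper_pearson(int(s), n)
                cover += c * (lo <= p * 100 <= hi)
            assert cover / reps >= 0.95


class TestMannWhitney:
    def test_identical_multisets_p_near_one(self):
        a = [1.0, 2.0, 3.0, 4.0]
        _, p = mann_whitney(a, list(a))
        assert p > 0.8

    def test_exact_enumeration_example(self):
        u, p = mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)  # 2 / C(6,3) = 2/20

    def test_invariant_under_monotone_transform(self, rng):
        a = rng.normal(0, 1, 30)
        b = rng.normal(0.5, 1, 25)
        _, p1 = mann_whitney(a, b)
        _, p2 = mann_whitney(np.exp(a), np.exp(b))
        assert p1 == pytest.approx(p2)

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestGroupSummary:
    def test_structure_and_invariance(self, small_scored, small_cohort):
        import pandas as pd

        moms, status = small_scored
        frame, _ = small_cohort
        data = moms.assign(pe_status=status.to_numpy(), sga=frame["sga"].to_numpy())
        table = summarize_group_moms(data)
        assert set(table["group"]) >= {"unaffected_by_pe", "pe", "early_pe", "late_pe", "sga"}
        shuffled = summarize_group_moms(data.sample(frac=1.0, random_state=0))
        pd.testing.assert_frame_equal(
            table.sort_values("group").reset_index(drop=True),
            shuffled.sort_values("group").reset_index(drop=True),
        )

    def test_constant_marker_zero_iqr(self, small_scored, small_cohort):
        moms, status = small_scored
        frame, _ = small_cohort
        data = moms.assign(pe_status=status.to_numpy(), sga=frame["sga"].to_numpy())
        data["mom_plgf"] = 1.0
        table = summarize_group_moms(data).set_index("group")
        row = table.loc["unaffected_by_pe"]
        assert row["mom_plgf_q3"] - row["mom_plgf_q1"] == 0.0

    def test_empty_group_emits_n_zero_row(self, small_scored, small_cohort):
        moms, status = small_scored
        frame, _ = small_cohort
        data = moms.assign(pe_status="none", sga=frame["sga"].to_numpy())
        table = summarize_group_moms(data).set_index("group")
        assert table.loc["early_pe", "n"] == 0
        assert np.isnan(table.loc["early_pe", "mom_plgf_median"])
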