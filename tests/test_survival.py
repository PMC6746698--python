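"""Kaplan-Meier, log-rank, cut-point search, Cox PH, concordance, cross-validation."""

import math

import numpy as np
import pytest
from lifelines import CoxPHFitter
from lifelines.statistics import logrank_test as ll_logrank
from lifelines.utils import concordance_index as ll_concordance
from scipy.optimize import minimize_scalar

import pandas as pd

from tilab import (
    CohortSpec,
    SurvivalRecord,
    ValidationError,
    concordance_index,
    cox_fit,
    cross_validate,
    generate_cohort,
    km_estimate,
    logrank_test,
    optimal_cutpoint,
    stratify,
)
from tilab.survival import read_cohort_csv, write_cohort_csv


def rec(i, t, e, score=0.0, **cov):
    return SurvivalRecord(f"s{i}", t, e, score, cov)


def sim_cohort(n, seed, log_hr=0.0, threshold=0.5, **kw):
    rng = np.random.default_rng(seed)
    scores = rng.uniform(0, 1, n)
    spec = CohortSpec(n_subjects=n, log_hr=log_hr, threshold=threshold,
                      seed=seed + 1_000_000, **kw)
    return generate_cohort(spec, scores)


# ---------------------------------------------------------------- Kaplan-Meier

class TestKaplanMeier:
    def test_all_censored_is_flat_one(self):
        curve = km_estimate([rec(i, t, 0) for i, t in enumerate([3.0, 5.0, 8.0])])
        assert np.all(curve.survival == 1.0)

    def test_three_events_product_limit(self):
        curve = km_estimate([rec(i, t, 1) for i, t in enumerate([1.0, 2.0, 3.0])])
        by_time = dict(zip(curve.times, curve.survival))
        assert by_time[1.0] == pytest.approx(2 / 3)
        assert by_time[2.0] == pytest.approx(1 / 3)
        assert by_time[3.0] == pytest.approx(0.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_product_limit_recurrence(self, seed):
        records = sim_cohort(30, seed, log_hr=0.5)
        curve = km_estimate(records)
        t = np.array([r.time for r in records])
        e = np.array([r.event for r in records])
        # independent recurrence: S(t) = prod over event times <= t of (1 - d/n)
        s = 1.0
        expected = {}
        for ti in np.unique(t[e == 1]):
            n_at = int((t >= ti).sum())
            d = int(((t == ti) & (e == 1)).sum())
            s *= 1 - d / n_at
            expected[ti] = s
        by_time = dict(zip(curve.times, curve.survival))
        for ti, si in expected.items():
            assert by_time[ti] == pytest.approx(si, abs=1e-12)

    def test_curve_shape_invariants(self):
        records = sim_cohort(40, 3, log_hr=0.7)
        curve = km_estimate(records)
        assert curve.survival[0] <= 1.0
        assert curve.times[0] == 0.0 and curve.survival[0] == 1.0
        assert np.all(np.diff(curve.survival) <= 1e-12)

    def test_nonpositive_time_rejected(self):
        with pytest.raises(ValidationError):
            rec(0, 0.0, 1)


# ---------------------------------------------------------------- log-rank

class TestLogrank:
    def test_identical_groups_null(self):
        g = [rec(i, t, e) for i, (t, e) in enumerate([(2, 1), (4, 0), (6, 1)])]
        chi2, p = logrank_test(g, g)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_six_subject_hand_table(self):
        """Hand-computed hypergeometric tables for a tiny worked example."""
        a = [rec(0, 1.0, 1), rec(1, 3.0, 1), rec(2, 5.0, 0)]
        b = [rec(3, 2.0, 1), rec(4, 4.0, 1), rec(5, 6.0, 1)]
        # event times: 1 (nA=3,nB=3), 2 (2,3), 3 (2,2), 4 (1,2), 6 (0,1)
        contributions = [
            (1, 3, 6),  # (dA, nA, n) at t=1
            (0, 2, 5),
            (1, 2, 4),
            (0, 1, 3),
            (0, 0, 1),
        ]
        o_minus_e = sum(dA - nA / n for dA, nA, n in contributions)
        var = sum((nA / n) * (1 - nA / n) * (n - 1) / (n - 1)
                  for dA, nA, n in contributions if n > 1)
        expected_chi2 = o_minus_e**2 / var
        chi2, _ = logrank_test(a, b)
        assert chi2 == pytest.approx(expected_chi2, abs=1e-10)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_lifelines(self, seed):
        ga = sim_cohort(35, seed, log_hr=0.8)
        gb = sim_cohort(30, seed + 500, log_hr=0.0)
        chi2, p = logrank_test(ga, gb)
        ref = ll_logrank(
            [r.time for r in ga], [r.time for r in gb],
            event_observed_A=[r.event for r in ga],
            event_observed_B=[r.event for r in gb],
        )
        assert chi2 == pytest.approx(ref.test_statistic, rel=1e-9)
        assert p == pytest.approx(ref.p_value, rel=1e-9)

    def test_symmetric_in_group_order(self):
        ga = sim_cohort(25, 11, log_hr=1.0)
        gb = sim_cohort(20, 12)
        assert logrank_test(ga, gb)[0] == pytest.approx(logrank_test(gb, ga)[0], abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            logrank_test([], sim_cohort(5, 1))

    def test_power_under_hazard_ratio_three(self):
        """Exponential groups with hazard ratio 3 at n=200/group: rejection
        rate at alpha=0.05 should be essentially one."""
        rejections = 0
        n_rep = 500
        for i in range(n_rep):
            r = np.random.default_rng(40_000 + i)
            ta = r.exponential(1 / 0.03, 200)
            tb = r.exponential(1 / 0.09, 200)
            ca = r.uniform(0, 60, 200)
            cb = r.uniform(0, 60, 200)
            ga = [SurvivalRecord(f"a{j}", max(min(ta[j], ca[j]), 1e-9),
                                 int(ta[j] <= ca[j]), 0.0) for j in range(200)]
            gb = [SurvivalRecord(f"b{j}", max(min(tb[j], cb[j]), 1e-9),
                                 int(tb[j] <= cb[j]), 0.0) for j in range(200)]
            if logrank_test(ga, gb)[1] < 0.05:
                rejections += 1
        assert rejections / n_rep > 0.9

    def test_type_i_error_under_label_permutation(self):
        """Permuting group labels of one cohort: empirical size near alpha."""
        records = sim_cohort(80, 77, log_hr=0.9)
        rng = np.random.default_rng(9)
        rejected = 0
        n_perm = 1000
        for _ in range(n_perm):
            mask = rng.permutation(80) < 40
            ga = [r for r, m in zip(records, mask) if m]
            gb = [r for r, m in zip(records, mask) if not m]
            if logrank_test(ga, gb)[1] < 0.05:
                rejected += 1
        assert 0.03 <= rejected / n_perm <= 0.07


# ---------------------------------------------------------------- cut-point

class TestOptimalCutpoint:
    def test_separable_groups_single_gap(self):
        lows = [SurvivalRecord(f"l{i}", 2.0 + 0.1 * i, 1, 0.1) for i in range(10)]
        highs = [SurvivalRecord(f"h{i}", 80.0 + i, 0, 0.9) for i in range(10)]
        res = optimal_cutpoint(lows + highs)
        assert res.cutpoint == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_scan_oracle(self, seed):
        records = sim_cohort(60, seed, log_hr=1.0)
        res = optimal_cutpoint(records, min_group_frac=0.1)
        scores = np.array([r.score for r in records])
        distinct = np.unique(scores)
        best_chi2, best_cut = -1.0, None
        for c in (distinct[:-1] + distinct[1:]) / 2:
            low = [r for r in records if r.score < c]
            high = [r for r in records if r.score >= c]
            if min(len(low), len(high)) < 0.1 * len(records):
                continue
            ref = ll_logrank(
                [r.time for r in low], [r.time for r in high],
                event_observed_A=[r.event for r in low],
                event_observed_B=[r.event for r in high],
            ).test_statistic
            if ref > best_chi2 + 1e-12:
                best_chi2, best_cut = ref, c
        assert res.chi2 == pytest.approx(best_chi2, rel=1e-9)
        assert res.cutpoint == pytest.approx(best_cut)

    def test_min_group_frac_respected(self):
        records = sim_cohort(50, 4, log_hr=1.2)
        res = optimal_cutpoint(records, min_group_frac=0.3)
        n_low = sum(r.score < res.cutpoint for r in records)
        assert 15 <= n_low <= 35

    def test_no_admissible_candidate_rejected(self):
        # 19 tied low scores and a single distinct high one: any split leaves
        # the high group below 10%
        records = [rec(i, 5.0 + i, 1, 0.2) for i in range(19)]
        records.append(rec(99, 50.0, 0, 0.9))
        with pytest.raises(ValidationError):
            optimal_cutpoint(records, min_group_frac=0.1)

    def test_needs_two_distinct_scores(self):
        with pytest.raises(ValidationError):
            optimal_cutpoint([rec(i, 5.0, 1, 0.5) for i in range(10)])

    def test_stratify_groups_partition_and_orientation(self):
        records = sim_cohort(60, 21, log_hr=1.2)
        res = optimal_cutpoint(records)
        strat = stratify(records, res.cutpoint)
        assert len(strat.group) == 60
        for r, g in zip(records, strat.group):
            assert g == ("high_risk" if r.score < res.cutpoint else "low_risk")
        assert strat.logrank_chi2 == pytest.approx(res.chi2, abs=1e-9)
        for curve in strat.km_curves.values():
            assert np.all(np.diff(curve.survival) <= 1e-12)


# ---------------------------------------------------------------- Cox PH

def oracle_partial_loglik(beta, t, e, z):
    """Hand-coded Cox partial log-likelihood (no ties)."""
    order = np.argsort(t)
    t, e, z = t[order], e[order], z[order]
    ll = 0.0
    for i in range(len(t)):
        if e[i]:
            risk = z[i:]  # all with time >= t_i (no ties)
            ll += beta * z[i] - math.log(np.exp(beta * risk).sum())
    return ll


class TestCoxFit:
    def test_null_covariate_ci_covers_one(self):
        records = sim_cohort(500, 31, log_hr=0.0)
        res = cox_fit(records, ["score"])
        cov = res.covariates[0]
        assert cov.ci_lower <= 1.0 <= cov.ci_upper

    def test_tiny_cohort_matches_partial_likelihood_maximizer(self):
        rng = np.random.default_rng(5)
        t = np.array([1.3, 2.1, 3.7, 5.2, 8.9, 13.0])
        e = np.ones(6, dtype=int)
        z = np.array([1.0, 0.0, 1.0, 0.0, 0.0, 1.0])
        records = [SurvivalRecord(f"s{i}", t[i], int(e[i]), 0.0, {"z": z[i]})
                   for i in range(6)]
        records += [SurvivalRecord(f"c{i}", 20.0 + i, 0, 0.0,
                                   {"z": float(i % 2)}) for i in range(4)]
        tt = np.array([r.time for r in records])
        ee = np.array([r.event for r in records])
        zz = np.array([r.covariates["z"] for r in records])
        opt = minimize_scalar(lambda b: -oracle_partial_loglik(b, tt, ee, zz),
                              bounds=(-5, 5), method="bounded",
                              options={"xatol": 1e-10})
        res = cox_fit(records, ["z"])
        assert res.covariates[0].coef == pytest.approx(opt.x, abs=1e-4)

    def test_matches_lifelines_coefficients(self):
        records = sim_cohort(200, 55, log_hr=1.0)
        res = cox_fit(records, ["score"])
        df = pd.DataFrame({
            "t": [r.time for r in records],
            "e": [r.event for r in records],
            "score": [r.score for r in records],
        })
        cph = CoxPHFitter().fit(df, "t", "e")
        assert res.covariates[0].coef == pytest.approx(
            cph.params_["score"], abs=1e-4)
        assert res.covariates[0].se == pytest.approx(
            cph.standard_errors_["score"], abs=1e-4)

    def test_breslow_equals_efron_without_ties(self):
        records = sim_cohort(80, 62, log_hr=0.8)
        a = cox_fit(records, ["score"], ties="efron")
        b = cox_fit(records, ["score"], ties="breslow")
        assert a.covariates[0].coef == pytest.approx(b.covariates[0].coef, abs=1e-6)

    def test_categorical_covariate_dummy_coding(self):
        records = []
        rng = np.random.default_rng(8)
        for i in range(60):
            grade = ["I", "II", "III"][i % 3]
            records.append(SurvivalRecord(
                f"s{i}", float(rng.exponential(30) + 0.01), int(rng.random() < 0.7),
                float(rng.uniform()), {"grade": grade}))
        res = cox_fit(records, ["grade"])
        names = [c.name for c in res.covariates]
        # lexicographically first level "I" is the reference
        assert names == ["grade_II", "grade_III"]

    def test_complete_separation_flagged_unbounded_ci(self):
        recs = [SurvivalRecord(f"a{i}", 1.0 + 0.1 * i, 1, 0.0, {"z": 1.0})
                for i in range(6)]
        recs += [SurvivalRecord(f"b{i}", 10.0 + i, 1, 1.0, {"z": 0.0})
                 for i in range(6)]
        res = cox_fit(recs, ["z"])
        cov = res.covariates[0]
        assert cov.separation_flag
        assert cov.ci_lower == 0.0 and cov.ci_upper == math.inf

    def test_constant_covariate_rejected(self):
        records = [rec(i, 1.0 + i, 1, 0.5, z=1.0) for i in range(12)]
        with pytest.raises(ValidationError):
            cox_fit(records, ["z"])

    def test_small_n_rejected(self):
        with pytest.raises(ValidationError):
            cox_fit([rec(i, 1.0 + i, 1, float(i)) for i in range(5)], ["score"])

    def test_sign_agrees_with_logrank_direction(self):
        records = sim_cohort(150, 71, log_hr=1.2)
        res = cox_fit(records, ["z_true"])
        # z_true = 1 marks the high-hazard group; beta should be positive and
        # that group's KM curve should sit below
        assert res.covariates[0].coef > 0
        high = [r for r in records if r.covariates["z_true"] == 1.0]
        low = [r for r in records if r.covariates["z_true"] == 0.0]
        chi2, p = logrank_test(high, low)
        assert p < 0.05

    def test_training_c_index_at_least_half(self):
        records = sim_cohort(120, 81, log_hr=1.0)
        res = cox_fit(records, ["score"])
        assert res.c_index >= 0.5


# ---------------------------------------------------------------- concordance

class TestConcordance:
    def test_perfect_ordering(self):
        # higher risk -> earlier event, all events
        records = [rec(i, float(10 - i), 1) for i in range(5)]
        risk = [float(i) for i in range(5)]
        c, ci = concordance_index(records, risk=risk)
        assert c == 1.0
        assert ci[1] == 1.0

    def test_identical_risks_give_half(self):
        records = [rec(i, float(i + 1), 1) for i in range(6)]
        c, _ = concordance_index(records, risk=[1.0] * 6)
        assert c == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", range(8))
    def test_small_n_matches_pair_enumeration(self, seed):
        r = np.random.default_rng(seed)
        n = int(r.integers(4, 11))
        records = [rec(i, float(r.exponential(10) + 0.01), int(r.random() < 0.7))
                   for i in range(n)]
        risk = r.normal(size=n)
        if sum(x.event for x in records) == 0:
            pytest.skip("no events drawn")
        num = den = 0.0
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                ti, tj = records[i].time, records[j].time
                ei, ej = records[i].event, records[j].event
                usable = (ei and ti < tj) or (ei and not ej and ti == tj)
                if usable:
                    den += 1
                    num += 1.0 if risk[i] > risk[j] else (0.5 if risk[i] == risk[j] else 0.0)
        c, _ = concordance_index(records, risk=risk)
        assert c == pytest.approx(num / den, abs=1e-12)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_lifelines(self, seed):
        records = sim_cohort(60, 600 + seed, log_hr=1.0)
        c, _ = concordance_index(records)
        ref = ll_concordance(
            [r.time for r in records],
            [r.score for r in records],  # lifelines: higher predicted = later
            [r.event for r in records],
        )
        assert c == pytest.approx(ref, abs=1e-12)

    def test_no_events_rejected(self):
        with pytest.raises(ValidationError):
            concordance_index([rec(i, 1.0 + i, 0) for i in range(5)])


# ---------------------------------------------------------------- cross-validation

class TestCrossValidate:
    def test_same_seed_reproduces(self):
        records = sim_cohort(90, 14, log_hr=1.2)
        a = cross_validate(records, k=3, seed=5)
        b = cross_validate(records, k=3, seed=5)
        assert np.array_equal(a.assignment, b.assignment)
        assert [f.cutpoint for f in a.folds] == [f.cutpoint for f in b.folds]
        assert [f.test_p for f in a.folds] == [f.test_p for f in b.folds]

    def test_leave_one_out_rejected(self):
        records = sim_cohort(20, 15)
        with pytest.raises(ValidationError):
            cross_validate(records, k=20, seed=0)

    def test_partition_is_near_equal_and_complete(self):
        records = sim_cohort(70, 16, log_hr=0.8)
        res = cross_validate(records, k=3, seed=2)
        sizes = np.bincount(res.assignment, minlength=3)
        assert sizes.sum() == 70 and sizes.max() - sizes.min() <= 1

    def test_eventless_fold_flagged_not_dropped(self):
        rng = np.random.default_rng(3)
        records = [SurvivalRecord(f"s{i}", float(rng.uniform(1, 50)), 0,
                                  float(rng.uniform())) for i in range(30)]
        res = cross_validate(records, k=3, seed=1)
        assert len(res.folds) == 3
        assert all("no events in test fold" in f.flags for f in res.folds)


def test_cohort_csv_roundtrip(tmp_path):
    records = sim_cohort(20, 44, log_hr=0.5)
    p = tmp_path / "cohort.csv"
    write_cohort_csv(records, p)
    loaded = read_cohort_csv(p)
    assert [r.subject_id for r in loaded] == [r.subject_id for r in records]
    assert np.allclose([r.time for r in loaded], [r.time for r in records])
    assert [r.event for r in loaded] == [r.event for r in records]
    assert np.allclose([r.score for r in loaded], [r.score for r in records])
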