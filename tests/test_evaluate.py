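"""Diagnostic contingency statistics, DeLong, bootstrap, survival."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from sgasnf import (ContingencyTable, bootstrap_compare, contingency, cox_hr,
                    diagnostic_stats, km_logrank, roc_delong)
from sgasnf.evaluate import clinical_classification
from sgasnf.validation import auroc


class TestContingency:
    def test_perfect_classifier_has_no_errors(self):
        y = np.array([1, 0, 1, 0, 1])
        ct = contingency(y, y)
        assert (ct.fp, ct.fn) == (0, 0)
        assert (ct.tp, ct.tn) == (3, 2)

    def test_matches_direct_four_way_tally(self, rng):
        h = rng.integers(0, 2, 50)
        y = rng.integers(0, 2, 50)
        ct = contingency(h, y)
        assert ct.tp == sum(1 for a, b in zip(h, y) if a == 1 and b == 1)
        assert ct.fp == sum(1 for a, b in zip(h, y) if a == 1 and b == 0)
        assert ct.tn == sum(1 for a, b in zip(h, y) if a == 0 and b == 0)
        assert ct.fn == sum(1 for a, b in zip(h, y) if a == 0 and b == 1)
        assert ct.total == 50

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError):
            contingency([0, 1, 2], [0, 1, 0])


class TestDiagnosticStats:
    def test_cluster_vs_preeclampsia_counts(self):
        s = diagnostic_stats(ContingencyTable(119, 97, 325, 32))
        assert s.dor.value == pytest.approx(12.46, abs=0.005)
        assert s.lr_positive.value == pytest.approx(3.43, abs=0.005)
        assert s.sensitivity.value == pytest.approx(0.79, abs=0.005)
        assert s.specificity.value == pytest.approx(0.77, abs=0.005)

    def test_zero_false_negatives_row(self):
        # perfect sensitivity: LR- = 0, NPV = 1, DOR undefined (NA)
        s = diagnostic_stats(ContingencyTable(15, 201, 358, 0))
        assert s.sensitivity.value == 1.0
        assert s.npv.value == 1.0
        assert s.lr_negative.value == 0.0
        assert np.isnan(s.lr_negative.hi)
        assert np.isnan(s.dor.value)

    def test_uninformative_classifier(self):
        s = diagnostic_stats(ContingencyTable(10, 10, 10, 10))
        assert s.dor.value == pytest.approx(1.0)
        assert s.lr_positive.value == pytest.approx(1.0)
        for est in (s.sensitivity, s.specificity, s.ppv, s.npv):
            assert est.value == pytest.approx(0.5)

    def test_dor_equals_lr_ratio_identity(self, rng):
        for _ in range(20):
            cells = rng.integers(1, 50, 4)
            s = diagnostic_stats(ContingencyTable(*cells))
            assert s.dor.value == pytest.approx(
                s.lr_positive.value / s.lr_negative.value)

    def test_wilson_and_log_wald_cis(self):
        # against direct formulas
        s = diagnostic_stats(ContingencyTable(119, 97, 325, 32))
        z = norm.ppf(0.975)
        se = np.sqrt(1 / 119 + 1 / 97 + 1 / 325 + 1 / 32)
        assert s.dor.lo == pytest.approx(s.dor.value * np.exp(-z * se))
        assert s.dor.hi == pytest.approx(s.dor.value * np.exp(z * se))
        assert s.sensitivity.lo < s.sensitivity.value < s.sensitivity.hi

    def test_haldane_correction_makes_zero_cells_finite(self):
        s = diagnostic_stats(ContingencyTable(15, 201, 358, 0), haldane=True)
        assert np.isfinite(s.dor.value)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(-1, 2, 3, 4)


class TestBootstrapCompare:
    def test_identical_systems_ci_contains_zero_and_narrows(self, rng):
        y = rng.integers(0, 2, 200)
        f = rng.integers(0, 2, 200)
        small = bootstrap_compare(f, f, y, B=200, seed=1)
        big = bootstrap_compare(f, f, y, B=2000, seed=1)
        for r in (small, big):
            assert r.lr_positive_diff.lo <= 0 <= r.lr_positive_diff.hi
        assert (big.lr_positive_diff.hi - big.lr_positive_diff.lo) <= \
            (small.lr_positive_diff.hi - small.lr_positive_diff.lo) + 1e-9
        assert big.n_used + big.n_skipped == 2000

    def test_more_discriminative_system_detected(self):
        detections = 0
        for s in range(20):
            rng = np.random.default_rng(s)
            y = rng.integers(0, 2, 300)
            good = np.where(rng.random(300) < 0.9, y, 1 - y)
            bad = np.where(rng.random(300) < 0.6, y, 1 - y)
            r = bootstrap_compare(good, bad, y, B=300, seed=s)
            detections += r.lr_positive_diff.lo > 0
        assert detections >= 18  # CI excludes 0 in >= 90% of seeds

    def test_deterministic_and_b_accounting(self, rng):
        y = rng.integers(0, 2, 100)
        f = rng.integers(0, 2, 100)
        g = rng.integers(0, 2, 100)
        a = bootstrap_compare(f, g, y, B=500, seed=7)
        b = bootstrap_compare(f, g, y, B=500, seed=7)
        assert a.lr_positive_diff == b.lr_positive_diff
        assert a.n_used + a.n_skipped == 500

    def test_too_few_replicates_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_compare([0, 1], [1, 0], [0, 1], B=10)


class TestDelong:
    def test_identical_scores_give_p_one(self, rng):
        y = rng.integers(0, 2, 60)
        s = rng.normal(size=60)
        out = roc_delong(s, s, y)
        assert out["diff"] == 0
        assert out["p"] == 1.0

    def test_aucs_match_auroc(self, rng):
        y = rng.integers(0, 2, 80)
        sa, sb = rng.normal(size=80) + y, rng.normal(size=80)
        out = roc_delong(sa, sb, y)
        assert out["auc_a"] == pytest.approx(auroc(sa, y))
        assert out["auc_b"] == pytest.approx(auroc(sb, y))

    def test_variance_matches_placement_definition(self, rng):
        # oracle: placement values via explicit double loops
        y = np.r_[np.ones(15, int), np.zeros(25, int)]
        sa = rng.normal(size=40) + y
        sb = rng.normal(size=40) + 0.5 * y
        pos_a, neg_a = sa[y == 1], sa[y == 0]
        pos_b, neg_b = sb[y == 1], sb[y == 0]

        def placements(pos, neg):
            v10 = np.array([np.mean((p > neg) + 0.5 * (p == neg)) for p in pos])
            v01 = np.array([np.mean((pos > q) + 0.5 * (pos == q)) for q in neg])
            return v10, v01

        v10a, v01a = placements(pos_a, neg_a)
        v10b, v01b = placements(pos_b, neg_b)
        var = (np.cov(np.vstack([v10a, v10b]))[0, 0] / 15
               + np.cov(np.vstack([v01a, v01b]))[0, 0] / 25)
        out = roc_delong(sa, sb, y)
        assert out["cov"][0, 0] == pytest.approx(var, rel=1e-10)
        assert out["auc_a"] == pytest.approx(v10a.mean())

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_delong([1.0, 2.0], [2.0, 1.0], [1, 1])


class TestSurvival:
    def test_no_events_rejected(self):
        with pytest.raises(ValueError, match="no events"):
            km_logrank([1.0, 2.0], [0, 0], [0, 1])

    def test_identical_groups_statistic_zero(self):
        t = np.array([1.0, 2.0, 3.0, 4.0] * 2)
        e = np.ones(8, int)
        g = np.repeat([0, 1], 4)
        out = km_logrank(t, e, g)
        assert out.logrank_statistic == pytest.approx(0.0, abs=1e-10)

    def test_km_and_logrank_match_hand_life_table(self):
        # oracle: manual product-limit / observed-vs-expected arithmetic
        t = np.array([1.0, 2.0, 3.0, 4.0, 1.5, 2.5, 4.5, 5.0])
        e = np.array([1, 1, 0, 1, 1, 1, 1, 0])
        g = np.repeat([0, 1], 4)
        out = km_logrank(t, e, g)
        # KM for group 0: events at 1, 2, 4 with risk sets 4, 3, 1
        km0 = out.curves[0]["0"]
        assert km0.loc[1.0] == pytest.approx(3 / 4)
        assert km0.loc[2.0] == pytest.approx(3 / 4 * 2 / 3)
        assert km0.loc[4.0] == pytest.approx(0.0)
        # log-rank: observed-minus-expected over the pooled event times
        times = sorted(set(t[e == 1]))
        o_minus_e, var = 0.0, 0.0
        for s in times:
            at_risk = t >= s
            n1 = int((at_risk & (g == 1)).sum())
            n_tot = int(at_risk.sum())
            d = int(((t == s) & (e == 1)).sum())
            d1 = int(((t == s) & (e == 1) & (g == 1)).sum())
            o_minus_e += d1 - d * n1 / n_tot
            if n_tot > 1:
                var += d * (n1 / n_tot) * (1 - n1 / n_tot) * (n_tot - d) / (n_tot - 1)
        expect = o_minus_e**2 / var
        assert out.logrank_statistic == pytest.approx(expect, rel=1e-10)

    def test_km_curves_non_increasing(self, rng):
        t = rng.exponential(5, 60) + 0.01
        e = np.ones(60, int)
        g = rng.integers(0, 2, 60)
        out = km_logrank(t, e, g)
        for lab, curve in out.curves.items():
            vals = curve.iloc[:, 0].to_numpy()
            assert (np.diff(vals) <= 1e-12).all()
        assert out.logrank_statistic >= 0


class TestCox:
    def test_coefficient_matches_partial_likelihood_grid(self):
        # oracle: exhaustive grid search of the (no-ties) partial likelihood
        t = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        e = np.array([1, 1, 1, 1, 1, 1])
        x = np.array([1, 0, 1, 0, 1, 0])

        def pl(beta):
            order = np.argsort(t)
            ll = 0.0
            for idx, i in enumerate(order):
                risk = order[idx:]
                ll += beta * x[i] - np.log(np.exp(beta * x[risk]).sum())
            return ll

        grid = np.arange(-3, 3, 1e-4)
        best = grid[np.argmax([pl(b) for b in grid])]
        res = cox_hr(t, e, x, ph_check=False)
        assert res.coef == pytest.approx(best, abs=1e-4)

    def test_null_groups_hr_near_one(self):
        hrs = []
        for s in range(20):
            rng = np.random.default_rng(s)
            t = rng.exponential(10, 400) + 1e-3
            e = np.ones(400, int)
            g = rng.integers(0, 2, 400)
            hrs.append(cox_hr(t, e, g, ph_check=False).hazard_ratio)
        assert 0.8 < np.median(hrs) < 1.25

    def test_ph_check_reports_p_value(self, rng):
        t = np.r_[rng.exponential(2, 100), rng.exponential(20, 100)] + 1e-3
        e = np.ones(200, int)
        g = np.repeat([1, 0], 100)
        res = cox_hr(t, e, g)
        assert 0 <= res.ph_test_p <= 1
        assert res.hazard_ratio > 1

    def test_too_few_events_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2 events"):
            cox_hr([1.0, 2.0, 3.0], [1, 0, 0], [1, 0, 0])


def test_clinical_classification_rule():
    df = pd.DataFrame({
        "efw_centile": [1.0, 5.0, 5.0, 5.0, 5.0],
        "ua_pi_z": [0.0, 2.5, 0.0, 0.0, 0.0],
        "uta_pi_z": [0.0, 0.0, 2.1, 0.0, 0.0],
        "cpr_z": [0.0, 0.0, 0.0, -2.5, 0.0],
    })
    assert clinical_classification(df).tolist() == [1, 1, 1, 1, 0]
    with pytest.raises(ValueError):
        clinical_classification(pd.DataFrame({"other": [1.0]}))
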