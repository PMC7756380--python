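"""EAST classes, ratios, 2x2 performance, group tests, PCA contributions."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from epitile.diagnostics import (
    compare_groups,
    diagnostic_performance,
    el_to_east_class,
    epitope_classifier,
    ige_igg4_ratio,
    pca_contributions,
    ratio_classifier,
    recognition_fraction,
    threshold_classifier,
)
from epitile.epitopes import EpitopeCall


class TestEastClass:
    @pytest.mark.parametrize(
        "ru,cls",
        [(0, 0), (2.9, 1), (2.4, 0), (3, 1), (6, 1), (7, 2), (15, 2), (16, 3),
         (30, 3), (31, 4), (44, 4), (50, 4), (51, 5), (67, 5), (100, 5),
         (101, 6), (110, 6), (6.5, 2)],
    )
    def test_step_mapping(self, ru, cls):
        assert el_to_east_class(ru) == cls

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            el_to_east_class(-1.0)

    def test_total_and_monotone_on_grid(self):
        grid = np.arange(0.0, 150.0, 0.25)
        classes = [el_to_east_class(r) for r in grid]
        assert all(0 <= c <= 6 for c in classes)
        assert all(b >= a for a, b in zip(classes, classes[1:]))


class TestRatios:
    def test_hand_values(self):
        rec = ige_igg4_ratio(50.0, 100.0)
        assert rec.ratio == pytest.approx(0.5)
        assert rec.log_ratio == pytest.approx(math.log10(0.5))
        assert ige_igg4_ratio(100.0, 100.0).log_ratio == 0.0

    def test_zero_igg4_undefined(self):
        rec = ige_igg4_ratio(50.0, 0.0)
        assert rec.ratio is None and rec.log_ratio is None

    def test_ratio_classifier_conventions(self):
        ratios = {"a": 1.0, "b": 0.99, "c": None}
        assert ratio_classifier(ratios, 1.0, inclusive=True) == {
            "a": True, "b": False, "c": False,
        }
        assert ratio_classifier(ratios, 1.0, inclusive=False)["a"] is False


class TestDiagnosticPerformance:
    def _truth(self):
        truth = {f"A{i}": "allergic" for i in range(13)}
        truth.update({f"T{i}": "tolerant" for i in range(15)})
        return truth

    def test_printed_two_by_two(self):
        """6/13 allergic and 1/15 tolerant positive: specificity 0.93,
        sensitivity 46%."""
        truth = self._truth()
        pred = {p: False for p in truth}
        for p in ["A0", "A1", "A2", "A3", "A4", "A5", "T0"]:
            pred[p] = True
        counts = diagnostic_performance(pred, truth)
        assert (counts.tp, counts.fp, counts.tn, counts.fn) == (6, 1, 14, 7)
        summary = counts.summary()
        assert summary["specificity"] == 0.93
        assert summary["sensitivity_pct"] == 46

    def test_degenerate_rules(self):
        truth = self._truth()
        all_neg = diagnostic_performance({p: False for p in truth}, truth)
        assert (all_neg.sensitivity, all_neg.specificity) == (0.0, 1.0)
        perfect = diagnostic_performance(
            {p: g == "allergic" for p, g in truth.items()}, truth
        )
        assert (perfect.sensitivity, perfect.specificity) == (1.0, 1.0)

    def test_margins_and_order_invariance(self):
        truth = self._truth()
        rng = np.random.default_rng(0)
        pred = {p: bool(rng.random() < 0.5) for p in truth}
        c1 = diagnostic_performance(pred, truth)
        assert c1.tp + c1.fn == 13
        assert c1.tn + c1.fp == 15
        shuffled = dict(reversed(list(truth.items())))
        c2 = diagnostic_performance(pred, shuffled)
        assert (c1.tp, c1.fp, c1.tn, c1.fn) == (c2.tp, c2.fp, c2.tn, c2.fn)

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            diagnostic_performance({}, {})

    def test_mismatched_patients_rejected(self):
        with pytest.raises(ValueError, match="different patients"):
            diagnostic_performance({"a": True}, {"b": "allergic"})


class TestThresholdClassifier:
    def test_inclusive_boundary(self):
        titres = {"a": 4.9, "b": 5.0, "c": 5.1}
        assert threshold_classifier(titres, 5.0) == {
            "a": False, "b": True, "c": True,
        }

    def test_extreme_cutoffs(self):
        titres = {"a": 0.4, "b": 77.0}
        assert threshold_classifier(titres, 100.0) == {"a": False, "b": False}
        assert threshold_classifier(titres, 0.35) == {"a": True, "b": True}


class TestRecognitionFraction:
    @pytest.mark.parametrize(
        "k,n,pct", [(5, 13, 38), (4, 15, 27), (9, 28, 32), (1, 15, 7), (6, 13, 46)]
    )
    def test_whole_percent_rounding(self, k, n, pct):
        assert recognition_fraction(k, n) == pct


class TestEpitopeClassifier:
    def _call(self, pid, region, channel="IgE"):
        return EpitopeCall(pid, channel, "GAL1", ("x",), region[0], region[1], 5.0)

    def test_overlap_with_discriminative_regions(self):
        calls = [
            self._call("P1", (31, 42)),     # overlaps aa30-41
            self._call("P2", (60, 71)),     # overlaps nothing
            self._call("P3", (84, 95)),     # exact discriminative region
            self._call("P4", (31, 42), channel="IgG4"),  # wrong channel
        ]
        pred = epitope_classifier(calls, ["P1", "P2", "P3", "P4", "P5"])
        assert pred == {
            "P1": True, "P2": False, "P3": True, "P4": False, "P5": False,
        }


def _oracle_exact_p(a, b):
    """Two-sided exact permutation p of the rank sum, full enumeration."""
    combined = np.concatenate([a, b])
    ranks = stats.rankdata(combined)
    n1 = len(a)
    obs = ranks[:n1].sum()
    sums = [
        sum(ranks[list(idx)])
        for idx in itertools.combinations(range(len(combined)), n1)
    ]
    sums = np.array(sums)
    p_low = np.mean(sums <= obs + 1e-9)
    p_high = np.mean(sums >= obs - 1e-9)
    return min(1.0, 2.0 * min(p_low, p_high))


class TestCompareGroups:
    def test_separated_groups_exact_p(self):
        u, p = compare_groups([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)

    def test_identical_groups_p_one(self):
        _, p = compare_groups([1, 2, 3], [1, 2, 3])
        assert p == pytest.approx(1.0)

    def test_constant_data_p_one(self):
        _, p = compare_groups([2.0, 2.0], [2.0, 2.0, 2.0])
        assert p == pytest.approx(1.0)

    def test_swap_symmetry(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(0, 1, 6), rng.normal(1, 1, 8)
        _, p1 = compare_groups(a, b)
        _, p2 = compare_groups(b, a)
        assert p1 == pytest.approx(p2)

    @pytest.mark.parametrize("seed", range(8))
    def test_exact_mode_matches_enumeration_with_ties(self, seed):
        """Combined n <= 8 with ties: DP p equals full enumeration."""
        rng = np.random.default_rng(seed)
        n1, n2 = rng.integers(2, 5), rng.integers(2, 5)
        a = rng.integers(0, 4, n1).astype(float)
        b = rng.integers(0, 4, n2).astype(float)
        _, p = compare_groups(a, b)
        assert p == pytest.approx(_oracle_exact_p(a, b))

    def test_matches_scipy_when_no_ties(self):
        rng = np.random.default_rng(9)
        a, b = rng.normal(0, 1, 8), rng.normal(0.8, 1, 9)
        u, p = compare_groups(a, b)
        u_sp, p_sp = stats.mannwhitneyu(a, b, alternative="two-sided",
                                        method="exact")
        assert u == pytest.approx(u_sp)
        assert p == pytest.approx(p_sp)

    def test_large_cohort_uses_tie_corrected_normal(self):
        rng = np.random.default_rng(11)
        a, b = rng.normal(0, 1, 16), rng.normal(0.5, 1, 14)
        u, p = compare_groups(a, b)
        u_sp, p_sp = stats.mannwhitneyu(a, b, alternative="two-sided",
                                        method="asymptotic")
        assert u == pytest.approx(u_sp)
        assert p == pytest.approx(p_sp)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([], [1.0])


class TestPcaContributions:
    def test_dominant_variance_feature_drives_pc1(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.normal(0, 0.1, size=(20, 5)),
                         columns=[f"f{i}" for i in range(5)])
        X["big"] = rng.normal(0, 10.0, size=20)
        res = pca_contributions(X)
        assert res.contributions.loc["big", "PC1"] > 95.0

    def test_contributions_sum_to_hundred(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.normal(size=(10, 6)))
        res = pca_contributions(X)
        np.testing.assert_allclose(
            res.contributions.sum(axis=0).to_numpy(), 100.0, atol=1e-9
        )
        assert (res.contributions.to_numpy() >= 0).all()

    def test_duplicated_patient_leaves_loadings_stable(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame(rng.normal(size=(12, 4)))
        res1 = pca_contributions(X)
        X2 = pd.concat([X, X], axis=0, ignore_index=True)
        res2 = pca_contributions(X2)
        np.testing.assert_allclose(
            res1.contributions.to_numpy(),
            res2.contributions.to_numpy(),
            atol=1e-8,
        )

    def test_constant_feature_dropped_zero_variance_rejected(self):
        rng = np.random.default_rng(6)
        X = pd.DataFrame(rng.normal(size=(8, 3)), columns=["a", "b", "c"])
        X["flat"] = 1.0
        res = pca_contributions(X)
        assert res.dropped_features == ["flat"]
        assert "flat" not in res.contributions.index
        with pytest.raises(ValueError, match="zero variance"):
            pca_contributions(pd.DataFrame(np.ones((5, 4))))

    def test_sign_convention_deterministic(self):
        rng = np.random.default_rng(8)
        X = pd.DataFrame(rng.normal(size=(15, 5)))
        res = pca_contributions(X)
        for col in res.contributions.columns:
            loadings = np.sqrt(res.contributions[col].to_numpy() / 100.0)
            assert loadings.max() >= 0  # magnitudes; sign fixed internally
        res2 = pca_contributions(X.iloc[::-1].reset_index(drop=True))
        np.testing.assert_allclose(
            res.contributions.to_numpy(), res2.contributions.to_numpy(),
            atol=1e-8,
        )
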