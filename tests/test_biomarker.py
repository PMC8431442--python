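import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from evmir.biomarker import (
    CombinedRule,
    RatioMarker,
    auc,
    choose_cutoff,
    classify_combined,
    classify_ratio,
    confusion_metrics,
    metastasis_candidates,
    rank_single_markers,
    ratio_search,
    ratio_values,
    roc_curve,
)


def _pair_enumeration_auc(cases, controls):
    """Brute-force oracle: average over all (case, control) pairs."""
    total = 0.0
    for c in cases:
        for k in controls:
            total += 1.0 if c > k else (0.5 if c == k else 0.0)
    return total / (len(cases) * len(controls))


class TestAuc:
    def test_perfect_separation(self):
        assert auc([4, 5, 6, 1, 2, 3], ["P"] * 3 + ["C"] * 3, "P") == 1.0

    def test_enumerated_four_pairs(self):
        # pairs (1>2)F (1>4)F (3>2)T (3>4)F -> 1/4
        assert auc([1, 3, 2, 4], ["P", "P", "C", "C"], "P") == pytest.approx(0.25)

    def test_exchangeable_with_ties(self):
        assert auc([1, 2, 3, 1, 2, 3], ["P"] * 3 + ["C"] * 3, "P") == 0.5

    def test_one_class_is_an_error(self):
        with pytest.raises(ValueError):
            auc([1, 2], ["P", "P"], "P")

    def test_no_automatic_flipping(self):
        # a protective marker reports AUC < 0.5 as-is
        assert auc([1, 2, 5, 6], ["P", "P", "C", "C"], "P") == 0.0

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_pair_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n1, n0 = rng.integers(1, 15, size=2)
        vals = rng.integers(0, 10, size=n1 + n0).astype(float)  # ints force ties
        labels = np.array(["P"] * n1 + ["C"] * n0)
        expected = _pair_enumeration_auc(vals[:n1], vals[n1:])
        assert auc(vals, labels, "P") == pytest.approx(expected, abs=1e-12)

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_invariance_under_increasing_transform_and_complement(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.normal(size=12)
        labels = np.array(["P"] * 5 + ["C"] * 7)
        a = auc(vals, labels, "P")
        assert auc(np.exp(vals), labels, "P") == pytest.approx(a, abs=1e-12)
        assert auc(-vals, labels, "P") == pytest.approx(1 - a, abs=1e-12)


class TestRocCurve:
    def test_perfect_separation_reaches_corner(self):
        pts = roc_curve([4, 5, 6, 1, 2, 3], ["P"] * 3 + ["C"] * 3, "P")
        assert any(np.allclose(p, [0, 1]) for p in pts)

    def test_endpoints_and_monotonicity(self, rng):
        vals = rng.normal(size=20)
        labels = np.array(["P"] * 8 + ["C"] * 12)
        pts = roc_curve(vals, labels, "P")
        assert np.allclose(pts[0], [0, 0]) and np.allclose(pts[-1], [1, 1])
        assert (np.diff(pts[:, 0]) >= -1e-12).all()
        assert (np.diff(pts[:, 1]) >= -1e-12).all()

    def test_trapezoid_area_equals_mann_whitney(self, rng):
        vals = rng.normal(size=20)
        labels = np.array(["P"] * 9 + ["C"] * 11)
        pts = roc_curve(vals, labels, "P")
        area = np.trapezoid(pts[:, 1], pts[:, 0])
        assert area == pytest.approx(auc(vals, labels, "P"), abs=1e-12)

    def test_single_case_single_control(self):
        pts = roc_curve([2.0, 1.0], ["P", "C"], "P")
        np.testing.assert_allclose(pts, [[0, 0], [0, 1], [1, 1]])


class TestRankAndRatioSearch:
    def test_single_candidate_ranks_first(self, default_norm, default_cohort):
        t = rank_single_markers(default_norm.values,
                                default_cohort.samples["diagnosis"], "PDAC",
                                ["miR-95-3p"])
        assert t.iloc[0]["mirna_id"] == "miR-95-3p"

    def test_label_permutation_concentrates_at_half(self, default_norm, rng):
        n = default_norm.values.shape[1]
        aucs = []
        for _ in range(50):
            labels = rng.permutation(["PDAC"] * 30 + ["CP"] * 18)
            aucs.append(auc(default_norm.values.iloc[10], labels, "PDAC"))
        se = np.std(aucs, ddof=1) / np.sqrt(len(aucs))
        assert abs(np.mean(aucs) - 0.5) < 3 * max(se, 1e-3)

    def test_constant_denominator_preserves_auc(self):
        vals = pd.DataFrame(
            {f"S{i}": [v, 2.0] for i, v in enumerate([5, 6, 7, 1, 2, 3])},
        )
        vals.index = ["num", "den"]
        labels = ["P"] * 3 + ["C"] * 3
        t = ratio_search(vals, labels, "P", "num", ["den"])
        assert t.iloc[0]["auc"] == pytest.approx(auc(vals.loc["num"], labels, "P"))

    def test_numerator_never_its_own_denominator(self, default_norm, default_cohort):
        t = ratio_search(default_norm.values, default_cohort.samples["diagnosis"],
                         "PDAC", "miR-95-3p", ["miR-95-3p", "miR-26b-5p"])
        assert "miR-95-3p" not in set(t["denominator"])

    def test_empty_candidates_is_an_error(self, default_norm, default_cohort):
        with pytest.raises(ValueError, match="empty candidate"):
            ratio_search(default_norm.values, default_cohort.samples["diagnosis"],
                         "PDAC", "miR-95-3p", ["miR-95-3p"])

    def test_zero_denominator_specimens_excluded(self):
        vals = pd.DataFrame([[4.0, 5.0, 1.0], [2.0, 0.0, 1.0]],
                            index=["num", "den"], columns=["S1", "S2", "S3"])
        r = ratio_values(vals, "num", "den")
        assert list(r.index) == ["S1", "S3"]


class TestChooseCutoff:
    def test_fixed_returns_constant(self):
        assert choose_cutoff([1, 2], ["P", "C"], "P", "fixed", fixed=0.06) == 0.06

    def test_separable_youden(self):
        c = choose_cutoff([10, 11, 1, 2], ["P", "P", "C", "C"], "P", "youden")
        assert 2 < c < 10
        calls = [classify_ratio(x, c) for x in [10, 11, 1, 2]]
        assert calls == ["Tumor", "Tumor", "Benign", "Benign"]

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_youden_matches_exhaustive_scan(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.integers(0, 8, size=12).astype(float)
        labels = np.array(["P"] * 5 + ["C"] * 7)
        c = choose_cutoff(vals, labels, "P", "youden")
        y = labels == "P"

        def youden_at(cut):
            call = vals >= cut
            return (call & y).sum() / y.sum() + (~call & ~y).sum() / (~y).sum() - 1

        best = max(youden_at(t) for t in np.concatenate([vals - 1e-9, vals + 1e-9]))
        assert youden_at(c) == pytest.approx(best, abs=1e-12)


class TestDecisionRules:
    @pytest.mark.parametrize("x, expected", [(0.05, "Benign"), (0.07, "Tumor"),
                                             (0.06, "Tumor")])
    def test_ratio_rule_boundaries(self, x, expected):
        assert classify_ratio(x, 0.06) == expected

    @pytest.mark.parametrize("x, y, expected", [
        (0.05, 200.0, "Benign"),   # both strictly below
        (0.05, 400.0, "Tumor"),    # CA19-9 alone triggers
        (0.07, 200.0, "Tumor"),    # ratio alone triggers
        (0.06, 300.0, "Tumor"),    # boundary falls to "else"
    ])
    def test_combined_rule(self, x, y, expected):
        assert classify_combined(x, y, CombinedRule()) == expected

    def test_missing_ca199_falls_back_to_ratio(self):
        assert classify_combined(0.05, None, CombinedRule()) == "Benign"
        assert classify_combined(0.07, None, CombinedRule()) == "Tumor"

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_combined_tumor_region_contains_ratio_tumor_region(self, seed):
        rng = np.random.default_rng(seed)
        xs = rng.uniform(0, 0.2, size=30)
        ys = rng.uniform(0, 600, size=30)
        rule = CombinedRule()
        for x, y in zip(xs, ys):
            if classify_ratio(x, rule.x0) == "Tumor":
                assert classify_combined(x, y, rule) == "Tumor"


class TestConfusionMetrics:
    def test_all_correct(self):
        res = confusion_metrics(["Tumor", "Benign"], ["PDAC", "CP"])
        assert res.sensitivity == 100.0 and res.specificity == 100.0

    def test_counts_partition_the_cohort(self):
        pred = ["Tumor"] * 3 + ["Benign"] * 5
        truth = ["PDAC", "PDAC", "CP", "PDAC", "CP", "CP", "PDAC", "CP"]
        res = confusion_metrics(pred, truth)
        assert res.tp + res.fn + res.tn + res.fp == 8

    def test_unknown_labels_rejected(self):
        with pytest.raises(ValueError):
            confusion_metrics(["Tumor"], ["IPMN"])

    def test_half_up_rounding_to_one_decimal(self):
        from evmir.biomarker import ConfusionResult
        # 13/14 = 92.857... -> 92.9 under half-up rounding
        assert ConfusionResult(tp=1, fn=0, tn=13, fp=1).specificity == 92.9


class TestMetastasisCandidates:
    @staticmethod
    def _setup(seed=0, n=20):
        rng = np.random.default_rng(seed)
        cols = [f"P{i}" for i in range(n)]
        met = np.array(["M1"] * (n // 2) + ["M0"] * (n - n // 2))
        up = np.where(met == "M1", 400.0, 100.0) * rng.lognormal(0, 0.2, n)
        down = np.where(met == "M0", 400.0, 100.0) * rng.lognormal(0, 0.2, n)
        null = 200.0 * rng.lognormal(0, 0.2, n)
        norm = pd.DataFrame([up, down, null], index=["mUp", "mDown", "mNull"],
                            columns=cols)
        de = pd.DataFrame({
            "mean_m1": norm.loc[:, met == "M1"].mean(axis=1),
            "mean_m0": norm.loc[:, met == "M0"].mean(axis=1),
            "log2fc": [2.0, -2.0, 0.0],
            "p_value": [1e-4, 1e-4, 0.9],
            "fdr": [3e-4, 3e-4, 0.9],
            "expressed_in_all": True,
        }, index=norm.index)
        # survival tied to the up-marker: high marker -> short survival
        os_days = np.where(met == "M1", 150, 900) + rng.integers(0, 100, n)
        surv = pd.DataFrame({"os_days": os_days.astype(float),
                             "os_event": np.ones(n, dtype=bool)},
                            index=cols)
        return norm, met, surv, de

    def test_no_events_is_an_error(self):
        norm, met, surv, de = self._setup()
        surv["os_event"] = False
        with pytest.raises(ValueError, match="no events"):
            metastasis_candidates(norm, met, surv, de)

    def test_identical_survival_retains_nothing(self):
        norm, met, surv, de = self._setup()
        surv["os_days"] = 500.0
        ranked, ratios = metastasis_candidates(norm, met, surv, de)
        assert ranked.empty and ratios.empty

    def test_planted_pair_recovered(self):
        norm, met, surv, de = self._setup()
        ranked, ratios = metastasis_candidates(norm, met, surv, de)
        assert ranked.iloc[0]["mirna_id"] == "mUp"
        assert ratios.iloc[0]["denominator"] == "mDown"


def test_ratio_marker_invariants(default_norm, default_cohort):
    labels = default_cohort.samples["diagnosis"]
    r = ratio_values(default_norm.values, "miR-95-3p", "miR-26b-5p")
    pts = roc_curve(r, labels.loc[r.index], "PDAC")
    marker = RatioMarker("miR-95-3p", "miR-26b-5p", cutoff=0.06,
                         auc=auc(r, labels.loc[r.index], "PDAC"), roc_points=pts)
    area = np.trapezoid(pts[:, 1], pts[:, 0])
    assert area == pytest.approx(marker.auc, abs=1e-9)
    with pytest.raises(ValueError):
        RatioMarker("a", "b", cutoff=0.0)
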