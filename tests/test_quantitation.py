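"""Differential indices (DAVE, DCI, ln fold change) and the normality-
gated group tests."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from airwayprot.quantitation import (
    ClassMap,
    ScorePanel,
    class_mean_score,
    compare_groups,
    dave,
    dci,
    differential_table,
    group_mean_fold_change,
    ln_fold_change,
    round_half_up,
    significant_dave,
)

scores = st.floats(min_value=0.0, max_value=1e6, allow_nan=False)
positive_scores = st.floats(min_value=1e-3, max_value=1e6, allow_nan=False)


class TestDave:
    @pytest.mark.parametrize("ref,sample,expected", [
        (117.5, 0.0, -2.0),       # absent after treatment
        (0.0, 42.0, 2.0),         # absent at baseline
        (5.0, 74.0, 1.75),        # the non-responder smooth-muscle shift
        (265.0, 7.5, -1.89),      # the responder smooth-muscle collapse
        (7.0, 7.0, 0.0),
        (0.0, 0.0, 0.0),          # no evidence of change
    ])
    def test_reference_values(self, ref, sample, expected):
        assert round_half_up(dave(ref, sample), 2) == expected

    def test_rejects_negative(self):
        with pytest.raises(ValueError):
            dave(-1.0, 2.0)

    @given(a=scores, b=scores)
    @settings(derandomize=True)
    def test_antisymmetry_and_bounds(self, a, b):
        assert dave(a, b) == pytest.approx(-dave(b, a))
        assert abs(dave(a, b)) <= 2.0

    @given(a=positive_scores, b=positive_scores,
           k=st.floats(min_value=1e-3, max_value=1e3))
    @settings(derandomize=True)
    def test_scale_invariance(self, a, b, k):
        assert dave(k * a, k * b) == pytest.approx(dave(a, b), abs=1e-9)

    @given(a=st.one_of(st.just(0.0), positive_scores),
           b=st.one_of(st.just(0.0), positive_scores))
    @settings(derandomize=True)
    def test_bounds_attained_exactly_at_absence(self, a, b):
        """|DAVE| = 2 iff exactly one condition has score zero."""
        v = dave(a, b)
        if abs(v) == 2.0:
            assert (a == 0) != (b == 0)
        elif (a == 0) != (b == 0):
            assert abs(v) == 2.0


class TestDci:
    @pytest.mark.parametrize("ref,sample,expected", [
        (2.0, 4.0, 6.0),
        (4.0, 2.0, -6.0),
        (3.0, 3.0, 0.0),
    ])
    def test_closed_form(self, ref, sample, expected):
        assert dci(ref, sample) == pytest.approx(expected)

    @given(a=positive_scores, b=positive_scores)
    @settings(derandomize=True)
    def test_sign_agrees_with_dave(self, a, b):
        assert np.sign(dci(a, b)) == np.sign(dave(a, b))


class TestLnFoldChange:
    def test_zero_replacement_convention(self):
        assert ln_fold_change(30.0, 0.0) == pytest.approx(math.log(1 / 30))
        assert ln_fold_change(0.0, 30.0) == pytest.approx(math.log(30))
        assert ln_fold_change(0.0, 0.0) == 0.0
        assert ln_fold_change(7.0, 7.0) == 0.0

    def test_custom_replacement(self):
        assert ln_fold_change(30.0, 0.0, zero_replacement=0.5) == pytest.approx(
            math.log(0.5 / 30))
        with pytest.raises(ValueError):
            ln_fold_change(1.0, 1.0, zero_replacement=0.0)

    @given(t0=positive_scores, b1=positive_scores, b2=positive_scores)
    @settings(derandomize=True)
    def test_monotone_in_t36(self, t0, b1, b2):
        lo, hi = sorted([b1, b2])
        assert ln_fold_change(t0, lo) <= ln_fold_change(t0, hi)


class TestPanelAggregation:
    def test_keratin_group_mean(self, score_panel):
        assert class_mean_score(score_panel, None, "OR", "T0", "keratin") == 1892.25

    @pytest.mark.parametrize("cls,group,expected", [
        ("periostin", "OR", -4.6),
        ("keratin", "OR", -2.0),
        ("smooth_muscle", "NOR", 2.5),
        ("smooth_muscle", "OR", -4.1),
    ])
    def test_group_mean_fold_change_printed_values(self, score_panel, cls,
                                                   group, expected):
        assert round_half_up(
            group_mean_fold_change(score_panel, None, cls, group), 1) == expected

    def test_group_mean_invariant_to_patient_permutation(self, score_panel):
        """Shuffling patients within a group leaves the mean unchanged."""
        ref = group_mean_fold_change(score_panel, None, "smooth_muscle", "NOR")
        d = score_panel.data.copy()
        perm = {"NOR1": "NOR3", "NOR3": "NOR4", "NOR4": "NOR1"}
        d["patient_id"] = [perm.get(p, p) for p in d["patient_id"]]
        assert group_mean_fold_change(
            ScorePanel(d), None, "smooth_muscle", "NOR") == pytest.approx(ref)

    def test_sign_concordance_dave_vs_fold_change(self, score_panel):
        """Wherever the study panel shows a significant DAVE shift, the
        group-mean fold change points the same way.  (Near-zero shifts can
        disagree: the zero-replacement convention lets per-patient fold
        changes average to a different sign than the ratio of group means,
        e.g. the non-responder periostin row.)"""
        for cls in ["smooth_muscle", "keratin", "periostin", "galectin3"]:
            for group in ["OR", "NOR"]:
                a = class_mean_score(score_panel, None, group, "T0", cls)
                b = class_mean_score(score_panel, None, group, "T36", cls)
                d = dave(a, b)
                if not significant_dave(d):
                    continue
                fc = group_mean_fold_change(score_panel, None, cls, group)
                assert np.sign(d) == np.sign(fc)


class TestSignificantDave:
    @pytest.mark.parametrize("value,expected", [
        (0.4, False), (-0.4, False), (0.41, True), (-1.89, True), (0.0, False),
        (2.0, True),
    ])
    def test_strict_cutoff(self, value, expected):
        assert significant_dave(value) is expected


def _enumerated_ranksum_p(a, b):
    """Exact two-sided rank-sum p by exhausting all group assignments."""
    pooled = sorted(a) + sorted(b)
    n = len(a)
    ranks = {v: r for r, v in enumerate(sorted(pooled), start=1)}
    def u_stat(idx):
        r = sum(ranks[pooled[i]] for i in idx)
        return r - n * (n + 1) / 2
    u_obs = sum(ranks[v] for v in a) - n * (n + 1) / 2
    n1n2 = n * (len(b))
    dist = [u_stat(idx) for idx in itertools.combinations(range(len(pooled)), n)]
    lo, hi = min(u_obs, n1n2 - u_obs), max(u_obs, n1n2 - u_obs)
    return sum(1 for u in dist if u <= lo or u >= hi) / len(dist)


class TestCompareGroups:
    def test_identical_samples_p_one(self):
        with pytest.warns(UserWarning, match="identical"):
            res = compare_groups([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        assert res.p_value == 1.0

    def test_eosinophil_fold_change_significant(self, panel):
        """The responder vs non-responder eosinophil shift is significant."""
        orv = [ln_fold_change(a, b) for a, b in
               zip(panel.values("eosinophils", "T0", "OR"),
                   panel.values("eosinophils", "T36", "OR"))]
        nov = [ln_fold_change(a, b) for a, b in
               zip(panel.values("eosinophils", "T0", "NOR"),
                   panel.values("eosinophils", "T36", "NOR"))]
        res = compare_groups(orv, nov)
        assert res.p_value < 0.05

    def test_ranksum_matches_enumeration(self):
        """Exact Wilcoxon rank-sum at n=4 vs 4 equals the 70-assignment
        enumeration."""
        rng = np.random.default_rng(7)
        for _ in range(5):
            # heavy-tailed draws fail the normality gate reliably
            a = list(np.round(rng.standard_cauchy(4) * 10, 3))
            b = list(np.round(rng.standard_cauchy(4) * 10 + 5, 3))
            res = compare_groups(a, b)
            if res.test_name != "wilcoxon":
                continue
            assert res.p_value == pytest.approx(_enumerated_ranksum_p(a, b))

    def test_welch_matches_closed_form(self):
        """Welch statistic/df/p recomputed from the textbook formulas."""
        from scipy import stats

        a = [27.5, 21.0, 19.0, 23.6, 17.0, 17.9, 16.9, 20.1]
        b = [27.1, 22.0, 20.8, 23.4, 23.4, 23.5, 25.8, 22.0]
        res = compare_groups(a, b)
        assert res.test_name == "t"
        va, vb = np.var(a, ddof=1) / len(a), np.var(b, ddof=1) / len(b)
        t = (np.mean(a) - np.mean(b)) / math.sqrt(va + vb)
        df = (va + vb) ** 2 / (va ** 2 / (len(a) - 1) + vb ** 2 / (len(b) - 1))
        p = 2 * stats.t.sf(abs(t), df)
        assert res.statistic == pytest.approx(t, abs=1e-6)
        assert res.p_value == pytest.approx(p, abs=1e-6)

    def test_zero_variance_reported(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            compare_groups([2.0, 2.0, 2.0, 2.0], [1.0, 3.0, 5.0, 7.0])

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([1.0], [2.0])


class TestClassMap:
    @pytest.mark.parametrize("label,expected", [
        ("Myosin-11", "smooth_muscle"),
        ("TROPOMYOSIN alpha-1", "smooth_muscle"),
        ("Keratin, type II cytoskeletal 1", "keratin"),
        ("Periostin precursor", "periostin"),
        ("Galectin-3", "galectin3"),
        ("LGALS3", "galectin3"),
        ("Collagen alpha-1(I)", "ecm"),
        ("Serum albumin", "other"),
    ])
    def test_default_patterns(self, label, expected):
        assert ClassMap().assign(label) == expected


def test_differential_table_on_study_panel(score_panel):
    table = differential_table(score_panel)
    table = table.set_index(["label", "group"])
    row = table.loc[("smooth_muscle", "OR")]
    assert round_half_up(row["dave"], 2) == -1.89
    assert row["significant_dave"]
    assert round_half_up(table.loc[("keratin", "OR")]["dave"], 2) == -1.45
    assert round_half_up(table.loc[("periostin", "OR")]["dave"], 1) == -2.0
    assert round_half_up(table.loc[("smooth_muscle", "NOR")]["dave"], 2) == 1.75
    assert not table.loc[("keratin", "NOR")]["significant_dave"]  # |-0.34| < 0.4
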