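"""Diagnostic accuracy statistics: 2×2 summaries, Fisher, ROC, correlation,
group comparisons and Bland–Altman agreement."""

import itertools
import math
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rhcmr.stats import (
    Direction,
    Group,
    PatientRecord,
    ThresholdRule,
    binary_test_auc,
    bland_altman,
    classify,
    confusion_counts,
    confusion_metrics,
    fisher_exact_p,
    group_compare,
    pearson_r,
    ppv_from_sens_spec,
    roc_auc,
)
from rhcmr.units import round_half_up


def fisher_enumeration(a, b, c, d):
    """Independent oracle: exhaustive two-sided Fisher p with fixed margins."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0
    denom = comb(n, c1)

    def prob(x):
        return comb(r1, x) * comb(r2, c1 - x) / denom

    p_obs = prob(a)
    return min(
        1.0,
        sum(prob(x) for x in range(max(0, c1 - r2), min(r1, c1) + 1) if prob(x) <= p_obs * (1 + 1e-12)),
    )


def record(pid, mpap, **metrics):
    return PatientRecord(
        patient_id=pid,
        group=Group.PH if mpap >= 25 else Group.NO_PH,
        mpap=mpap,
        metrics=metrics,
    )


class TestClassify:
    @pytest.mark.parametrize(
        "value,cut,direction,expected",
        [
            (0.41, 0.4, Direction.GE_POSITIVE, True),
            (0.40, 0.4, Direction.GE_POSITIVE, True),  # boundary inclusive
            (0.39, 0.4, Direction.GE_POSITIVE, False),
            (2.0, 2.0, Direction.LE_POSITIVE, True),
            (2.1, 2.0, Direction.LE_POSITIVE, False),
        ],
    )
    def test_boundary_semantics(self, value, cut, direction, expected):
        rule = ThresholdRule("vmi", cut, direction)
        assert classify(rule, record("p", 40.0, vmi=value)) is expected

    def test_missing_metric_excludes_record(self):
        rule = ThresholdRule("vmi", 0.4, Direction.GE_POSITIVE)
        assert classify(rule, record("p", 40.0, tapse=1.0)) is None
        counts = confusion_counts(rule, [record("a", 40.0), record("b", 10.0, vmi=0.2)])
        assert counts == (0, 0, 0, 1)


class TestConfusionMetrics:
    def test_published_lge_counts(self):
        res = confusion_metrics(tp=108, fp=2, fn=20, tn=29)
        assert round_half_up(res.ppv) == 98
        assert round_half_up(res.sensitivity) == 84  # 108/128
        assert round_half_up(res.specificity) == 94  # 29/31

    def test_symmetric_table_gives_fifty_fifty(self):
        res = confusion_metrics(tp=10, fp=7, fn=10, tn=7)
        assert res.sensitivity == pytest.approx(50.0)
        assert res.specificity == pytest.approx(50.0)

    def test_perfect_test(self):
        res = confusion_metrics(tp=20, fp=0, fn=0, tn=10)
        assert (res.sensitivity, res.specificity, res.ppv, res.npv) == (100, 100, 100, 100)
        assert res.auc == 1.0

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        tp=st.integers(0, 50), fp=st.integers(0, 50), fn=st.integers(0, 50), tn=st.integers(0, 50)
    )
    def test_bayes_ppv_consistency(self, tp, fp, fn, tn):
        """PPV from counts equals s·p/(s·p + (1−c)(1−p)) at the table's prevalence."""
        if tp + fn == 0 or fp + tn == 0 or tp + fp == 0:
            return
        res = confusion_metrics(tp, fp, fn, tn)
        n = tp + fp + fn + tn
        expected = ppv_from_sens_spec(res.sensitivity, res.specificity, tp + fn, fp + tn)
        assert res.ppv == pytest.approx(expected, abs=1e-9)


class TestFisherExact:
    def test_small_table_frozen_value(self):
        # exhaustive enumeration of [[3,1],[1,3]]: p = 0.4857142857...
        assert fisher_exact_p(3, 1, 1, 3) == pytest.approx(0.4857142857142857, abs=1e-12)

    def test_degenerate_margin(self):
        assert fisher_exact_p(0, 0, 5, 7) == 1.0

    def test_perfectly_separated_table(self):
        # doubled single tail 2/C(20,10)
        assert fisher_exact_p(10, 0, 0, 10) == pytest.approx(2 / 184756, rel=1e-9)
        assert fisher_exact_p(10, 0, 0, 10) < 0.001

    def test_agrees_with_enumeration_for_all_small_tables(self):
        for n in range(1, 17):
            for a, b, c in itertools.combinations_with_replacement(range(n + 1), 3):
                d = n - a - b - c
                if d < 0:
                    continue
                assert fisher_exact_p(a, b, c, d) == pytest.approx(
                    fisher_enumeration(a, b, c, d), abs=1e-9
                ), (a, b, c, d)

    def test_agrees_with_enumeration_for_random_tables_up_to_n30(self):
        rng = np.random.default_rng(17)
        for _ in range(200):
            n = int(rng.integers(4, 31))
            cuts = np.sort(rng.integers(0, n + 1, size=3))
            a, b, c = cuts[0], cuts[1] - cuts[0], cuts[2] - cuts[1]
            d = n - a - b - c
            assert fisher_exact_p(a, b, c, d) == pytest.approx(
                fisher_enumeration(a, b, c, d), abs=1e-9
            )


class TestRocAuc:
    def test_perfect_separation(self):
        v = [1, 2, 3, 10, 11, 12]
        labels = [False] * 3 + [True] * 3
        assert roc_auc(v, labels, Direction.GE_POSITIVE) == 1.0
        assert roc_auc(v, labels, Direction.LE_POSITIVE) == 0.0

    def test_all_tied_values(self):
        assert roc_auc([5.0] * 6, [True, False] * 3, Direction.GE_POSITIVE) == 0.5

    def test_binary_marker_equals_half_sens_plus_spec(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            labels = rng.random(60) < 0.6
            marker = rng.random(60) < np.where(labels, 0.8, 0.2)
            tp = int((marker & labels).sum())
            fp = int((marker & ~labels).sum())
            fn = int((~marker & labels).sum())
            tn = int((~marker & ~labels).sum())
            if tp + fn == 0 or fp + tn == 0:
                continue
            assert roc_auc(marker.astype(float), labels, Direction.GE_POSITIVE) == pytest.approx(
                binary_test_auc(tp, fp, fn, tn), abs=1e-12
            )

    def test_matches_sklearn_on_random_data(self):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(9)
        labels = rng.random(200) < 0.5
        values = rng.normal(loc=np.where(labels, 1.0, 0.0))
        ours = roc_auc(values, labels, Direction.GE_POSITIVE)
        ref = sklearn_metrics.roc_auc_score(labels, values)
        assert ours == pytest.approx(ref, abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(5)
        labels = rng.random(100) < 0.4
        values = rng.normal(np.where(labels, 0.5, 0.0))
        base = roc_auc(values, labels, Direction.GE_POSITIVE)
        for f in (np.exp, np.tanh, lambda v: v**3 + 5 * v):
            assert roc_auc(f(values), labels, Direction.GE_POSITIVE) == pytest.approx(base, abs=1e-12)


class TestBinaryTestAuc:
    def test_published_lge_auc(self):
        assert round_half_up(binary_test_auc(108, 2, 20, 29), 2) == pytest.approx(0.89)

    def test_useless_test(self):
        # sens = 1 - spec = 0.6
        assert binary_test_auc(6, 6, 4, 4) == pytest.approx(0.5)

    def test_perfect_counts(self):
        assert binary_test_auc(12, 0, 0, 8) == 1.0


class TestPearson:
    def test_affine_relationships(self):
        x = np.arange(10.0)
        assert pearson_r(x, 2 * x + 1)[0] == pytest.approx(1.0)
        assert pearson_r(x, -x)[0] == pytest.approx(-1.0)

    def test_bivariate_normal_sampling_distribution(self):
        """Sample r at rho=0.78, n=233 falls in the Fisher-z 95% band nearly always."""
        rng = np.random.default_rng(12)
        rho, n = 0.78, 233
        inside = 0
        trials = 200
        for _ in range(trials):
            z1 = rng.standard_normal(n)
            z2 = rho * z1 + math.sqrt(1 - rho**2) * rng.standard_normal(n)
            r, _ = pearson_r(z1, z2)
            inside += 0.70 <= r <= 0.84
        assert inside / trials >= 0.95


class TestGroupCompare:
    def test_identical_groups_t_zero(self):
        vals = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        groups = ["A"] * 3 + ["B"] * 3
        res = group_compare(vals, groups)
        assert res.test == "t"
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_separated_groups_significant(self):
        rng = np.random.default_rng(0)
        vals = np.concatenate([rng.normal(0, 1, 50), rng.normal(5, 1, 50)])
        groups = ["A"] * 50 + ["B"] * 50
        assert group_compare(vals, groups).p_value < 0.001

    def test_five_subgroups_yield_ten_bonferroni_pairs(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(size=100)
        groups = [f"G{i % 5}" for i in range(100)]
        res = group_compare(vals, groups)
        assert res.test == "anova"
        assert len(res.pairwise) == 10
        assert all(0 < p <= 1 for p in res.pairwise.values())

    def test_categorical_chi_square(self):
        vals = ["yes"] * 30 + ["no"] * 10 + ["yes"] * 10 + ["no"] * 30
        groups = ["A"] * 40 + ["B"] * 40
        res = group_compare(vals, groups, categorical=True)
        assert res.test == "chi2"
        assert res.p_value < 0.001


class TestBlandAltman:
    def test_published_limits_of_agreement(self):
        """A sample with bias −2.1 g and SD 10.8 g gives LoA (−23.3, 19.1) to 1 dp."""
        rng = np.random.default_rng(8)
        z = rng.standard_normal(40)
        z = (z - z.mean()) / z.std(ddof=1)  # exact sample moments
        diffs = -2.1 + 10.8 * z
        obs2 = rng.normal(100, 20, size=40)
        res = bland_altman(obs2 + diffs, obs2)
        assert res.bias == pytest.approx(-2.1, abs=1e-9)
        assert res.sd_diff == pytest.approx(10.8, abs=1e-9)
        assert round_half_up(res.loa_low, 1) == pytest.approx(-23.3)
        assert round_half_up(res.loa_high, 1) == pytest.approx(19.1)

    def test_identical_observers(self):
        res = bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.bias == 0 and res.loa_low == 0 and res.loa_high == 0

    def test_constant_offset(self):
        res = bland_altman([4.0, 5.0, 6.0], [1.0, 2.0, 3.0])
        assert res.bias == pytest.approx(3.0)
        assert res.sd_diff == pytest.approx(0.0)


def test_patient_record_group_must_match_mpap():
    with pytest.raises(ValueError):
        PatientRecord(patient_id="x", group=Group.NO_PH, mpap=30.0)
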