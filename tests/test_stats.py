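"""ROC/AUC, cut-offs, 2x2 metrics, kappa, nonparametric tests, responder rule."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pvrkit.errors import ValidationError
from pvrkit.stats import (
    chi_square,
    cohens_kappa,
    contingency,
    evaluate_cohort,
    kruskal_wallis,
    mann_whitney_u,
    revasc_response,
    roc,
    youden_cutoff,
)
from tests.conftest import pairwise_auc


class TestROC:
    def test_perfect_separation(self):
        assert roc([1, 2, 3, 4], [0, 0, 1, 1], n_boot=50).auc == 1.0

    def test_toy_example_matches_pairwise_oracle(self):
        scores, labels = [1, 2, 3, 4], [1, 0, 1, 0]
        r = roc(scores, labels, n_boot=50)
        assert r.auc == pytest.approx(pairwise_auc(scores, labels))  # = 0.25

    def test_direction_symmetry(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=40)
        labels = rng.integers(0, 2, size=40)
        labels[0], labels[1] = 0, 1
        hi = roc(scores, labels, "higher_is_disease", n_boot=10).auc
        lo = roc(scores, labels, "lower_is_disease", n_boot=10).auc
        assert hi + lo == pytest.approx(1.0)

    @given(st.integers(0, 1000))
    @settings(deadline=None, derandomize=True, max_examples=25)
    def test_auc_equals_pairwise_counting_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 200))
        scores = np.round(rng.normal(size=n), 1)  # coarse grid forces ties
        labels = rng.integers(0, 2, size=n)
        labels[:2] = [0, 1]
        r = roc(scores, labels, n_boot=1)
        assert r.auc == pytest.approx(pairwise_auc(scores, labels), abs=1e-12)

    def test_roc_curve_monotone(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(size=120)
        labels = (rng.random(120) < 0.4).astype(int)
        r = roc(scores, labels, n_boot=10)
        assert np.all(np.diff(r.sens) >= 0)  # sens grows as threshold loosens
        assert np.all(np.diff(r.spec) <= 0)

    def test_ci_brackets_auc_and_is_seeded(self):
        rng = np.random.default_rng(5)
        scores = np.concatenate([rng.normal(1, 1, 30), rng.normal(0, 1, 30)])
        labels = np.concatenate([np.ones(30, int), np.zeros(30, int)])
        r1 = roc(scores, labels, n_boot=200, seed=42)
        r2 = roc(scores, labels, n_boot=200, seed=42)
        assert r1.auc_ci_low <= r1.auc <= r1.auc_ci_high
        assert (r1.auc_ci_low, r1.auc_ci_high) == (r2.auc_ci_low, r2.auc_ci_high)

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            roc([1, 2, 3], [1, 1, 1])


class TestYouden:
    def test_perfect_classifier(self):
        r = roc([1, 2, 3, 4], [0, 0, 1, 1], n_boot=10)
        thr, sens, spec = youden_cutoff(r)
        assert sens == 1.0 and spec == 1.0
        assert 2 < thr <= 3

    def test_exhaustive_scan_oracle(self):
        rng = np.random.default_rng(8)
        scores = rng.normal(size=50)
        labels = (rng.random(50) < 0.5).astype(int)
        labels[:2] = [0, 1]
        r = roc(scores, labels, n_boot=10)
        thr, sens, spec = youden_cutoff(r)
        # brute force over all distinct thresholds
        best = max(
            (np.mean(scores[labels == 1] >= t) + np.mean(scores[labels == 0] < t) - 1)
            for t in np.unique(scores)
        )
        assert sens + spec - 1 == pytest.approx(best, abs=1e-12)


class TestContingency:
    def test_reference_table(self):
        m = contingency(9, 0, 1, 10)
        assert m.sensitivity == 0.9 and m.specificity == 1.0

    def test_undefined_ratio_is_absent_not_zero(self):
        m = contingency(0, 0, 5, 5)
        assert m.sensitivity == 0.0
        assert m.ppv is None

    @given(st.tuples(*[st.integers(0, 30)] * 4))
    @settings(deadline=None, derandomize=True, max_examples=50)
    def test_random_tables_match_direct_formulas(self, counts):
        tp, fp, fn, tn = counts
        m = contingency(tp, fp, fn, tn)
        assert m.sensitivity == (tp / (tp + fn) if tp + fn else None)
        assert m.specificity == (tn / (tn + fp) if tn + fp else None)
        assert m.ppv == (tp / (tp + fp) if tp + fp else None)
        assert m.npv == (tn / (tn + fn) if tn + fn else None)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValidationError):
            contingency(-1, 0, 0, 0)


class TestKappa:
    def test_perfect_agreement(self):
        k = cohens_kappa(["a", "b", "a"], ["a", "b", "a"])
        assert k.kappa == 1.0

    def test_worked_confusion_matrix(self):
        # confusion matrix [[20, 5], [10, 15]] -> po 0.7, pe 0.5, kappa 0.4
        a = ["x"] * 25 + ["y"] * 25
        b = ["x"] * 20 + ["y"] * 5 + ["x"] * 10 + ["y"] * 15
        k = cohens_kappa(a, b)
        assert k.observed_agreement == pytest.approx(0.7)
        assert k.expected_agreement == pytest.approx(0.5)
        assert k.kappa == pytest.approx(0.4)

    def test_constant_rater_gives_zero_kappa(self):
        a = ["x", "y", "x", "y"]
        b = ["x", "x", "x", "x"]
        k = cohens_kappa(a, b)
        assert k.observed_agreement == pytest.approx(k.expected_agreement)
        assert k.kappa == pytest.approx(0.0)

    def test_matches_sklearn_reference(self):
        from sklearn.metrics import cohen_kappa_score

        rng = np.random.default_rng(17)
        cats = ["normal", "mildly_abnormal", "severely_abnormal", "non_pulsatile"]
        a = rng.choice(cats, 80)
        b = np.where(rng.random(80) < 0.6, a, rng.choice(cats, 80))
        k = cohens_kappa(a, b, categories=cats)
        assert k.kappa == pytest.approx(cohen_kappa_score(a, b), abs=1e-12)
        assert k.kappa <= k.observed_agreement

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            cohens_kappa([], [])


class TestNonparametric:
    def test_identical_samples_give_p_near_one(self):
        x = np.arange(30.0)
        u, p = mann_whitney_u(x, x + 0.0)
        assert p > 0.9

    def test_complete_separation_u_zero(self):
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0.0

    def test_exact_p_equals_enumeration_oracle(self):
        x = [1.2, 3.4, 2.2, 5.0]
        y = [2.5, 4.1, 6.0]
        u_obs, p_exact = mann_whitney_u(x, y, method="exact")

        # full enumeration of group assignments
        pooled = np.array(x + y)
        nx = len(x)
        stats = []
        from scipy.stats import mannwhitneyu

        for idx in itertools.combinations(range(len(pooled)), nx):
            mask = np.zeros(len(pooled), bool)
            mask[list(idx)] = True
            stats.append(
                mannwhitneyu(pooled[mask], pooled[~mask],
                             alternative="two-sided", method="asymptotic").statistic
            )
        stats = np.array(stats)
        n = len(x) * len(y)
        dev = np.abs(stats - n / 2)
        p_oracle = np.mean(dev >= abs(u_obs - n / 2) - 1e-12)
        assert p_exact == pytest.approx(p_oracle, abs=1e-9)

    def test_exact_and_asymptotic_agree_at_moderate_n(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, 20)
        y = rng.normal(0.5, 1, 20)
        _, p_asym = mann_whitney_u(x, y, method="asymptotic")
        assert 0 <= p_asym <= 1

    def test_kruskal_and_chi_square_basic(self):
        h, p = kruskal_wallis([[1, 2, 3, 9], [4, 5, 6, 2], [7, 8, 9, 1]])
        assert 0 <= p <= 1
        stat, p2 = chi_square([[20, 10], [5, 25]])
        assert p2 < 0.01

    def test_all_tied_data_rejected(self):
        with pytest.raises(ValidationError):
            mann_whitney_u([1, 1, 1], [1, 1, 1])
        with pytest.raises(ValidationError):
            kruskal_wallis([[2, 2], [2, 2]])


class TestRevascResponse:
    def test_clean_separation(self):
        pre = [0.2, 0.3, 0.2, 0.4]
        post = [0.5, 0.6, 0.2, 0.4]
        m = revasc_response(pre, post, [True, True, False, False])
        assert m.sensitivity == 1.0 and m.specificity == 1.0

    def test_threshold_is_inclusive(self):
        m = revasc_response([0.2], [0.3], [True])
        assert m.tp == 1  # delta of exactly 0.1 counts as response

    def test_simulated_sensitivity_matches_reported_moments(self):
        """Success deltas ~ N(0.24, 0.26), failures ~ N(-0.07, 0.3); n = 35/9."""
        rng = np.random.default_rng(99)
        sens = []
        for _ in range(1000):
            d_s = rng.normal(0.24, 0.26, 35)
            d_f = rng.normal(-0.07, 0.3, 9)
            pre = np.zeros(44)
            post = np.concatenate([d_s, d_f])
            m = revasc_response(pre, post, [True] * 35 + [False] * 9)
            sens.append(m.sensitivity)
        assert 0.5 <= np.mean(sens) <= 0.8

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            revasc_response([1, 2], [1], [True])


class TestEvaluateCohort:
    def test_report_structure_and_exclusions(self):
        from pvrkit.cohort import default_config, simulate_cohort

        records = simulate_cohort(default_config(), scale=2, seed=1)
        rep = evaluate_cohort(records, n_boot=20, seed=1)
        assert rep["n_limbs"] == 180
        assert rep["n_non_pulsatile"] == 12
        assert rep["n_analyzed"] == 168
        feats = rep["endpoints"]["any_pad"]["features"]
        assert feats["msa_mmhg"]["direction"] == "lower_is_disease"
        assert feats["ust_ms"]["direction"] == "higher_is_disease"
        for f in feats.values():
            assert f["auc_ci_low"] <= f["auc"] <= f["auc_ci_high"]

    def test_single_class_stratum_is_skipped_explicitly(self):
        import pandas as pd

        frame = pd.DataFrame(
            {
                "limb_id": ["a", "b"],
                "glass_stage": ["0", "0"],
                "imd": ["P0", "P0"],
                "ust_ms": [220, 250],
                "usr": [0.28, 0.3],
                "msa_mmhg": [1.0, 0.8],
                "pulsatile": [True, True],
                "abi_ge_1_3": [True, False],
                "infection": [False, False],
            }
        )
        rep = evaluate_cohort(frame, endpoints=("any_pad",), n_boot=5)
        assert "skipped" in rep["endpoints"]["any_pad"]

    def test_unknown_subgroup_rejected(self):
        from pvrkit.cohort import default_config, simulate_cohort

        records = simulate_cohort(default_config(), scale=1, seed=1)
        with pytest.raises(ValidationError):
            evaluate_cohort(records, subgroup="no_such_column", n_boot=5)
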