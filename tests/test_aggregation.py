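"""Majority vote, regression aggregation, identity alerts and metrics."""

import numpy as np
import pytest

from petguard import Demographics
from petguard.aggregation import (
    PatientPrediction,
    age_bin,
    aggregate_regression,
    check_identity,
    evaluate,
    majority_vote,
    weight_bin,
)
from petguard.errors import ConfigurationError, EmptyInputError


def _probs(n_male, n_female, p=0.9):
    rows = [[p, 1 - p]] * n_male + [[1 - p, p]] * n_female
    return np.array(rows)


class TestMajorityVote:
    def test_ten_to_nine_split(self):
        label, frac, _, tie = majority_vote(_probs(10, 9))
        assert label == "male"
        assert frac == pytest.approx(10 / 19)
        assert not tie

    def test_unanimous(self):
        label, frac, _, tie = majority_vote(_probs(0, 36))
        assert (label, frac, tie) == ("female", 1.0, False)

    def test_tie_broken_by_mean_probability(self):
        # 18/18 split, but the male votes are more confident on average
        rows = [[0.6, 0.4]] * 18 + [[0.45, 0.55]] * 18
        label, frac, mean_p, tie = majority_vote(np.array(rows))
        # oracle: summed P(male) = 18*0.6 + 18*0.45 > half the total
        assert label == "male" and tie
        assert frac == pytest.approx(0.5)

    def test_agrees_with_counting_oracle(self, rng):
        for _ in range(1000):
            n = int(rng.integers(1, 40))
            p = rng.random(n)
            probs = np.column_stack([p, 1 - p])
            label, frac, _, tie = majority_vote(probs)
            males = int((p > 0.5).sum()) + int(((p == 0.5) & False).sum())
            females = n - int((p > 0.5).sum())
            if males > females:
                expect = "male"
            elif females > males:
                expect = "female"
            else:
                expect = "male" if p.mean() >= 0.5 else "female"
            assert label == expect
            assert frac == pytest.approx(max(males, females) / n)
            assert tie == (males == females)

    def test_odd_view_counts_cannot_tie(self, rng):
        for _ in range(200):
            p = rng.random(19)
            *_, tie = majority_vote(np.column_stack([p, 1 - p]))
            assert not tie

    def test_empty_rejected(self):
        with pytest.raises(EmptyInputError):
            majority_vote([])


class TestAggregateRegression:
    def test_median(self):
        assert aggregate_regression([60, 61, 62]) == 61

    def test_single(self):
        assert aggregate_regression([70]) == 70

    def test_median_robust_to_outlier_view(self):
        assert aggregate_regression([50, 50, 90]) == 50
        assert aggregate_regression([50, 50, 90], method="mean") == pytest.approx(63.333, abs=0.01)

    def test_empty_rejected(self):
        with pytest.raises(EmptyInputError):
            aggregate_regression([])


class TestCheckIdentity:
    def _pred(self, sex="male", age=60.0, weight=70.0):
        return PatientPrediction(
            patient_id="P1", sex_label=sex, age_estimate=age, weight_estimate=weight, n_images=19
        )

    def test_exact_match_no_flags(self):
        rep = check_identity(self._pred(), Demographics("male", 60, 70))
        assert not rep.any_mismatch

    def test_sex_mismatch(self):
        rep = check_identity(self._pred(sex="female"), Demographics("male", 60, 70))
        assert rep.sex_mismatch is True

    def test_age_outside_ten_years_flags(self):
        rep = check_identity(self._pred(age=75.0), Demographics("male", 60, 70))
        assert rep.age_mismatch is True
        rep = check_identity(self._pred(age=69.0), Demographics("male", 60, 70))
        assert rep.age_mismatch is False

    def test_missing_claim_is_unverifiable_not_pass(self):
        rep = check_identity(self._pred(), {"sex": "male", "age": None, "weight": 70.0})
        assert rep.age_mismatch is None
        assert "unverifiable" in rep.details


class TestBins:
    @pytest.mark.parametrize(
        "age,idx", [(9, 0), (10, 0), (11, 1), (12, 1), (15, 1), (16, 2), (86, 16), (90, 16), (91, 17), (95, 17)]
    )
    def test_age_bins(self, age, idx):
        assert age_bin(age) == idx

    @pytest.mark.parametrize("w,idx", [(25, 0), (30, 0), (31, 1), (35, 1), (36, 2), (90, 12), (91, 13), (95, 13)])
    def test_weight_bins(self, w, idx):
        assert weight_bin(w) == idx


class TestEvaluate:
    def _setup(self, n=10):
        truths = {
            f"P{i}": Demographics("male" if i % 2 else "female", 40.0 + i, 60.0 + i)
            for i in range(n)
        }
        preds = [
            PatientPrediction(
                patient_id=pid,
                sex_label=d.sex,
                age_estimate=d.age,
                weight_estimate=d.weight,
                n_images=3,
                view_labels=[d.sex] * 3,
            )
            for pid, d in truths.items()
        ]
        return preds, truths

    def test_perfect_predictions(self):
        preds, truths = self._setup()
        rep = evaluate(preds, truths)
        assert rep.patient_accuracy == 1.0
        assert rep.image_accuracy == 1.0
        assert rep.per_sex_accuracy == {"male": 1.0, "female": 1.0}
        assert rep.within_tolerance_fractions["age_within_10y"] == 1.0
        assert np.all(rep.age_confusion == np.diag(rep.age_confusion.diagonal()))

    def test_confusion_row_sums_match_truth_counts(self):
        preds, truths = self._setup(12)
        rep = evaluate(preds, truths)
        from collections import Counter

        truth_bins = Counter(age_bin(d.age) for d in truths.values())
        for b, cnt in truth_bins.items():
            assert rep.age_confusion[b].sum() == cnt

    def test_id_mismatch_rejected(self):
        preds, truths = self._setup()
        del truths["P0"]
        with pytest.raises(ConfigurationError):
            evaluate(preds, truths)
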