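"""Metric implementations against independent brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from symptomnet.evaluation import (
    TrainStats,
    UndefinedDenominatorError,
    evaluate,
    f1_scores,
    ma_mae,
    mae,
    read_predictions,
    rrmse,
    write_predictions,
)
from symptomnet.transcripts import SYMPTOM_KEYS, SymptomProfile, ValidationError


# -- independent oracles (simple loops, no vectorisation) -------------------

def mae_oracle(pred, gold):
    total = 0.0
    for p, g in zip(pred, gold):
        total += abs(p - g)
    return total / len(pred)


def f1_oracle(pred, gold, classes):
    tp_all = fp_all = fn_all = 0
    per_class = []
    for c in classes:
        tp = fp = fn = 0
        for p, g in zip(pred, gold):
            if p == c and g == c:
                tp += 1
            elif p == c:
                fp += 1
            elif g == c:
                fn += 1
        tp_all, fp_all, fn_all = tp_all + tp, fp_all + fp, fn_all + fn
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        per_class.append(2 * prec * rec / (prec + rec) if prec + rec else 0.0)
    prec = tp_all / (tp_all + fp_all) if tp_all + fp_all else 0.0
    rec = tp_all / (tp_all + fn_all) if tp_all + fn_all else 0.0
    micro = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
    return micro, sum(per_class) / len(per_class)


def rrmse_oracle(pred, gold, mean):
    num = den = 0.0
    for p, g in zip(pred, gold):
        num += (p - g) ** 2
        den += (g - mean) ** 2
    return (num / den) ** 0.5


class TestMae:
    def test_perfect_predictions(self):
        assert mae([1, 2, 3], [1, 2, 3]) == 0.0

    def test_hand_computed(self):
        assert mae([1, 2], [0, 4]) == pytest.approx(1.5)

    def test_against_loop_oracle_on_random_instances(self, rng):
        for _ in range(30):
            n = int(rng.integers(1, 200))
            pred = rng.uniform(0, 24, n)
            gold = rng.uniform(0, 24, n)
            assert mae(pred, gold) == pytest.approx(mae_oracle(pred, gold), abs=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            mae([], [])


class TestMaMae:
    def test_two_classes_average(self):
        pred = [1.0, 1.0, 5.0]
        gold = [0.0, 0.0, 2.0]  # class A MAE 1, class B MAE 3
        assert ma_mae(pred, gold, ["a", "a", "b"]) == pytest.approx(2.0)

    def test_single_class_reduces_to_mae(self, rng):
        pred, gold = rng.uniform(0, 10, 50), rng.uniform(0, 10, 50)
        assert ma_mae(pred, gold, ["x"] * 50) == pytest.approx(mae(pred, gold))

    def test_equal_sized_classes_equal_mae_identity(self, rng):
        """With equally occupied classes of equal per-class MAE structure,
        random within-class permutations leave maMAE fixed while a direct
        oracle confirms the unweighted-average definition."""
        labels = np.repeat(np.arange(5), 20)
        gold = rng.uniform(0, 24, 100)
        pred = gold + rng.standard_normal(100)
        by_class = [mae_oracle(pred[labels == c], gold[labels == c]) for c in range(5)]
        assert ma_mae(pred, gold, labels) == pytest.approx(np.mean(by_class), abs=1e-12)
        perm = rng.permutation(100)
        # permuting items together with their labels changes nothing
        assert ma_mae(pred[perm], gold[perm], labels[perm]) == pytest.approx(
            ma_mae(pred, gold, labels), abs=1e-12
        )

    def test_accepts_callable_class_of(self):
        assert ma_mae([1, 9], [0, 10], lambda g: g >= 5) == pytest.approx(1.0)


class TestF1:
    def test_perfect_and_allwrong(self):
        assert f1_scores([0, 1], [0, 1], (0, 1)) == (1.0, 1.0)
        assert f1_scores([1, 0], [0, 1], (0, 1)) == (0.0, 0.0)

    def test_three_class_confusion_matches_counting_oracle(self):
        gold = ["A"] * 10 + ["B"] * 5 + ["C"] * 5
        pred = ["A"] * 8 + ["B"] * 2 + ["B"] * 3 + ["C"] * 2 + ["C"] * 5
        mine = f1_scores(pred, gold, ("A", "B", "C"))
        oracle = f1_oracle(pred, gold, ("A", "B", "C"))
        assert mine == pytest.approx(oracle, abs=1e-12)

    def test_label_outside_classes_rejected(self):
        with pytest.raises(ValidationError):
            f1_scores([0, 2], [0, 1], (0, 1))

    @given(
        st.lists(st.integers(0, 3), min_size=1, max_size=60),
        st.integers(0, 2**31 - 1),
    )
    @settings(deadline=None, max_examples=60, derandomize=True)
    def test_micro_f1_equals_accuracy_for_single_label(self, gold, seed):
        rng = np.random.default_rng(seed)
        pred = rng.integers(0, 4, size=len(gold)).tolist()
        micro, _ = f1_scores(pred, gold, (0, 1, 2, 3))
        accuracy = np.mean([p == g for p, g in zip(pred, gold)])
        assert micro == pytest.approx(accuracy, abs=1e-12)

    def test_against_oracle_on_random_instances(self, rng):
        for _ in range(50):
            n = int(rng.integers(2, 100))
            k = int(rng.integers(2, 6))
            pred = rng.integers(0, k, n).tolist()
            gold = rng.integers(0, k, n).tolist()
            assert f1_scores(pred, gold, tuple(range(k))) == pytest.approx(
                f1_oracle(pred, gold, tuple(range(k))), abs=1e-12
            )


class TestRrmse:
    def test_perfect_predictions(self):
        assert rrmse([1, 2, 3], [1, 2, 3], 2.0) == 0.0

    def test_mean_predictor_on_training_set_is_exactly_one(self, rng):
        gold = rng.integers(0, 4, 50).astype(float)
        pred = np.full(50, gold.mean())
        assert rrmse(pred, gold, gold.mean()) == pytest.approx(1.0, abs=1e-12)

    def test_worse_than_mean_predictor_exceeds_one(self, rng):
        gold = rng.integers(0, 4, 50).astype(float)
        mean = gold.mean()
        shift = 2 * np.abs(gold - mean).max()
        assert rrmse(gold + shift, gold, mean) > 1.0

    def test_scale_consistency(self, rng):
        pred, gold = rng.uniform(0, 3, 30), rng.uniform(0, 3, 30)
        base = rrmse(pred, gold, 1.5)
        assert rrmse(7 * pred, 7 * gold, 7 * 1.5) == pytest.approx(base, rel=1e-12)

    def test_constant_gold_at_mean_is_undefined(self):
        with pytest.raises(UndefinedDenominatorError):
            rrmse([1, 1], [2, 2], 2.0)

    def test_against_loop_oracle(self, rng):
        for _ in range(30):
            n = int(rng.integers(2, 100))
            gold = rng.uniform(0, 3, n)
            pred = rng.uniform(0, 3, n)
            mean = gold.mean() + 0.1
            assert rrmse(pred, gold, mean) == pytest.approx(
                rrmse_oracle(pred, gold, mean), abs=1e-12
            )


class TestEvaluate:
    def _gold_as_predictions(self, corpus, split):
        return {
            iv.id: SymptomProfile(
                {k: float(v) for k, v in corpus.labels[iv.id].scores.items()},
                kind="predicted",
            )
            for iv in corpus.split(split)
        }

    def test_gold_predictions_are_perfect(self, small_corpus):
        report = evaluate(self._gold_as_predictions(small_corpus, "test"),
                          small_corpus, "test")
        assert report.binary_miF1 == 1.0 and report.binary_maF1 == 1.0
        assert report.mae == 0.0 and report.ma_mae == 0.0
        assert (report.per_symptom["MAE"] == 0.0).all()
        assert (report.per_symptom["miF1"] == 1.0).all()

    def test_fractional_total_just_below_cutoff_counts_non_depressed(self, small_corpus):
        ivs = small_corpus.split("test")
        preds = {iv.id: SymptomProfile.from_array([0.0] * 8, kind="predicted")
                 for iv in ivs}
        preds[ivs[0].id] = SymptomProfile.from_array([1.175] * 8, kind="predicted")  # 9.4
        report = evaluate(preds, small_corpus, "test")
        # a 9.4 total lands in the non-depressed and mild bins
        from symptomnet.evaluation import recast_binary, recast_severity

        assert recast_binary("symptoms8", preds[ivs[0].id].as_array()) == 0
        assert recast_severity("symptoms8", preds[ivs[0].id].as_array()) == 1
        gold_bin = [int(sum(small_corpus.labels[iv.id].scores.values()) >= 10)
                    for iv in ivs]
        # with every predicted total below 10, recall of the depressed class is 0
        assert report.binary_miF1 == pytest.approx(
            gold_bin.count(0) / len(gold_bin)
        )

    def test_report_matches_metric_oracles_recomputed_from_files(
        self, tmp_path, small_corpus, tiny_trained
    ):
        predictions = tiny_trained.predict_profiles(small_corpus, "test")
        path = tmp_path / "preds.csv"
        write_predictions(path, predictions)
        loaded = read_predictions(path)
        report = evaluate(loaded, small_corpus, "test")
        stats = TrainStats.from_corpus(small_corpus)
        ids = [iv.id for iv in small_corpus.split("test")]
        P = np.stack([loaded[i].as_array() for i in ids])
        G = np.stack([small_corpus.labels[i].as_array() for i in ids])
        assert report.mae == pytest.approx(mae_oracle(P.sum(1), G.sum(1)), abs=1e-12)
        pred_bin = (P.sum(1) >= 10).astype(int).tolist()
        gold_bin = (G.sum(1) >= 10).astype(int).tolist()
        assert (report.binary_miF1, report.binary_maF1) == pytest.approx(
            f1_oracle(pred_bin, gold_bin, (0, 1)), abs=1e-12
        )
        for k, key in enumerate(SYMPTOM_KEYS):
            assert report.per_symptom.loc[key, "RRMSE"] == pytest.approx(
                rrmse_oracle(P[:, k], G[:, k], stats.symptom_means[k]), abs=1e-10
            )

    def test_missing_predictions_rejected(self, small_corpus):
        with pytest.raises(ValidationError):
            evaluate({}, small_corpus, "test")

    def test_severity_profiles_have_gold_and_pred_rows(self, small_corpus):
        report = evaluate(self._gold_as_predictions(small_corpus, "test"),
                          small_corpus, "test")
        assert any(name.endswith("/gold") for name in report.severity_profiles.index)
        assert any(name.endswith("/pred") for name in report.severity_profiles.index)
        text = report.to_json()
        assert '"binary"' in text and '"per_symptom"' in text
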