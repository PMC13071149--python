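"""Metric, collapse-statistic and group-aggregation tests with brute-force oracles."""

import numpy as np
import pytest

from ecgfewshot.finetune import RunRecord
from ecgfewshot.stability_audit import (
    ConfusionMatrix,
    GROUP_DEFINITIONS,
    accuracy,
    aggregate_group,
    collapse_rate,
    confusion_matrix,
    macro_f1,
    majority_baseline_macro_f1,
    per_class_prf,
    results_table,
)


def brute_force_metrics(true, pred):
    """Independent recomputation of accuracy/P/R/F1 from raw label pairs."""
    true, pred = np.asarray(true), np.asarray(pred)
    acc = np.mean(true == pred)
    f1s, prf = [], []
    for c in range(5):
        tp = np.sum((true == c) & (pred == c))
        fp = np.sum((true != c) & (pred == c))
        fn = np.sum((true == c) & (pred != c))
        p = tp / (tp + fp) if tp + fp else 0.0
        r = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * p * r / (p + r) if p + r else 0.0
        prf.append((p, r, f1))
        f1s.append(f1)
    return float(acc), float(np.mean(f1s)), prf


class TestConfusionMatrix:
    def test_perfect_predictions_are_diagonal(self):
        labels = np.repeat(np.arange(5), 10)
        cm = confusion_matrix(labels, labels)
        assert np.array_equal(cm.counts, 10 * np.eye(5, dtype=int))

    def test_constant_predictor_forms_vertical_stripe(self):
        true = np.repeat(np.arange(5), 10)
        cm = confusion_matrix(true, np.zeros_like(true))
        expected = np.zeros((5, 5), dtype=int)
        expected[:, 0] = 10
        assert np.array_equal(cm.counts, expected)

    def test_matches_double_loop_tally(self, rng):
        true = rng.integers(0, 5, 200)
        pred = rng.integers(0, 5, 200)
        cm = confusion_matrix(true, pred)
        manual = np.zeros((5, 5), dtype=int)
        for t, p in zip(true, pred):
            manual[t, p] += 1
        assert np.array_equal(cm.counts, manual)
        assert cm.total == 200

    def test_out_of_range_labels_rejected(self):
        with pytest.raises(ValueError):
            confusion_matrix([0, 5], [0, 0])


class TestPerClassMetrics:
    def test_diagonal_matrix_gives_perfect_f1(self):
        cm = ConfusionMatrix(np.diag([3, 4, 5, 6, 7]))
        assert all(f1 == 1.0 for _, _, f1 in per_class_prf(cm))
        assert macro_f1(cm) == 1.0
        assert accuracy(cm) == 1.0

    def test_constant_predictor_hand_computation(self):
        true = np.repeat(np.arange(5), 10)
        cm = confusion_matrix(true, np.zeros_like(true))
        prf = per_class_prf(cm)
        assert prf[0] == pytest.approx((0.2, 1.0, 1 / 3))
        assert all(prf[c] == (0.0, 0.0, 0.0) for c in range(1, 5))
        assert macro_f1(cm) == pytest.approx(1 / 15)
        assert accuracy(cm) == pytest.approx(0.2)

    def test_absent_class_f1_is_zero_by_convention(self):
        counts = np.zeros((5, 5), dtype=int)
        counts[:4, :4] = np.diag([5, 5, 5, 5])
        cm = ConfusionMatrix(counts)
        assert per_class_prf(cm)[4] == (0.0, 0.0, 0.0)

    def test_metric_identities_against_label_pair_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(10, 200))
            true = rng.integers(0, 5, n)
            pred = rng.integers(0, 5, n)
            cm = confusion_matrix(true, pred)
            acc_o, mf1_o, prf_o = brute_force_metrics(true, pred)
            assert abs(accuracy(cm) - acc_o) < 1e-12
            assert abs(macro_f1(cm) - mf1_o) < 1e-12
            for got, want in zip(per_class_prf(cm), prf_o):
                assert np.allclose(got, want, atol=1e-12)

    def test_macro_f1_is_mean_of_per_class_f1(self, rng):
        cm = ConfusionMatrix(rng.integers(0, 30, (5, 5)))
        assert macro_f1(cm) == pytest.approx(
            np.mean([f1 for _, _, f1 in per_class_prf(cm)]), abs=1e-12
        )

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            macro_f1(ConfusionMatrix(np.zeros((5, 5), dtype=int)))


class TestCollapseRate:
    @pytest.mark.parametrize(
        "epochs,expected",
        [([1, 1, 3], 2 / 3), ([1, 26, 27], 1 / 3), ([40, 40, 41], 0.0), ([1], 1.0)],
    )
    def test_worked_examples_exact(self, epochs, expected):
        assert collapse_rate(epochs) == expected

    def test_exact_arithmetic_for_large_run_counts(self):
        epochs = [1] * 333 + [2] * 667
        assert collapse_rate(epochs) == 333 / 1000

    def test_threshold_parameter(self):
        assert collapse_rate([1, 2, 3], threshold=2) == pytest.approx(2 / 3)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            collapse_rate([])
        with pytest.raises(ValueError):
            collapse_rate([0, 1])


class TestMajorityBaseline:
    def test_single_class_test_set(self):
        assert majority_baseline_macro_f1([1, 0, 0, 0, 0]) == pytest.approx(0.2)

    def test_half_majority_closed_form(self):
        dist = [0.5, 0.2, 0.1, 0.1, 0.1]
        assert majority_baseline_macro_f1(dist) == pytest.approx(2 * 0.5 / (5 * 1.5))

    def test_dominant_class_value_near_typical_long_tail(self):
        dist = [0.818, 0.05, 0.05, 0.05, 0.032]
        assert majority_baseline_macro_f1(dist) == pytest.approx(0.18, abs=0.005)

    def test_degenerate_predictor_signature_on_constructed_runs(self, rng):
        # a constant predictor's Macro-F1 must equal (1/5) * 2p/(1+p) where
        # p is the predicted class's truth fraction
        for _ in range(10):
            counts = rng.multinomial(100, [0.4, 0.3, 0.1, 0.1, 0.1])
            true = np.repeat(np.arange(5), counts)
            cm = confusion_matrix(true, np.full_like(true, 0))
            p = counts[0] / 100
            assert macro_f1(cm) == pytest.approx(2 * p / (5 * (1 + p)), abs=1e-12)


def _run(tag, seed, f1, acc, e, meta=None):
    r = RunRecord(
        seed=seed, val_history=[0.0] * max(e, 1), best_epoch=e,
        test_confusion=np.zeros((5, 5), dtype=int) + np.diag([1] * 5),
        test_macro_f1=f1, test_accuracy=acc, group_tag=tag,
    )
    r._group_meta = meta or {"n_labeled": 70, "strategy": "scratch", "aug": False}
    return r


class TestAggregation:
    def test_identical_runs_have_zero_sd(self):
        runs = [_run("C", s, 0.19, 0.3, 2) for s in range(3)]
        g = aggregate_group(runs)
        assert g.macro_f1_mean == pytest.approx(0.19)
        assert g.macro_f1_sd == pytest.approx(0.0, abs=1e-15)
        assert g.R == 3

    def test_mean_best_epoch_and_collapse_rate(self):
        runs = [_run("C", s, 0.1, 0.2, e) for s, e in enumerate([1, 1, 3])]
        g = aggregate_group(runs)
        assert g.best_epoch_mean == pytest.approx(5 / 3)
        assert g.collapse_rate == pytest.approx(2 / 3)

    def test_sample_sd_matches_independent_statistics(self, rng):
        f1s = rng.random(5)
        runs = [_run("E", s, f, 0.2, 2) for s, f in enumerate(f1s)]
        g = aggregate_group(runs)
        assert g.macro_f1_sd == pytest.approx(np.std(f1s, ddof=1), abs=1e-12)

    def test_single_run_sd_zero_collapse_binary(self):
        g = aggregate_group([_run("C", 0, 0.2, 0.3, 1)])
        assert g.macro_f1_sd == 0.0
        assert g.collapse_rate == 1.0

    def test_mixed_group_tags_rejected(self):
        with pytest.raises(ValueError):
            aggregate_group([_run("C", 0, 0.1, 0.2, 1), _run("E", 1, 0.1, 0.2, 1)])


class TestExperimentMatrix:
    def test_group_definitions_cover_the_seven_configurations(self):
        tags = [g[0] for g in GROUP_DEFINITIONS]
        assert tags == ["A", "A'", "B", "C", "E", "D-Aug", "D-NoAug"]
        # D groups are the only SSL-initialized ones; A uses the imbalanced
        # reference, A'/B the balanced one, C/E/D the few-shot set
        by_tag = {g[0]: g for g in GROUP_DEFINITIONS}
        assert by_tag["A"][1] == "ref" and by_tag["A'"][1] == "ref_bal"
        assert all(by_tag[t][1] == "few" for t in ("C", "E", "D-Aug", "D-NoAug"))
        assert all(by_tag[t][2] == "ssl" for t in ("D-Aug", "D-NoAug"))
        assert {t: by_tag[t][3] for t in ("B", "E", "D-Aug")} == {
            "B": True, "E": True, "D-Aug": True,
        }

    def test_missing_ssl_checkpoint_is_a_config_error(self, mini_splits):
        from ecgfewshot.stability_audit import run_experiment_matrix

        with pytest.raises(ValueError, match="checkpoint"):
            run_experiment_matrix(mini_splits, seeds=[0], groups=["D-NoAug"])

    def test_matrix_bookkeeping_on_scratch_groups(self, mini_splits):
        from dataclasses import replace

        from ecgfewshot.finetune import FinetuneConfig
        from ecgfewshot.nn import TINY_ENCODER_SPEC
        from ecgfewshot.stability_audit import run_experiment_matrix

        results, runs = run_experiment_matrix(
            mini_splits, seeds=[0, 1],
            base_cfg=FinetuneConfig(max_epochs=2, patience=1),
            enc_spec=TINY_ENCODER_SPEC, groups=["C", "E"],
        )
        assert [g.group_tag for g in results] == ["C", "E"]
        assert all(g.R == 2 for g in results)
        assert len(runs) == 4
        table = results_table(results)
        assert list(table.columns) == [
            "group", "N", "strategy", "aug",
            "macro_f1_mean", "macro_f1_sd", "accuracy_mean", "accuracy_sd",
            "best_epoch_mean", "collapse_rate",
        ]
        assert table["N"].tolist() == [20, 20]
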