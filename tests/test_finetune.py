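"""Fine-tuning tests: loss, best-epoch selection, early stopping, training."""

import numpy as np
import pytest

from ecgfewshot.finetune import (
    EarlyStopper,
    FinetuneConfig,
    RunRecord,
    cross_entropy,
    predict,
    select_best_epoch,
    train_supervised,
)
from ecgfewshot.nn import TINY_ENCODER_SPEC
from ecgfewshot.stability_audit import confusion_matrix, macro_f1


class TestCrossEntropy:
    def test_uniform_probabilities_give_log_5(self):
        assert cross_entropy(np.full(5, 0.2), 3) == pytest.approx(np.log(5))

    def test_one_hot_on_true_label_gives_zero(self):
        probs = np.zeros(5)
        probs[2] = 1.0
        assert cross_entropy(probs, 2) == 0.0

    def test_direct_evaluation(self):
        probs = np.array([0.7, 0.1, 0.1, 0.05, 0.05])
        assert cross_entropy(probs, 0) == pytest.approx(-np.log(0.7))

    def test_invalid_simplex_rejected(self):
        with pytest.raises(ValueError):
            cross_entropy(np.array([0.5, 0.5, 0.5, 0, 0]), 0)
        with pytest.raises(ValueError):
            cross_entropy(np.full(5, 0.2), 7)


class TestBestEpoch:
    def test_immediate_peak_is_epoch_one(self):
        assert select_best_epoch([0.5, 0.4, 0.3]) == 1

    def test_earliest_tie_wins(self):
        assert select_best_epoch([0.1, 0.2, 0.9, 0.9]) == 3

    def test_matches_brute_force_scan(self, rng):
        for _ in range(20):
            hist = rng.random(50)
            best, best_val = 0, -np.inf
            for i, v in enumerate(hist):
                if v > best_val:
                    best, best_val = i + 1, v
            assert select_best_epoch(hist) == best

    def test_empty_history_rejected(self):
        with pytest.raises(ValueError):
            select_best_epoch([])


class TestEarlyStopping:
    def test_halts_exactly_patience_epochs_after_last_improvement(self):
        # improvement at epochs 1, 2, 4; patience 3 => stop at epoch 7
        history = [0.1, 0.2, 0.15, 0.3, 0.25, 0.2, 0.1, 0.05]
        stopper = EarlyStopper(patience=3)
        stopped_at = None
        for epoch, v in enumerate(history, start=1):
            if stopper.update(v):
                stopped_at = epoch
                break
        assert stopped_at == 7
        assert stopper.best_epoch == 4

    def test_monotone_decreasing_history_collapses_to_epoch_one(self):
        stopper = EarlyStopper(patience=10)
        for epoch, v in enumerate(np.linspace(0.5, 0.1, 30), start=1):
            if stopper.update(v):
                break
        assert stopper.best_epoch == 1
        assert epoch == 11  # exactly patience epochs after the epoch-1 peak

    def test_flat_history_keeps_earliest_epoch(self):
        stopper = EarlyStopper(patience=4)
        stops = [stopper.update(0.7) for _ in range(10)]
        assert stopper.best_epoch == 1
        assert stops.index(True) + 1 == 5  # epoch 5 = 1 + patience

    def test_no_stop_while_improving(self):
        stopper = EarlyStopper(patience=2)
        assert not any(stopper.update(v) for v in np.arange(1, 30))

    def test_invalid_patience_rejected(self):
        with pytest.raises(ValueError):
            EarlyStopper(patience=0)


class TestRunRecordInvariants:
    def test_best_epoch_must_index_history(self):
        with pytest.raises(ValueError):
            RunRecord(
                seed=0, val_history=[0.1, 0.2], best_epoch=3,
                test_confusion=np.zeros((5, 5), dtype=int),
                test_macro_f1=0.0, test_accuracy=0.0,
            )

    def test_confusion_must_be_5x5_nonnegative(self):
        with pytest.raises(ValueError):
            RunRecord(
                seed=0, val_history=[0.1], best_epoch=1,
                test_confusion=-np.ones((5, 5), dtype=int),
                test_macro_f1=0.0, test_accuracy=0.0,
            )


class TestTrainSupervised:
    CFG = FinetuneConfig(max_epochs=4, patience=2, batch_size=16)

    def test_run_record_bookkeeping(self, mini_splits):
        import dataclasses

        run = train_supervised(
            mini_splits.few, mini_splits.val, mini_splits.test,
            cfg=self.CFG, enc_spec=TINY_ENCODER_SPEC, group_tag="C",
        )
        assert 1 <= run.best_epoch <= len(run.val_history) <= 4
        assert run.best_epoch == select_best_epoch(run.val_history)
        # confusion rows must tally the true test class counts
        true_counts = np.bincount([int(r.label) for r in mini_splits.test], minlength=5)
        assert np.array_equal(np.asarray(run.test_confusion).sum(axis=1), true_counts)

    def test_reproducible_given_seed(self, mini_splits):
        runs = [
            train_supervised(
                mini_splits.few, mini_splits.val, mini_splits.test,
                cfg=dataclasses_replace_seed(self.CFG, 11),
                enc_spec=TINY_ENCODER_SPEC,
            )
            for _ in range(2)
        ]
        assert runs[0].best_epoch == runs[1].best_epoch
        assert runs[0].val_history == runs[1].val_history
        assert np.array_equal(runs[0].test_confusion, runs[1].test_confusion)

    def test_weights_restored_from_best_epoch(self, mini_splits):
        # the returned model must reproduce the recorded best validation
        # metric, not the final epoch's
        run, model = train_supervised(
            mini_splits.few, mini_splits.val, mini_splits.test,
            cfg=FinetuneConfig(max_epochs=6, patience=5, seed=2),
            enc_spec=TINY_ENCODER_SPEC, return_model=True,
        )
        true = np.array([int(r.label) for r in mini_splits.val])
        pred = predict(model, mini_splits.val)
        restored_metric = macro_f1(confusion_matrix(true, pred))
        assert restored_metric == pytest.approx(run.val_history[run.best_epoch - 1])

    def test_ssl_checkpoint_init_runs(self, mini_splits, mini_pretrain):
        run = train_supervised(
            mini_splits.few, mini_splits.val, mini_splits.test,
            init_state=mini_pretrain.encoder_state,
            cfg=FinetuneConfig(init="ssl_checkpoint", max_epochs=2, patience=2),
            enc_spec=TINY_ENCODER_SPEC, group_tag="D-NoAug",
        )
        assert np.asarray(run.test_confusion).sum() == len(mini_splits.test)

    def test_checkpoint_init_without_weights_rejected(self, mini_splits):
        with pytest.raises(ValueError):
            train_supervised(
                mini_splits.few, mini_splits.val, mini_splits.test,
                cfg=FinetuneConfig(init="ssl_checkpoint"),
                enc_spec=TINY_ENCODER_SPEC,
            )

    def test_test_leakage_is_a_hard_failure(self, mini_splits):
        with pytest.raises(RuntimeError, match="leakage"):
            train_supervised(
                mini_splits.few + mini_splits.test[:1],
                mini_splits.val, mini_splits.test,
                cfg=self.CFG, enc_spec=TINY_ENCODER_SPEC,
            )


def dataclasses_replace_seed(cfg, seed):
    import dataclasses

    return dataclasses.replace(cfg, seed=seed)
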