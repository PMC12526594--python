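"""Two-stage protocol semantics and the cross-session hold-out harness."""

import numpy as np
import pytest

from tsfnet.network import ModelConfig, TSFNet
from tsfnet.training import (TrainConfig, TrainState, cross_session_holdout,
                             run_stage1, run_stage2, shuffle_labels,
                             split_train_val, train_two_stage)


def small_model(seed=0):
    return TSFNet(ModelConfig(width_scale=0.125, cafe_dim=8, cafe_heads=2,
                              head_hidden=8, seed=seed))


class TestSplit:
    def test_four_to_one_at_trial_level(self, tiny_samples):
        train, val = split_train_val(tiny_samples, seed=1)
        n_trials = len(np.unique(np.stack([tiny_samples.session, tiny_samples.trial], 1), axis=0))
        val_trials = len(np.unique(np.stack([val.session, val.trial], 1), axis=0))
        assert abs(val_trials - round(n_trials / 5)) <= 1
        # windows of one trial never straddle the split
        train_keys = set(map(tuple, np.stack([train.session, train.trial], 1)))
        val_keys = set(map(tuple, np.stack([val.session, val.trial], 1)))
        assert train_keys.isdisjoint(val_keys)
        assert len(train) + len(val) == len(tiny_samples)

    def test_deterministic_per_seed(self, tiny_samples):
        a1, _ = split_train_val(tiny_samples, seed=5)
        a2, _ = split_train_val(tiny_samples, seed=5)
        assert np.array_equal(a1.labels, a2.labels)
        assert np.array_equal(a1.trial, a2.trial)

    def test_too_few_samples_rejected(self, tiny_samples):
        with pytest.raises(ValueError):
            split_train_val(tiny_samples.subset(np.arange(3)))


def test_shuffle_labels_permutes_at_trial_level(tiny_samples):
    shuffled = shuffle_labels(tiny_samples, seed=3)
    assert sorted(shuffled.labels) == sorted(tiny_samples.labels)
    # all windows of one trial share a label after shuffling
    keys = np.stack([shuffled.session, shuffled.trial], axis=1)
    for key in np.unique(keys, axis=0):
        mask = (keys == key).all(axis=1)
        assert len(np.unique(shuffled.labels[mask])) == 1


class _Stub:
    """Mocked epoch/evaluator pair driving the stopping rules."""

    def __init__(self, accs=None, losses=None):
        self.accs = list(accs or [])
        self.losses = list(losses or [])
        self.epochs_run = 0

    def train_epoch(self, model, samples, optimizer, config, rng):
        self.epochs_run += 1
        return self.losses.pop(0) if self.losses else 1.0

    def eval(self, model, samples):
        return self.accs.pop(0) if self.accs else 0.5


class TestStage1:
    def test_strictly_improving_accuracy_runs_to_cap(self, tiny_samples):
        stub = _Stub(accs=[0.1 * k for k in range(1, 100)])
        cfg = TrainConfig(stage1_max_epochs=8, stage1_patience=3)
        state = run_stage1(small_model(), tiny_samples, tiny_samples, cfg,
                           eval_fn=stub.eval, train_epoch_fn=stub.train_epoch)
        assert state.epoch == 8 and stub.epochs_run == 8

    def test_flat_accuracy_stops_after_patience(self, tiny_samples):
        stub = _Stub(accs=[0.5] * 100)
        cfg = TrainConfig(stage1_max_epochs=50, stage1_patience=4)
        state = run_stage1(small_model(), tiny_samples, tiny_samples, cfg,
                           eval_fn=stub.eval, train_epoch_fn=stub.train_epoch)
        # first epoch improves over -inf; then patience exhausts
        assert state.epoch == 1 + 4
        assert state.best_epoch == 1

    def test_best_checkpoint_restored(self, tiny_samples):
        model = small_model()
        marker = model.fuse_weights

        def noisy_epoch(m, s, o, c, r):
            marker.data = marker.data + 1.0
            return 1.0

        stub = _Stub(accs=[0.9, 0.2, 0.1, 0.05])
        cfg = TrainConfig(stage1_max_epochs=4, stage1_patience=10)
        state = run_stage1(model, tiny_samples, tiny_samples, cfg,
                           eval_fn=stub.eval, train_epoch_fn=noisy_epoch)
        assert state.best_epoch == 1
        assert np.allclose(model.fuse_weights.data, 1.0)   # epoch-1 weights restored


class TestStage2:
    def test_degenerate_threshold_stops_after_one_epoch(self, tiny_samples):
        stub = _Stub(losses=[5.0] * 100)
        state = TrainState(stage=1, epoch=0, best_val_accuracy=1.0, best_epoch=1,
                           stage1_final_train_loss=np.inf, checkpoint={})
        run_stage2(small_model(), tiny_samples, state,
                   TrainConfig(stage2_max_epochs=50), train_epoch_fn=stub.train_epoch)
        assert stub.epochs_run == 1

    def test_unreachable_threshold_runs_to_cap(self, tiny_samples):
        stub = _Stub(losses=[5.0] * 100)
        state = TrainState(stage=1, epoch=0, best_val_accuracy=1.0, best_epoch=1,
                           stage1_final_train_loss=0.0, checkpoint={})
        run_stage2(small_model(), tiny_samples, state,
                   TrainConfig(stage2_max_epochs=7), train_epoch_fn=stub.train_epoch)
        assert stub.epochs_run == 7


class TestHoldout:
    def test_rotation_and_disjointness(self, tiny_samples):
        cfg = TrainConfig(batch_size=64, stage1_max_epochs=1, stage2_max_epochs=1,
                          stage1_patience=1, seed=0)
        result = cross_session_holdout(lambda s: small_model(s), tiny_samples, cfg)
        tested = sorted(f.test_session for f in result.folds)
        assert tested == sorted(int(s) for s in np.unique(tiny_samples.session))
        for fold in result.folds:
            assert fold.report.n_samples == int((tiny_samples.session == fold.test_session).sum())
        assert 0.0 <= result.mean_accuracy <= 1.0
        assert len(result.pooled()[0]) == len(tiny_samples)

    def test_single_session_rejected(self, tiny_samples):
        single = tiny_samples.subset(tiny_samples.session == 0)
        with pytest.raises(ValueError):
            cross_session_holdout(lambda s: small_model(s), single, TrainConfig())

    def test_chance_level_for_uninformative_predictions(self, rng):
        """A constant-prediction model scores the label base rate per fold."""
        from tsfnet.evaluation import make_report
        labels = np.array([0, 1] * 20)
        preds = np.zeros(40, dtype=int)
        report = make_report(preds, labels, np.tile(np.arange(1, 11), 4))
        assert report.accuracy == pytest.approx(0.5)


def test_training_loss_decreases_on_learnable_data(tiny_samples):
    """A logistic read-out of the generator's known discriminative feature
    separates the classes, so a short real training run must reduce the loss."""
    from sklearn.linear_model import LogisticRegression

    # oracle separability check: hemispheric band-power asymmetry
    x = tiny_samples.eeg_batch(np.arange(len(tiny_samples)))
    power = (x ** 2).mean(axis=3)
    left = power[:, :, :8].mean(axis=(1, 2))
    right = power[:, :, 8:].mean(axis=(1, 2))
    feat = np.column_stack([left, right, left - right])
    clf = LogisticRegression(max_iter=1000).fit(feat, tiny_samples.labels)
    assert clf.score(feat, tiny_samples.labels) > 0.8

    model = small_model(seed=1)
    cfg = TrainConfig(batch_size=64, stage1_max_epochs=3, stage2_max_epochs=1,
                      stage1_patience=5, seed=0)
    state = train_two_stage(model, tiny_samples, cfg)
    losses = [h["train_loss"] for h in state.history if h["stage"] == 1]
    assert losses[-1] < losses[0]
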