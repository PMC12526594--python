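"""Cross-session hold-out with the two-stage training protocol.

Stage 1 trains on a 4:1 trial-level split of the training sessions with Adam
(learning rate 0.001), stopping when validation accuracy has not improved for
``stage1_patience`` consecutive epochs (cap ``stage1_max_epochs``); the
weights of the best validation epoch are restored and the training loss of
that epoch recorded.  Stage 2 continues from those weights on the *entire*
training set with a fresh optimizer, stopping as soon as the epoch-mean
training loss drops below the stage-1 reference (cap ``stage2_max_epochs``).

The hold-out rotates each session out as the test set in turn and reports the
mean test accuracy over sessions.  Splitting is at the trial level so that
overlapping windows of one trial never straddle the train/validation divide.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np

from .autograd import Tensor, no_grad
from .evaluation import EvalReport, make_report
from .losses import LossWeights, total_loss
from .network import TSFNet, clamp_gates, make_optimizer
from .tensorize import SampleSet


class TrainingError(RuntimeError):
    """Raised when the loss diverges (non-finite) during training."""


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-3
    batch_size: int = 64
    stage1_patience: int = 50
    stage1_max_epochs: int = 300
    stage2_max_epochs: int = 200
    split_ratio: tuple[int, int] = (4, 1)
    seed: int = 0
    loss_weights: LossWeights = field(default_factory=LossWeights)

    def __post_init__(self):
        for name in ("batch_size", "stage1_patience", "stage1_max_epochs", "stage2_max_epochs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class TrainState:
    stage: int
    epoch: int
    best_val_accuracy: float
    best_epoch: int
    stage1_final_train_loss: float
    checkpoint: dict
    history: list[dict] = field(default_factory=list)


def split_train_val(samples: SampleSet, ratio: tuple[int, int] = (4, 1),
                    seed: int = 0) -> tuple[SampleSet, SampleSet]:
    """Random trial-level split; all windows of a trial stay together."""
    if len(samples) < 5:
        raise ValueError("need at least 5 samples to split")
    keys = np.stack([samples.session, samples.trial], axis=1)
    trials, inverse = np.unique(keys, axis=0, return_inverse=True)
    n_trials = len(trials)
    n_val = int(round(n_trials * ratio[1] / (ratio[0] + ratio[1])))
    n_val = min(max(n_val, 1), n_trials - 1)
    order = np.random.default_rng(seed).permutation(n_trials)
    val_trials = np.zeros(n_trials, dtype=bool)
    val_trials[order[:n_val]] = True
    val_mask = val_trials[inverse]
    return samples.subset(~val_mask), samples.subset(val_mask)


def shuffle_labels(samples: SampleSet, seed: int = 0) -> SampleSet:
    """Permute labels at the trial level (control for learnability tests)."""
    out = samples.subset(np.arange(len(samples)))
    keys = np.stack([samples.session, samples.trial], axis=1)
    trials, inverse = np.unique(keys, axis=0, return_inverse=True)
    trial_labels = np.array([samples.labels[inverse == k][0] for k in range(len(trials))])
    permuted = np.random.default_rng(seed).permutation(trial_labels)
    out.labels = permuted[inverse].astype(np.int64)
    return out


def _batches(samples: SampleSet, batch_size: int, rng: np.random.Generator | None):
    """Batch index generator; trial-grouped so that the overlapping fNIRS
    stacks inside one batch share their deduplicated windows.

    With ``rng`` the trial order (and the sample order within trials) is
    shuffled; without, samples come in their deterministic stored order,
    which is already trial-major.
    """
    n = len(samples)
    if rng is None:
        idx = np.arange(n)
    else:
        rows = samples.trial_row
        trial_order = rng.permutation(np.unique(rows))
        by_trial = {t: np.flatnonzero(rows == t) for t in trial_order}
        idx = np.concatenate([rng.permutation(by_trial[t]) for t in trial_order])
    for start in range(0, n, batch_size):
        yield idx[start:start + batch_size]


def ensure_patch_bank(samples: SampleSet, chunk: int = 32) -> None:
    """Precompute the EEG front-conv patch matrix of every sample (float16).

    The patches depend only on the data, so repeated training epochs can skip
    the im2col gather entirely; subsets share the bank by reference.
    """
    from .nn import gather_patches
    from .network import EEG_CONV

    if getattr(samples, "_patch_bank", None) is not None:
        return
    kernel, stride, _ = EEG_CONV[0]
    n = len(samples)
    bank = None
    for start in range(0, n, chunk):
        idx = np.arange(start, min(start + chunk, n))
        x = samples.eeg_batch(idx)[..., None]
        cols = gather_patches(x, kernel, stride)
        if bank is None:
            bank = np.empty((n, cols.shape[1], cols.shape[2]), dtype=np.float16)
        bank[start:start + len(idx)] = cols
    samples._patch_bank = bank
    samples._patch_idx = np.arange(n)


def _forward_batch(model: TSFNet, samples: SampleSet, idx: np.ndarray):
    from . import autograd as _ag
    from .nn import _pool

    windows, seg_map = samples.fnirs_unique_windows(idx)
    bank = getattr(samples, "_patch_bank", None)
    if bank is not None:
        rows = samples._patch_idx[idx]
        cols = _pool.acquire((len(idx), bank.shape[1], bank.shape[2]), np.float32)
        np.copyto(cols, bank[rows], casting="safe")
        result = model.forward_windows(None, Tensor(windows), seg_map, front_cols=cols)
        if not _ag._GRAD_ENABLED:
            _pool.release(cols)      # no backward pass will return it
        return result
    eeg = Tensor(samples.eeg_batch(idx))
    return model.forward_windows(eeg, Tensor(windows), seg_map)


def train_epoch(model: TSFNet, samples: SampleSet, optimizer, config: TrainConfig,
                rng: np.random.Generator) -> float:
    """One pass over the training set; returns the sample-weighted mean loss."""
    model.train()
    total = 0.0
    for idx in _batches(samples, config.batch_size, rng):
        optimizer.zero_grad()
        result = _forward_batch(model, samples, idx)
        loss, breakdown = total_loss(result, samples.labels[idx], config.loss_weights)
        if not np.isfinite(breakdown.L_total):
            raise TrainingError(f"non-finite training loss: {breakdown}")
        loss.backward()
        optimizer.step()
        clamp_gates(model)
        total += breakdown.L_total * len(idx)
    return total / len(samples)


def predict(model: TSFNet, samples: SampleSet, batch_size: int = 64) -> dict[str, np.ndarray]:
    """Evaluation-mode forward pass over a sample set (probabilities)."""
    model.eval()
    outs: dict[str, list[np.ndarray]] = {k: [] for k in ("y_eeg", "y_fnirs", "y_fusion", "y_pred")}
    with no_grad():
        for idx in _batches(samples, batch_size, rng=None):
            result = _forward_batch(model, samples, idx)
            for key in outs:
                outs[key].append(getattr(result, key).data)
    return {k: np.concatenate(v) for k, v in outs.items()}


def evaluate_accuracy(model: TSFNet, samples: SampleSet, batch_size: int = 64) -> float:
    scores = predict(model, samples, batch_size)
    return float(np.mean(scores["y_pred"].argmax(axis=1) == samples.labels))


def run_stage1(model: TSFNet, train: SampleSet, val: SampleSet, config: TrainConfig,
               eval_fn=evaluate_accuracy, train_epoch_fn=train_epoch) -> TrainState:
    """First training stage with patience-based early stopping.

    Improvement means a strict increase in validation accuracy; the best
    checkpoint is restored into ``model`` before returning.
    """
    if len(train) == 0 or len(val) == 0:
        raise ValueError("stage 1 needs nonempty training and validation sets")
    optimizer = make_optimizer(model, config.learning_rate)
    rng = np.random.default_rng(config.seed)
    state = TrainState(stage=1, epoch=0, best_val_accuracy=-np.inf, best_epoch=0,
                       stage1_final_train_loss=np.inf, checkpoint={})
    since_best = 0
    for epoch in range(1, config.stage1_max_epochs + 1):
        mean_loss = train_epoch_fn(model, train, optimizer, config, rng)
        val_acc = eval_fn(model, val)
        state.epoch = epoch
        state.history.append({"stage": 1, "epoch": epoch, "train_loss": mean_loss,
                              "val_accuracy": val_acc})
        if val_acc > state.best_val_accuracy:
            state.best_val_accuracy = val_acc
            state.best_epoch = epoch
            state.stage1_final_train_loss = mean_loss
            state.checkpoint = copy.deepcopy(model.state_dict())
            since_best = 0
        else:
            since_best += 1
            if since_best >= config.stage1_patience:
                break
    if state.checkpoint:
        model.load_state_dict(state.checkpoint)
    return state


def run_stage2(model: TSFNet, full_train: SampleSet, state: TrainState,
               config: TrainConfig, train_epoch_fn=train_epoch) -> TSFNet:
    """Second stage: full training set, fresh optimizer, loss-threshold stop."""
    optimizer = make_optimizer(model, config.learning_rate)
    rng = np.random.default_rng(config.seed + 1)
    for epoch in range(1, config.stage2_max_epochs + 1):
        mean_loss = train_epoch_fn(model, full_train, optimizer, config, rng)
        state.stage = 2
        state.epoch = epoch
        state.history.append({"stage": 2, "epoch": epoch, "train_loss": mean_loss})
        if mean_loss < state.stage1_final_train_loss:
            break
    return model


def train_two_stage(model: TSFNet, train_samples: SampleSet, config: TrainConfig) -> TrainState:
    ensure_patch_bank(train_samples)
    tr, val = split_train_val(train_samples, config.split_ratio, config.seed)
    state = run_stage1(model, tr, val, config)
    run_stage2(model, train_samples, state, config)
    return state


@dataclass
class FoldResult:
    test_session: int
    report: EvalReport
    state: TrainState
    predictions: dict[str, np.ndarray]
    labels: np.ndarray
    window_right_edge: np.ndarray


@dataclass
class HoldoutResult:
    folds: list[FoldResult]

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean([f.report.accuracy for f in self.folds]))

    @property
    def std_accuracy(self) -> float:
        return float(np.std([f.report.accuracy for f in self.folds]))

    @property
    def mean_kappa(self) -> float:
        return float(np.mean([f.report.kappa for f in self.folds]))

    def pooled(self, key: str = "y_pred") -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Concatenated (pred_class, labels, window_right_edge) over folds."""
        preds = np.concatenate([f.predictions[key].argmax(axis=1) for f in self.folds])
        labels = np.concatenate([f.labels for f in self.folds])
        edges = np.concatenate([f.window_right_edge for f in self.folds])
        return preds, labels, edges


def cross_session_holdout(model_builder, samples: SampleSet,
                          config: TrainConfig = TrainConfig(),
                          checkpoint_dir=None) -> HoldoutResult:
    """Rotate each session out as the test set; train on the rest.

    ``model_builder(fold_seed)`` must return a fresh network.  Test-session
    samples never enter any gradient or normalization statistic of their
    fold's model (the training subset excludes the session outright).
    """
    sessions = sorted(int(s) for s in np.unique(samples.session))
    if len(sessions) < 2:
        raise ValueError("cross-session hold-out needs at least 2 sessions")
    ensure_patch_bank(samples)
    folds = []
    for fold, test_session in enumerate(sessions):
        test_mask = samples.session == test_session
        train_set = samples.subset(~test_mask)
        test_set = samples.subset(test_mask)
        assert test_session not in set(train_set.session.tolist())  # leakage guard
        fold_config = replace(config, seed=config.seed + 1000 * fold)
        model = model_builder(fold_config.seed)
        state = train_two_stage(model, train_set, fold_config)
        if checkpoint_dir is not None:
            from pathlib import Path
            ckpt_dir = Path(checkpoint_dir)
            ckpt_dir.mkdir(parents=True, exist_ok=True)
            model.save_checkpoint(ckpt_dir / f"fold_session{test_session}")
        scores = predict(model, test_set, config.batch_size)
        pred_class = scores["y_pred"].argmax(axis=1)
        report = make_report(
            pred_class, test_set.labels, test_set.window_right_edge,
            branch_preds={
                "eeg": scores["y_eeg"].argmax(axis=1),
                "fnirs": scores["y_fnirs"].argmax(axis=1),
                "fusion": scores["y_fusion"].argmax(axis=1),
            },
        )
        folds.append(FoldResult(
            test_session=test_session, report=report, state=state,
            predictions=scores, labels=test_set.labels,
            window_right_edge=test_set.window_right_edge,
        ))
    return HoldoutResult(folds)
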