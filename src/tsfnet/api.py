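"""Model/Results facade over the pipeline.

`TSFNetModel` is built from data (a :class:`~tsfnet.tensorize.SampleSet`, a
study container, or a fresh simulation) and ``fit()`` runs the cross-session
hold-out with the two-stage protocol, returning a :class:`TSFNetResults`
object carrying per-fold metrics, the learned gate/weight parameters, and a
``summary()`` table.
"""

from __future__ import annotations

from dataclasses import asdict, replace

import numpy as np

from .network import ModelConfig, TSFNet
from .preprocess import preprocess_study
from .simulate import SimulationConfig, simulate_subject
from .tensorize import SampleSet, build_samples
from .training import TrainConfig, HoldoutResult, cross_session_holdout
from .evaluation import per_window_accuracy


class TSFNetModel:
    """Three-branch EEG/fNIRS fusion classifier bound to a sample set."""

    def __init__(self, samples: SampleSet, model_config: ModelConfig | None = None,
                 train_config: TrainConfig | None = None):
        self.samples = samples
        self.model_config = model_config or ModelConfig()
        self.train_config = train_config or TrainConfig()

    @classmethod
    def from_study(cls, study, conditioned: bool = False, **kwargs) -> "TSFNetModel":
        """Build from a (simulated or loaded) study; conditions signals first
        unless ``conditioned=True``."""
        if not conditioned:
            study = preprocess_study(study)
        return cls(build_samples(study), **kwargs)

    @classmethod
    def from_simulation(cls, sim_config: SimulationConfig | None = None, **kwargs) -> "TSFNetModel":
        study = simulate_subject(sim_config or SimulationConfig())
        return cls.from_study(study, **kwargs)

    def _builder(self):
        base = self.model_config

        def build(seed: int) -> TSFNet:
            return TSFNet(replace(base, seed=seed))

        return build

    def fit(self) -> "TSFNetResults":
        """Cross-session hold-out with two-stage training on every fold."""
        holdout = cross_session_holdout(self._builder(), self.samples, self.train_config)
        return TSFNetResults(self, holdout)


class TSFNetResults:
    """Fitted-model results: fold metrics, learned fusion parameters,
    per-window accuracy curves."""

    def __init__(self, model: TSFNetModel, holdout: HoldoutResult):
        self.model = model
        self.holdout = holdout

    # -- headline metrics ----------------------------------------------------
    @property
    def accuracy(self) -> float:
        return self.holdout.mean_accuracy

    @property
    def accuracy_std(self) -> float:
        return self.holdout.std_accuracy

    @property
    def kappa(self) -> float:
        return self.holdout.mean_kappa

    @property
    def fold_accuracies(self) -> list[float]:
        return [f.report.accuracy for f in self.holdout.folds]

    # -- learned parameters --------------------------------------------------
    def fusion_parameters(self) -> dict[str, list[float]]:
        """Decision weights and EFGF gates per fold (post-sigmoid / clipped)."""
        out: dict[str, list[float]] = {}
        for fold in self.holdout.folds:
            ckpt = fold.state.checkpoint
            w = 1.0 / (1.0 + np.exp(-np.asarray(ckpt["fuse_weights"])))
            for i, name in enumerate(("w_eeg", "w_fusion", "w_fnirs")):
                out.setdefault(name, []).append(float(w[i]))
            for key in ("efgf1.gamma", "efgf1.alpha", "efgf2.gamma", "efgf2.alpha"):
                if key in ckpt:
                    out.setdefault(key.replace(".", "_"), []).append(float(ckpt[key]))
        return out

    def per_window(self, branch: str = "y_pred") -> dict[float, float]:
        preds, labels, edges = self.holdout.pooled(branch)
        return per_window_accuracy(preds, labels, edges)

    # -- presentation --------------------------------------------------------
    def summary(self) -> str:
        cfg = self.model.model_config
        lines = [
            "Temporal-Spatial Fusion Network — cross-session hold-out",
            "=" * 58,
            f"variant: {cfg.variant:<12} conv width scale: {cfg.width_scale}",
            f"CAFE dim/heads: {cfg.cafe_dim}/{cfg.cafe_heads}    samples: {len(self.model.samples)}",
            "-" * 58,
            f"{'fold (test session)':<24}{'accuracy':>10}{'kappa':>10}{'n':>8}",
        ]
        for f in self.holdout.folds:
            lines.append(f"{f.test_session:<24}{f.report.accuracy:>10.4f}"
                         f"{f.report.kappa:>10.4f}{f.report.n_samples:>8}")
        lines.append("-" * 58)
        lines.append(f"{'mean ± std':<24}{self.accuracy:>10.4f}"
                     f"{self.kappa:>10.4f}{'':>8}")
        lines.append(f"{'':<24}{'±' + format(self.accuracy_std, '.4f'):>10}")
        fp = self.fusion_parameters()
        if fp:
            lines.append("-" * 58)
            lines.append("learned fusion parameters (mean over folds):")
            for name, vals in fp.items():
                lines.append(f"  {name:<14} {np.mean(vals):.4f}")
        return "\n".join(lines)

    def config_dict(self) -> dict:
        return {"model": asdict(self.model.model_config),
                "train": {k: v for k, v in asdict(self.model.train_config).items()}}
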