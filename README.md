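# tsfnet

Temporal-spatial fusion of EEG and fNIRS for hybrid brain-computer
interfaces: a three-branch 3D-CNN classifier with an EEG-fNIRS-guided
attention fusion layer (EFGF), a bidirectional cross-attention feature
enhancement layer (CAFE), Pearson-correlation regularized training, and the
full pipeline around it — synthetic paired-recording simulation, signal
conditioning, topographic tensorization, two-stage cross-session training,
and evaluation.

## Who this is for

EEG and fNIRS are complementary: EEG resolves millisecond oscillatory
dynamics (e.g. event-related desynchronization of the 8-12 Hz rhythm during
motor imagery) but is spatially coarse; fNIRS resolves the cortical
hemodynamic response (HbO/HbR concentration changes) with better spatial
specificity but a 5-8 s physiological lag.  This package is for researchers
who want a fully tested, CPU-only reference implementation of a deep fusion
classifier for such paired recordings — exercisable end to end on synthetic
data with known ground truth, without downloading the public benchmark
datasets or using a GPU.

## The model

Both modalities are projected to a 16 x 16 scalp grid (azimuthal equidistant
projection + piecewise-cubic scattered-data interpolation) and cut into 3 s
sliding windows (step 1 s) over the -2..10 s trial period.  Each EEG window
`X_eeg ∈ R^{16x16x600}` is paired with the time-matched fNIRS window plus the
10 subsequent ones, `X_fnirs ∈ R^{11x16x16x30x2}`, to bridge the hemodynamic
lag.  Three 3D-CNN branches (EEG, fNIRS, fusion — the fusion branch consumes
the EEG tensor) feed two fusion mechanisms:

```
F̂_fusion = γ·F_eeg + (1-γ)·F_fusion + Φ ⊙ F_fusion
Φ        = α·σ(GAP(conv(F_fnirs))) + (1-α)·σ(GAP(conv(F_eeg)))
```

with trainable gates γ, α ∈ [0,1] (EFGF), followed by bidirectional
multi-head cross-attention between the 11 fNIRS segment tokens and the 16
spatial fusion tokens (CAFE), `Attention(Q,K,V) = softmax(QKᵀ/√d_k)V`.
Each branch ends in a two-layer softmax head; decision fusion averages the
sigmoid-weighted branch scores.  The objective is

```
L = L_pred + λ_eeg·L_eeg + λ_fnirs·L_fnirs + L_fusion + L_efgf + L_cafe
```

with cross-entropy classification terms (λ = 0.2) and two Pearson-correlation
regularizers in [0, 2] that pull the attention map toward the pooled EEG
feature map and the enhanced fNIRS features toward the enhanced fusion
features.  Training follows a two-stage protocol: stage 1 on a 4:1
trial-level split with early stopping on validation accuracy (patience 50,
cap 300 epochs), stage 2 on the full training set until the training loss
falls below the stage-1 reference (cap 200); evaluation is cross-session
hold-out (each session tested once, mean accuracy and Cohen's kappa
reported).

The network is implemented on a compact NumPy reverse-mode autodiff core
(`tsfnet.autograd` / `tsfnet.nn`) with numba-compiled conv patch kernels —
no deep-learning framework required.

## Worked example

```python
from tsfnet import SimulationConfig, TSFNetModel
from tsfnet.network import ModelConfig
from tsfnet.training import TrainConfig

model = TSFNetModel.from_simulation(
    SimulationConfig(seed=7),
    model_config=ModelConfig(width_scale=0.125, cafe_dim=32, head_hidden=32,
                             dropout=0.3),
    train_config=TrainConfig(stage1_max_epochs=30, stage2_max_epochs=20),
)
results = model.fit()
print(results.summary())
```

prints (abridged; ~15 min on one CPU):

```
Temporal-Spatial Fusion Network — cross-session hold-out
==========================================================
variant: full         conv width scale: 0.125
CAFE dim/heads: 32/4    samples: 600
----------------------------------------------------------
fold (test session)       accuracy     kappa       n
0                           0.9450    0.8900     200
1                           0.8100    0.6200     200
2                           0.7600    0.5200     200
----------------------------------------------------------
mean ± std                  0.8383    0.6767
                           ±0.0781
----------------------------------------------------------
learned fusion parameters (mean over folds):
  w_eeg          0.4941
  w_fusion       0.5058
  w_fnirs        0.5029
```

Each fold trains on two sessions and tests on the held-out one; `accuracy`
is the fraction of correctly classified 3-s windows and `kappa` the
chance-corrected agreement `(p0 - pe)/(1 - pe)`.
`results.per_window(branch)` exposes the per-window accuracy curves: here
the EEG branch reaches its plateau (0.83) already at window right-edge 2 s
and declines after 7 s as the simulated desynchronization adapts away, while
the fNIRS branch first attains its maximum (0.87) at 4 s — the hemodynamic
lag signature.

A command-line interface covers the same pipeline:
`tsfnet simulate|preprocess|tensorize|train|evaluate|ablate|run` (see
`tsfnet --help`).

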