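"""The temporal-spatial fusion network.

Three parallel 3D-CNN branches (EEG, fNIRS, fusion — the fusion branch
consumes the EEG tensor) feed two fusion mechanisms:

* **EFGF** (EEG-fNIRS-guided fusion), applied after each fusion-branch conv
  block: a hybrid spatial attention map is built from a sigmoid of the
  temporally pooled single-channel convolution of the EEG features and of the
  fNIRS features, mixed by a trainable gate ``alpha`` in [0, 1]; the fusion
  features are modulated by the map and combined with a trainable residual
  ``gamma`` in [0, 1] on the EEG features::

      fused = gamma * F_eeg + (1 - gamma) * F_fusion + Phi * F_fusion
      Phi   = alpha * sigmoid(GAP(conv(F_fnirs))) + (1 - alpha) * sigmoid(GAP(conv(F_eeg)))

* **CAFE** (cross-attention feature enhancement): the 11 post-GAP fNIRS
  segment features become tokens (plus learnable positional encodings), the
  16 spatial fusion features become tokens; two multi-head cross-attention
  streams exchange information bidirectionally and a per-stream sigmoid gate
  mixes attended with original tokens.

Each branch ends in a two-layer softmax head; the three probability pairs are
combined by decision fusion with trainable sigmoid weights.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .autograd import Tensor, concatenate, softmax, as_tensor
from .nn import (Adam, BatchNorm, Conv3d, Dropout, Linear, Module, Parameter,
                 temporal_mean_conv)

VARIANTS = ("full", "no_efgf", "no_cafe")

# kernel geometry of the two conv layers per branch (spatial, spatial, temporal)
EEG_CONV = (((4, 4, 12), (2, 2, 6), 16), ((2, 2, 6), (2, 2, 2), 32))
FNIRS_CONV = (((4, 4, 6), (2, 2, 2), 16), ((2, 2, 3), (2, 2, 2), 32))
EFGF_KERNELS = (((2, 2, 6), (2, 2, 3)), ((2, 2, 3), (2, 2, 3)))  # (eeg, fnirs) per layer


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters of the network; defaults follow the published layout."""

    variant: str = "full"
    width_scale: float = 1.0          # scales conv channel counts (reduced-width runs)
    cafe_dim: int = 512
    cafe_heads: int = 4
    head_hidden: int = 64
    dropout: float = 0.5
    fuse_mean: str = "three"          # "three": divide by 3; "weights": divide by sum w
    seed: int = 0

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; expected one of {VARIANTS}")
        if self.cafe_dim % self.cafe_heads:
            raise ValueError("cafe_dim must be divisible by cafe_heads")
        if self.fuse_mean not in ("three", "weights"):
            raise ValueError("fuse_mean must be 'three' or 'weights'")

    def channels(self) -> tuple[int, int]:
        c1 = max(1, int(round(EEG_CONV[0][2] * self.width_scale)))
        c2 = max(1, int(round(EEG_CONV[1][2] * self.width_scale)))
        return c1, c2


class PostConv(Module):
    """ELU -> batch norm -> dropout, the tail of every conv block."""

    def __init__(self, channels, dropout, rng):
        super().__init__()
        self.bn = BatchNorm(channels)
        self.drop = Dropout(dropout, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.drop(self.bn(x.elu()))


class ConvBlock(Module):
    """conv -> ELU -> batch norm -> dropout (dropout active in training only)."""

    def __init__(self, cin, cout, kernel, stride, dropout, rng):
        super().__init__()
        self.conv = Conv3d(cin, cout, kernel, stride, rng)
        self.post = PostConv(cout, dropout, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.post(self.conv(x))


def gap_temporal(x: Tensor, segment_axis: bool = False) -> Tensor:
    """Mean over the temporal axis (and the segment axis for fNIRS features).

    Input layout (..., h, w, t, channels); the temporal axis is -2.
    """
    x = as_tensor(x)
    if segment_axis:
        return x.mean(axis=(1, x.ndim - 2))
    return x.mean(axis=x.ndim - 2)


def scaled_dot_attention(q, k, v):
    """softmax(Q K^T / sqrt(d_k)) V with rows of the softmax summing to 1."""
    q, k, v = as_tensor(q), as_tensor(k), as_tensor(v)
    d_k = k.shape[-1]
    if d_k == 0:
        raise ValueError("key dimensionality must be positive")
    if q.shape[-1] != d_k:
        raise ValueError("query and key dimensionality differ")
    scores = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(d_k))
    return softmax(scores, axis=-1) @ v


class Efgf(Module):
    """One EEG-fNIRS-guided fusion layer.

    ``gamma`` and ``alpha`` are stored as unconstrained scalars initialized to
    zero and clipped to [0, 1] after each optimizer update (see
    ``TSFNet.clamped_parameters``).
    """

    def __init__(self, c_eeg: int, c_fnirs: int, kernel_eeg, kernel_fnirs, rng):
        super().__init__()
        self.gamma = Parameter(np.zeros((), dtype=np.float32))
        self.alpha = Parameter(np.zeros((), dtype=np.float32))
        self.conv_eeg = Conv3d(c_eeg, 1, kernel_eeg, (1, 1, 1), rng)
        self.conv_fnirs = Conv3d(c_fnirs, 1, kernel_fnirs, (1, 1, 1), rng)

    def fnirs_gate(self, fnirs_windows: Tensor, seg_map: np.ndarray) -> tuple[Tensor, tuple]:
        """Pre-sigmoid pooled fNIRS gate map, one (h, w) map per sample.

        ``fnirs_windows`` holds the distinct conv features (U, h, w, t', C);
        ``seg_map`` (N, S) indexes each sample's segments into them, so shared
        windows are convolved once.  GAP runs over the temporal axis per
        window and over the segment axis after the gather.
        """
        cw = self.conv_fnirs.weight
        pooled_u = temporal_mean_conv(fnirs_windows, cw, self.conv_fnirs.bias)
        pooled = pooled_u[seg_map]                                         # (N, S, h, w)
        shape = (seg_map.shape[1], *pooled_u.shape[1:3], fnirs_windows.shape[3], 1)
        return pooled.mean(axis=1), shape

    def __call__(self, f_eeg: Tensor, f_fusion: Tensor,
                 fnirs_gate_pooled: Tensor) -> tuple[Tensor, Tensor]:
        if f_eeg.shape != f_fusion.shape:
            raise ValueError("EEG and fusion features must have identical shapes")
        n, h, w, t, _ = f_eeg.shape
        a_eeg = temporal_mean_conv(
            f_eeg, self.conv_eeg.weight, self.conv_eeg.bias).sigmoid()     # (N, h, w)
        a_fn = fnirs_gate_pooled.sigmoid()
        phi = self.alpha * a_fn + (1.0 - self.alpha) * a_eeg
        phi_b = phi.reshape(n, h, w, 1, 1)
        fused = self.gamma * f_eeg + (1.0 - self.gamma) * f_fusion + phi_b * f_fusion
        return fused, phi


def efgf_forward(layer: Efgf, f_eeg, f_fnirs, f_fusion) -> tuple[Tensor, Tensor]:
    """Spec-shaped EFGF application on per-sample fNIRS feature stacks.

    ``f_fnirs`` has shape (N, S, h', w', t', C); the segment axis is folded
    for the single-channel convolution and pooled for the gate map.
    """
    f_fnirs = as_tensor(f_fnirs)
    n, s = f_fnirs.shape[:2]
    windows = f_fnirs.reshape(n * s, *f_fnirs.shape[2:])
    seg_map = np.arange(n * s).reshape(n, s)
    pooled, _ = layer.fnirs_gate(windows, seg_map)
    return layer(as_tensor(f_eeg), as_tensor(f_fusion), pooled)


class CrossAttentionStream(Module):
    """Multi-head cross-attention with a sigmoid-gated residual mix."""

    def __init__(self, dim: int, heads: int, rng):
        super().__init__()
        self.wq = Linear(dim, dim, rng)
        self.wk = Linear(dim, dim, rng)
        self.wv = Linear(dim, dim, rng)
        self.wo = Linear(dim, dim, rng)
        self.gate = Parameter(np.zeros((), dtype=np.float32))
        self.heads = heads
        self.dim = dim

    def _split(self, x: Tensor) -> Tensor:
        n, t, _ = x.shape
        return x.reshape(n, t, self.heads, self.dim // self.heads).transpose((0, 2, 1, 3))

    def __call__(self, query_tokens: Tensor, context_tokens: Tensor) -> Tensor:
        q = self._split(self.wq(query_tokens))
        k = self._split(self.wk(context_tokens))
        v = self._split(self.wv(context_tokens))
        att = scaled_dot_attention(q, k, v)                     # (N, H, Tq, dh)
        n, _, tq, _ = att.shape
        merged = att.transpose((0, 2, 1, 3)).reshape(n, tq, self.dim)
        attended = self.wo(merged)
        g = self.gate.sigmoid()
        return g * attended + (1.0 - g) * query_tokens


class Cafe(Module):
    """Bidirectional cross-attention between fNIRS segment tokens and fusion
    spatial tokens, both projected to a common model dimension."""

    def __init__(self, fnirs_token_dim: int, fusion_token_dim: int,
                 dim: int, heads: int, rng):
        super().__init__()
        self.pos_enc = Parameter(rng.normal(0.0, 0.02, (11, fnirs_token_dim)).astype(np.float32))
        self.proj_fnirs = Linear(fnirs_token_dim, dim, rng)
        self.proj_fusion = Linear(fusion_token_dim, dim, rng)
        self.stream_fnirs = CrossAttentionStream(dim, heads, rng)   # fNIRS attends to fusion
        self.stream_fusion = CrossAttentionStream(dim, heads, rng)  # fusion attends to fNIRS
        self.dim = dim

    def __call__(self, f_fnirs: Tensor, f_fusion: Tensor) -> tuple[Tensor, Tensor]:
        n = f_fnirs.shape[0]
        fnirs_tokens = f_fnirs.reshape(n, 11, -1) + self.pos_enc
        fusion_tokens = f_fusion.reshape(n, -1, f_fusion.shape[-1])
        fnirs_p = self.proj_fnirs(fnirs_tokens)
        fusion_p = self.proj_fusion(fusion_tokens)
        enhanced_fnirs = self.stream_fnirs(fnirs_p, fusion_p)
        enhanced_fusion = self.stream_fusion(fusion_p, fnirs_p)
        return enhanced_fnirs, enhanced_fusion


class Head(Module):
    """Two dense layers (ELU between) followed by a binary softmax."""

    def __init__(self, n_in: int, hidden: int, rng):
        super().__init__()
        self.fc1 = Linear(n_in, hidden, rng)
        self.fc2 = Linear(hidden, 2, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return softmax(self.fc2(self.fc1(x).elu()), axis=-1)


def decision_fuse(y_eeg, y_fusion, y_fnirs, raw_weights, mode: str = "three") -> Tensor:
    """Weighted mean of the branch scores with sigmoid weights.

    ``mode='three'`` divides by 3 (a mean over the three weighted scores);
    ``mode='weights'`` divides by the sum of the weights instead.
    """
    y_eeg, y_fusion, y_fnirs = as_tensor(y_eeg), as_tensor(y_fusion), as_tensor(y_fnirs)
    raw = as_tensor(raw_weights)
    w = raw.sigmoid()
    total = w[0] * y_eeg + w[1] * y_fusion + w[2] * y_fnirs
    if mode == "three":
        return total * (1.0 / 3.0)
    return total / (w[0] + w[1] + w[2])


@dataclass
class ForwardResult:
    """Per-branch probabilities, fused score, and the auxiliary activations
    the regularization losses consume."""

    y_eeg: Tensor
    y_fnirs: Tensor
    y_fusion: Tensor
    y_pred: Tensor
    phi_maps: list[Tensor] = field(default_factory=list)        # (N,h,w) per EFGF layer
    eeg_maps: list[Tensor] = field(default_factory=list)        # (N,h,w) per EFGF layer
    enhanced_fnirs: Tensor | None = None                        # (N, 11, d)
    enhanced_fusion: Tensor | None = None                       # (N, 16, d)
    conv_shapes: dict = field(default_factory=dict)


class TSFNet(Module):
    """Three-branch EEG/fNIRS fusion classifier.

    Variants: ``full``; ``no_efgf`` (the fusion branch runs the EEG tensor
    through its convolutions without attention/gates); ``no_cafe`` (heads
    consume the raw flattened post-GAP features).
    """

    def __init__(self, config: ModelConfig = ModelConfig()):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.rng = rng
        c1, c2 = config.channels()
        dr = config.dropout

        # the EEG and fusion branches share the conv1 input (the EEG tensor)
        # and kernel geometry, so their first convolutions are evaluated as one
        # 2*c1-channel convolution and split — one patch gather instead of two
        self.front1 = Conv3d(1, 2 * c1, EEG_CONV[0][0], EEG_CONV[0][1], rng)
        self.eeg1_post = PostConv(c1, dr, rng)
        self.fusion1_post = PostConv(c1, dr, rng)
        self.eeg2 = ConvBlock(c1, c2, EEG_CONV[1][0], EEG_CONV[1][1], dr, rng)
        self.fnirs1 = ConvBlock(2, c1, FNIRS_CONV[0][0], FNIRS_CONV[0][1], dr, rng)
        self.fnirs2 = ConvBlock(c1, c2, FNIRS_CONV[1][0], FNIRS_CONV[1][1], dr, rng)
        self.fusion2 = ConvBlock(c1, c2, EEG_CONV[1][0], EEG_CONV[1][1], dr, rng)

        if config.variant != "no_efgf":
            self.efgf1 = Efgf(c1, c1, EFGF_KERNELS[0][0], EFGF_KERNELS[0][1], rng)
            self.efgf2 = Efgf(c2, c2, EFGF_KERNELS[1][0], EFGF_KERNELS[1][1], rng)

        eeg_feat = 4 * 4 * c2
        if config.variant != "no_cafe":
            self.cafe = Cafe(eeg_feat, c2, config.cafe_dim, config.cafe_heads, rng)
            fusion_in = 16 * config.cafe_dim
            fnirs_in = 11 * config.cafe_dim
        else:
            fusion_in = eeg_feat
            fnirs_in = 11 * eeg_feat
        self.head_eeg = Head(eeg_feat, config.head_hidden, rng)
        self.head_fusion = Head(fusion_in, config.head_hidden, rng)
        self.head_fnirs = Head(fnirs_in, config.head_hidden, rng)
        self.fuse_weights = Parameter(np.zeros(3, dtype=np.float32))

    # parameters clipped to [0, 1] after every optimizer step
    def clamped_parameters(self) -> list[Parameter]:
        if self.config.variant == "no_efgf":
            return []
        return [self.efgf1.gamma, self.efgf1.alpha, self.efgf2.gamma, self.efgf2.alpha]

    def __call__(self, eeg, fnirs) -> ForwardResult:
        """Forward on per-sample tensors: eeg (N, 16, 16, 600), fnirs
        (N, 11, 16, 16, 30, 2).  Thin wrapper over :meth:`forward_windows`
        with every segment treated as distinct."""
        fnirs = as_tensor(fnirs)
        n, s = fnirs.shape[:2]
        windows = fnirs.reshape(n * s, *fnirs.shape[2:])
        seg_map = np.arange(n * s).reshape(n, s)
        return self.forward_windows(eeg, windows, seg_map)

    def forward_windows(self, eeg, fnirs_windows, seg_map: np.ndarray,
                        front_cols: np.ndarray | None = None,
                        front_shape: tuple[int, int, int] = (8, 8, 100)) -> ForwardResult:
        """Forward pass with deduplicated fNIRS windows.

        ``fnirs_windows`` (U, 16, 16, 30, 2) holds each distinct 3-s fNIRS
        window of the batch once; ``seg_map`` (N, 11) indexes every sample's
        segment stack into it.  Because the fNIRS convolutions treat segments
        independently, convolving the distinct windows and gathering the
        results is equivalent in evaluation mode to convolving the stacks
        (and is how overlapping stacks are trained efficiently; batch-norm
        statistics are then taken over distinct windows).
        """
        wins = as_tensor(fnirs_windows)
        shapes: dict[str, tuple] = {}
        n_seg = seg_map.shape[1]

        if front_cols is not None:
            # patches of the EEG tensor were precomputed by the caller
            from .nn import conv3d_from_patches
            n = front_cols.shape[0]
            front = conv3d_from_patches(front_cols, self.front1.weight,
                                        self.front1.bias, front_shape, release=True)
        else:
            eeg = as_tensor(eeg)
            n = eeg.shape[0]
            x_e = eeg.reshape(n, 16, 16, eeg.shape[3], 1)
            front = self.front1(x_e)
        c1 = front.shape[-1] // 2
        e1 = self.eeg1_post(front[..., :c1]); shapes["eeg_conv1"] = e1.shape[1:]
        u1 = self.fusion1_post(front[..., c1:]); shapes["fusion_conv1"] = u1.shape[1:]
        e2 = self.eeg2(e1); shapes["eeg_conv2"] = e2.shape[1:]

        n1 = self.fnirs1(wins)
        shapes["fnirs_conv1"] = (n_seg, *n1.shape[1:])
        n2 = self.fnirs2(n1)
        shapes["fnirs_conv2"] = (n_seg, *n2.shape[1:])

        phi_maps, eeg_maps = [], []
        if self.config.variant != "no_efgf":
            gate1, sh_fn1 = self.efgf1.fnirs_gate(n1, seg_map)
            u1, phi1 = self.efgf1(e1, u1, gate1)
            shapes["efgf1_conv_eeg"] = (*phi1.shape[1:], e1.shape[3], 1)
            shapes["efgf1_conv_fnirs"] = sh_fn1
            phi_maps.append(phi1)
            eeg_maps.append(e1.mean(axis=(3, 4)))
        u2 = self.fusion2(u1); shapes["fusion_conv2"] = u2.shape[1:]
        if self.config.variant != "no_efgf":
            gate2, sh_fn2 = self.efgf2.fnirs_gate(n2, seg_map)
            u2, phi2 = self.efgf2(e2, u2, gate2)
            shapes["efgf2_conv_eeg"] = (*phi2.shape[1:], e2.shape[3], 1)
            shapes["efgf2_conv_fnirs"] = sh_fn2
            phi_maps.append(phi2)
            eeg_maps.append(e2.mean(axis=(3, 4)))

        f_eeg = gap_temporal(e2)                                  # (N, 4, 4, c2)
        f_fusion = gap_temporal(u2)                               # (N, 4, 4, c2)
        c2 = n2.shape[-1]
        f_fnirs = gap_temporal(n2)[seg_map]                       # (N, 11, 4, 4, c2)

        flat_eeg = f_eeg.reshape(n, -1)
        enhanced_fnirs = enhanced_fusion = None
        if self.config.variant != "no_cafe":
            seg_tokens = f_fnirs.reshape(n, n_seg, -1)
            enhanced_fnirs, enhanced_fusion = self.cafe(
                seg_tokens, f_fusion.reshape(n, 16, c2))
            flat_fusion = enhanced_fusion.reshape(n, -1)
            flat_fnirs = enhanced_fnirs.reshape(n, -1)
        else:
            flat_fusion = f_fusion.reshape(n, -1)
            flat_fnirs = f_fnirs.reshape(n, -1)

        y_eeg = self.head_eeg(flat_eeg)
        y_fusion = self.head_fusion(flat_fusion)
        y_fnirs = self.head_fnirs(flat_fnirs)
        y_pred = decision_fuse(y_eeg, y_fusion, y_fnirs, self.fuse_weights,
                               self.config.fuse_mean)
        return ForwardResult(
            y_eeg=y_eeg, y_fnirs=y_fnirs, y_fusion=y_fusion, y_pred=y_pred,
            phi_maps=phi_maps, eeg_maps=eeg_maps,
            enhanced_fnirs=enhanced_fnirs, enhanced_fusion=enhanced_fusion,
            conv_shapes=shapes,
        )

    # -- persistence ---------------------------------------------------------
    def save_checkpoint(self, path: str | Path) -> Path:
        path = Path(path)
        np.savez(path.with_suffix(".npz"), **self.state_dict())
        sidecar = asdict(self.config)
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
        return path.with_suffix(".npz")

    @classmethod
    def load_checkpoint(cls, path: str | Path) -> "TSFNet":
        path = Path(path)
        config = ModelConfig(**json.loads(path.with_suffix(".json").read_text()))
        model = cls(config)
        with np.load(path.with_suffix(".npz")) as data:
            model.load_state_dict({k: data[k] for k in data.files})
        return model


def build_model(variant: str = "full", config: ModelConfig | None = None, **overrides) -> TSFNet:
    """Construct a network variant; unknown variants raise."""
    if config is None:
        config = ModelConfig(variant=variant, **overrides)
    elif overrides or config.variant != variant:
        config = ModelConfig(**{**asdict(config), "variant": variant, **overrides})
    return TSFNet(config)


def make_optimizer(model: TSFNet, lr: float = 1e-3) -> Adam:
    return Adam(model.parameters(), lr=lr)


def clamp_gates(model: TSFNet) -> None:
    """Clip the EFGF residual/gate scalars to [0, 1] (call after each step)."""
    for p in model.clamped_parameters():
        p.data = np.clip(p.data, 0.0, 1.0)
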