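"""Training objective: branch cross-entropies plus correlation regularizers.

The total loss is::

    L = L_class + L_efgf + L_cafe
    L_class = L_pred + lambda_eeg * L_eeg + lambda_fnirs * L_fnirs + L_fusion

where every ``L_*`` classification term is a mean binary cross-entropy and
the two regularizers reward Pearson correlation (PCC): ``L_efgf`` between the
temporally/channel-averaged EEG feature map and the hybrid attention map of
each fusion layer, ``L_cafe`` between the (segment- and position-pooled)
enhanced fNIRS and enhanced fusion features.  Both regularizers lie in
[0, 2] because PCC lies in [-1, 1].

The printed form of the PCC denominator in the source material lacks the
squares/square root (which would make it degenerate); the standard Pearson
formula is used.  A variance guard returns 0 (uncorrelated) instead of NaN
for constant inputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .autograd import Tensor, as_tensor

EPS_LOG = 1e-7
EPS_VAR = 1e-12


@dataclass(frozen=True)
class LossWeights:
    """Classification loss weights and regularizer switches."""

    lambda_eeg: float = 0.2
    lambda_fnirs: float = 0.2
    efgf_reg: bool = True
    cafe_reg: bool = True

    def __post_init__(self):
        if self.lambda_eeg < 0 or self.lambda_fnirs < 0:
            raise ValueError("loss weights must be nonnegative")


@dataclass(frozen=True)
class LossBreakdown:
    """All scalar terms of the objective (nats)."""

    L_pred: float
    L_eeg: float
    L_fnirs: float
    L_fusion: float
    L_class: float
    L_efgf: float
    L_cafe: float
    L_total: float


def _check_labels(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    if not np.isin(labels, [0, 1]).all():
        raise ValueError("labels must be binary (0/1)")
    return labels.astype(np.int64)


def cross_entropy(probabilities, labels) -> Tensor:
    """Mean negative log probability of the true class.

    Probabilities are clipped to [1e-7, 1 - 1e-7] before the log.
    """
    probs = as_tensor(probabilities)
    labels = _check_labels(labels)
    onehot = np.zeros(probs.shape, dtype=probs.dtype)
    onehot[np.arange(len(labels)), labels] = 1.0
    p_true = (probs * Tensor(onehot)).sum(axis=-1)
    return -(p_true.clip(EPS_LOG, 1.0 - EPS_LOG).log().mean())


def renormalize(scores) -> Tensor:
    """Scale score pairs to the probability simplex (guarded by eps).

    The fused decision score is a weighted mean and need not sum to 1; it is
    renormalized before entering the cross-entropy so the loss stays a proper
    log score while the argmax is preserved.
    """
    scores = as_tensor(scores)
    total = scores.sum(axis=-1, keepdims=True).clip(EPS_LOG, np.inf)
    return scores / total


def pcc(u, v) -> Tensor:
    """Pearson correlation of two equally shaped arrays over all entries.

    Returns 0 (with a warning) when either input is constant.
    """
    u, v = as_tensor(u), as_tensor(v)
    if u.shape != v.shape:
        raise ValueError(f"shape mismatch: {u.shape} vs {v.shape}")
    uc = u.reshape(-1) - u.mean()
    vc = v.reshape(-1) - v.mean()
    var_u = float((uc.data ** 2).sum())
    var_v = float((vc.data ** 2).sum())
    if var_u < EPS_VAR or var_v < EPS_VAR:
        warnings.warn("pcc of a constant input is undefined; returning 0", stacklevel=2)
        return Tensor(np.zeros((), dtype=u.dtype))
    return (uc * vc).sum() / ((uc ** 2).sum() * (vc ** 2).sum() + EPS_VAR**2).sqrt()


def _rowwise_pcc(u: Tensor, v: Tensor) -> Tensor:
    """Per-row Pearson correlation for (N, M) tensors; degenerate rows -> ~0.

    The epsilon inside the square root bounds |pcc| <= 1 and sends constant
    rows to zero without NaNs, keeping gradients finite.
    """
    uc = u - u.mean(axis=1, keepdims=True)
    vc = v - v.mean(axis=1, keepdims=True)
    cov = (uc * vc).sum(axis=1)
    denom = ((uc ** 2).sum(axis=1) * (vc ** 2).sum(axis=1) + EPS_VAR**2).sqrt()
    return cov / denom


def efgf_loss(eeg_maps, attention_maps) -> Tensor:
    """1 - mean per-sample, per-layer PCC between pooled EEG maps and
    attention maps; both arguments are sequences with one (N, h, w) entry per
    fusion layer.  Result lies in [0, 2]."""
    if len(eeg_maps) == 0 or len(eeg_maps) != len(attention_maps):
        raise ValueError("need matching per-layer EEG and attention maps")
    terms = []
    for fmap, phi in zip(eeg_maps, attention_maps):
        fmap, phi = as_tensor(fmap), as_tensor(phi)
        if fmap.shape != phi.shape:
            raise ValueError(f"map shape mismatch: {fmap.shape} vs {phi.shape}")
        n = fmap.shape[0]
        terms.append(_rowwise_pcc(fmap.reshape(n, -1), phi.reshape(n, -1)))
    total = terms[0].sum()
    for t in terms[1:]:
        total = total + t.sum()
    n_terms = sum(t.shape[0] for t in terms)
    return 1.0 - total * (1.0 / n_terms)


def cafe_loss(enhanced_fnirs, enhanced_fusion) -> Tensor:
    """1 - mean per-sample PCC between pooled enhanced fNIRS and fusion
    features.  Token inputs of shape (N, tokens, d) are mean-pooled over the
    token axis (segments / spatial positions) to (N, d) first."""
    f = as_tensor(enhanced_fnirs)
    g = as_tensor(enhanced_fusion)
    if f.ndim == 3:
        f = f.mean(axis=1)
    if g.ndim == 3:
        g = g.mean(axis=1)
    if f.shape != g.shape:
        raise ValueError(f"pooled feature length mismatch: {f.shape} vs {g.shape}")
    r = _rowwise_pcc(f, g)
    return 1.0 - r.mean()


def total_loss(result, labels, weights: LossWeights = LossWeights()) -> tuple[Tensor, LossBreakdown]:
    """Assemble the full objective from a network forward result.

    Returns the differentiable total and a float breakdown for logging.
    ``result`` needs attributes y_eeg / y_fnirs / y_fusion / y_pred and, for
    the regularizers, eeg_maps / phi_maps / enhanced_fnirs / enhanced_fusion
    (absent ones contribute 0, as in the ablated variants).
    """
    l_eeg = cross_entropy(result.y_eeg, labels)
    l_fnirs = cross_entropy(result.y_fnirs, labels)
    l_fusion = cross_entropy(result.y_fusion, labels)
    l_pred = cross_entropy(renormalize(result.y_pred), labels)
    l_class = l_pred + weights.lambda_eeg * l_eeg + weights.lambda_fnirs * l_fnirs + l_fusion

    zero = Tensor(np.zeros((), dtype=np.float64))
    l_efgf = zero
    if weights.efgf_reg and getattr(result, "phi_maps", None):
        l_efgf = efgf_loss(result.eeg_maps, result.phi_maps)
    l_cafe = zero
    if weights.cafe_reg and getattr(result, "enhanced_fnirs", None) is not None:
        l_cafe = cafe_loss(result.enhanced_fnirs, result.enhanced_fusion)

    total = l_class + l_efgf + l_cafe
    breakdown = LossBreakdown(
        L_pred=l_pred.item(), L_eeg=l_eeg.item(), L_fnirs=l_fnirs.item(),
        L_fusion=l_fusion.item(), L_class=l_class.item(),
        L_efgf=l_efgf.item(), L_cafe=l_cafe.item(), L_total=total.item(),
    )
    return total, breakdown
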