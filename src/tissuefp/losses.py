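"""Identity and style-invariance losses for fingerprint training.

For a pair of same-morphology images of core *i* rendered in two staining
styles, the composite loss is

    loss = CE(c_1, y) + CE(c_2, y) + gamma * d2_FP(fp_1, fp_2)

where ``CE`` is softmax cross-entropy against the core index and ``d2_FP``
is the squared Euclidean distance between the (epsilon-regularized)
L2-normalized fingerprints. With ``gamma = 0`` the loss reduces to plain
identity cross-entropy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LossConfig",
    "cross_entropy",
    "softmax",
    "fingerprint_distance",
    "fingerprint_distance_grad",
    "composite_loss",
    "batch_cross_entropy",
]


@dataclass
class LossConfig:
    """Composite-loss constants: style weight gamma and norm regularizer epsilon."""

    gamma: float = 0.5
    epsilon: float = 1e-6

    def __post_init__(self):
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")


def softmax(c: np.ndarray, axis: int = -1) -> np.ndarray:
    z = c - c.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def cross_entropy(c: np.ndarray, y: int) -> float:
    """-ln softmax(c)[y] for a single classification vector, 1-based label.

    Computed via log-sum-exp for numerical stability.
    """
    c = np.asarray(c, dtype=np.float64).ravel()
    if not 1 <= y <= c.size:
        raise ValueError(f"label {y} out of range 1..{c.size}")
    m = c.max()
    lse = m + np.log(np.exp(c - m).sum())
    return float(lse - c[y - 1])


def batch_cross_entropy(logits: np.ndarray, labels0: np.ndarray):
    """Mean CE over a batch (0-based labels); returns (loss, dlogits).

    dlogits is the gradient of the *mean* loss: (softmax - onehot) / N.
    """
    n = logits.shape[0]
    p = softmax(logits.astype(np.float64), axis=1)
    ll = -np.log(np.clip(p[np.arange(n), labels0], 1e-300, None))
    d = p.copy()
    d[np.arange(n), labels0] -= 1.0
    return float(ll.mean()), (d / n).astype(np.float32)


def _unit(fp: np.ndarray, eps: float) -> np.ndarray:
    fp = np.asarray(fp, dtype=np.float64)
    return fp / (np.linalg.norm(fp, axis=-1, keepdims=True) + eps)


def fingerprint_distance(fp1: np.ndarray, fp2: np.ndarray, epsilon: float = 1e-6) -> float:
    """Squared Euclidean distance between epsilon-regularized unit fingerprints.

    Ranges over [0, 4] (up to epsilon effects): 0 for identical, 2 for
    orthogonal, 4 for antipodal directions.
    """
    fp1 = np.asarray(fp1, dtype=np.float64).ravel()
    fp2 = np.asarray(fp2, dtype=np.float64).ravel()
    if fp1.shape != fp2.shape:
        raise ValueError(f"fingerprint length mismatch: {fp1.shape} vs {fp2.shape}")
    d = _unit(fp1, epsilon) - _unit(fp2, epsilon)
    return float(d @ d)


def fingerprint_distance_grad(fp1: np.ndarray, fp2: np.ndarray, epsilon: float = 1e-6):
    """Gradients of ``fingerprint_distance`` w.r.t. fp1 and fp2 (batched rows)."""
    fp1 = np.asarray(fp1, dtype=np.float64)
    fp2 = np.asarray(fp2, dtype=np.float64)
    n1 = np.linalg.norm(fp1, axis=-1, keepdims=True)
    n2 = np.linalg.norm(fp2, axis=-1, keepdims=True)
    u1 = fp1 / (n1 + epsilon)
    u2 = fp2 / (n2 + epsilon)
    diff = u1 - u2
    # d u/d fp has rows delta_ij/(n+eps) - fp_i fp_j / (n (n+eps)^2)
    proj1 = (diff * fp1).sum(axis=-1, keepdims=True)
    proj2 = (diff * fp2).sum(axis=-1, keepdims=True)
    g1 = 2.0 * (diff / (n1 + epsilon) - fp1 * proj1 / (np.clip(n1, 1e-300, None) * (n1 + epsilon) ** 2))
    g2 = -2.0 * (diff / (n2 + epsilon) - fp2 * proj2 / (np.clip(n2, 1e-300, None) * (n2 + epsilon) ** 2))
    return g1, g2


def composite_loss(c1: np.ndarray, fp1: np.ndarray, c2: np.ndarray, fp2: np.ndarray,
                   y: int, config: LossConfig | None = None) -> float:
    """CE(c1,y) + CE(c2,y) + gamma * d2_FP(fp1, fp2) for one style pair."""
    config = config or LossConfig()
    return (
        cross_entropy(c1, y)
        + cross_entropy(c2, y)
        + config.gamma * fingerprint_distance(fp1, fp2, config.epsilon)
    )
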