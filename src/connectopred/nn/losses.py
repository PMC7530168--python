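"""Training objectives: binary cross-entropy and mean absolute error.

``cross_entropy_loss`` and ``mae_loss`` are the reported quantities

    J(W,b) = -(1/N) sum_i [ y_i log p(x_i) + (1 - y_i) log(1 - p(x_i)) ]
    L(W,b) =  (1/N) sum_i | y_i - yhat_i |

evaluated on probabilities/predictions; the ``*_with_grad`` variants take
raw network outputs (logits or linear-unit outputs) and additionally
return the gradient used by the training loop.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "cross_entropy_loss",
    "mae_loss",
    "softmax",
    "softmax_cross_entropy_with_grad",
    "mae_with_grad",
]

PROB_EPS = 1e-7


def cross_entropy_loss(predictions, labels) -> float:
    """Mean negative log-likelihood of binary labels under probabilities.

    Probabilities are clipped to [eps, 1-eps] with eps = 1e-7 before the
    logarithm for numerical safety.
    """
    p = np.asarray(predictions, dtype=float)
    y = np.asarray(labels, dtype=float)
    if p.size == 0 or y.size == 0:
        raise ValueError("cross_entropy_loss requires nonempty inputs")
    if p.shape != y.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {y.shape}")
    p = np.clip(p, PROB_EPS, 1.0 - PROB_EPS)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def mae_loss(predictions, targets) -> float:
    """Mean absolute deviation between predictions and targets."""
    yhat = np.asarray(predictions, dtype=float)
    y = np.asarray(targets, dtype=float)
    if yhat.size == 0 or y.size == 0:
        raise ValueError("mae_loss requires nonempty inputs")
    if yhat.shape != y.shape:
        raise ValueError(f"shape mismatch: {yhat.shape} vs {y.shape}")
    return float(np.mean(np.abs(y - yhat)))


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy_with_grad(
    logits: np.ndarray, labels: np.ndarray
) -> tuple[float, np.ndarray]:
    """Two-way softmax cross-entropy on integer labels; grad w.r.t. logits."""
    n = logits.shape[0]
    p = softmax(logits.astype(np.float64))
    loss = cross_entropy_loss(p[:, 1], labels)
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    return loss, (grad / n).astype(logits.dtype)


def mae_with_grad(outputs: np.ndarray, targets: np.ndarray) -> tuple[float, np.ndarray]:
    """MAE on a single linear unit; subgradient sign(yhat - y)/N."""
    yhat = outputs[:, 0]
    resid = yhat - targets
    loss = float(np.mean(np.abs(resid)))
    grad = np.zeros_like(outputs)
    grad[:, 0] = np.sign(resid) / len(targets)
    return loss, grad
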