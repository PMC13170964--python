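"""Shared encoder, classifier, class weighting and the classification loss.

The encoder is a two-layer fully connected network (genes → hidden →
latent); the classifier a single fully connected layer from the latent
space to the source classes.  Forward and backward passes are written in
NumPy, with an Adam optimizer, so the whole training loop is pure NumPy.
The same encoder parameters are applied to source and target cells (the
"shared encoder" contract of the model).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence
import warnings

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "EncoderSpec",
    "ClassWeights",
    "Network",
    "Adam",
    "compute_class_weights",
    "classification_loss",
]


@dataclass(frozen=True)
class EncoderSpec:
    """Architecture of the shared encoder: genes → hidden → latent."""

    input_dim: int
    hidden_dim: int = 256
    latent_dim: int = 64
    activation: str = "relu"

    def __post_init__(self) -> None:
        if min(self.input_dim, self.hidden_dim, self.latent_dim) < 1:
            raise ValueError("all dimensions must be >= 1")
        if not (self.latent_dim <= self.hidden_dim <= self.input_dim):
            warnings.warn(
                "recommended ordering latent_dim <= hidden_dim <= input_dim violated"
            )
        if self.activation != "relu":
            raise ValueError("only 'relu' activation is implemented")


@dataclass(frozen=True)
class ClassWeights:
    """Inverse-frequency class weights.

    ``raw[i] = 1/counts[i]`` and the normalized weights satisfy
    ``sum(normalized) == n_classes``.
    """

    counts: np.ndarray
    raw: np.ndarray
    normalized: np.ndarray


def compute_class_weights(class_counts: Sequence[int]) -> ClassWeights:
    """Inverse-count weights, rescaled so they sum to the number of classes."""
    counts = np.asarray(class_counts, dtype=float)
    if counts.size == 0:
        raise ValueError("empty class counts")
    if np.any(counts < 1):
        raise ValueError("every class must have count >= 1")
    raw = 1.0 / counts
    normalized = raw / raw.sum() * counts.size
    return ClassWeights(counts=counts.astype(int), raw=raw, normalized=normalized)


class Network:
    """Two-layer encoder plus linear classifier with manual backprop.

    Parameters are He-initialized from ``rng``.  ``encode`` optionally
    returns a cache used by ``backward`` to accumulate gradients from
    both the classification head (``dlogits``) and any loss defined
    directly on the latent coordinates (``dZ``).
    """

    PARAM_NAMES = ("W1", "b1", "W2", "b2", "W3", "b3")

    def __init__(self, spec: EncoderSpec, n_classes: int, rng: np.random.Generator):
        if n_classes < 2:
            raise ValueError("need at least 2 classes")
        self.spec = spec
        self.n_classes = int(n_classes)
        m, h, d = spec.input_dim, spec.hidden_dim, spec.latent_dim
        self.params = {
            "W1": rng.standard_normal((m, h)) * np.sqrt(2.0 / m),
            "b1": np.zeros(h),
            "W2": rng.standard_normal((h, d)) * np.sqrt(2.0 / h),
            "b2": np.zeros(d),
            "W3": rng.standard_normal((d, n_classes)) * np.sqrt(2.0 / d),
            "b3": np.zeros(n_classes),
        }

    def encode(self, X: np.ndarray, return_cache: bool = False):
        """Latent representations Z = W2·relu(W1·X + b1) + b2, row-wise."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.spec.input_dim:
            raise ValueError(
                f"expected input with {self.spec.input_dim} features, got shape {X.shape}"
            )
        p = self.params
        A = X @ p["W1"] + p["b1"]
        H = np.maximum(A, 0.0)
        Z = H @ p["W2"] + p["b2"]
        if return_cache:
            return Z, {"X": X, "A": A, "H": H}
        return Z

    def classify(self, Z: np.ndarray) -> np.ndarray:
        """Logits over the source classes for latent rows ``Z``."""
        Z = np.asarray(Z, dtype=float)
        if Z.shape[1] != self.spec.latent_dim:
            raise ValueError(
                f"expected latent dim {self.spec.latent_dim}, got {Z.shape[1]}"
            )
        return Z @ self.params["W3"] + self.params["b3"]

    def backward(
        self,
        cache: dict,
        Z: np.ndarray,
        dZ: np.ndarray | None = None,
        dlogits: np.ndarray | None = None,
    ) -> dict[str, np.ndarray]:
        """Gradients of a scalar loss w.r.t. all parameters.

        ``dlogits`` is the loss gradient at the classifier output (may be
        ``None`` for unlabeled batches); ``dZ`` a gradient arriving
        directly at the latent layer (e.g. from a divergence loss).
        """
        p = self.params
        grads = {k: np.zeros_like(v) for k, v in p.items()}
        dZ_total = np.zeros_like(Z) if dZ is None else dZ.copy()
        if dlogits is not None:
            grads["W3"] = Z.T @ dlogits
            grads["b3"] = dlogits.sum(axis=0)
            dZ_total += dlogits @ p["W3"].T
        dH = (dZ_total @ p["W2"].T) * (cache["A"] > 0)
        grads["W2"] = cache["H"].T @ dZ_total
        grads["b2"] = dZ_total.sum(axis=0)
        grads["W1"] = cache["X"].T @ dH
        grads["b1"] = dH.sum(axis=0)
        return grads

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k in self.PARAM_NAMES:
            self.params[k] = np.asarray(state[k], dtype=float).copy()


def classification_loss(
    logits: np.ndarray,
    labels: np.ndarray,
    weights: ClassWeights | np.ndarray | None = None,
    override: np.ndarray | dict[int, float] | None = None,
    return_grad: bool = False,
):
    """Weighted cross-entropy: mean over cells of ``w[y_i] * NLL_i``.

    ``weights`` are the normalized per-class weights (all-ones recovers
    plain cross-entropy); ``override`` multiplies selected class weights
    (e.g. to upweight a rare cell type).  With ``return_grad`` also
    returns the gradient w.r.t. the logits.
    """
    logits = np.asarray(logits, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n, p = logits.shape
    if labels.shape[0] != n:
        raise ValueError("logits and labels must align")
    if labels.size and (labels.min() < 0 or labels.max() >= p):
        raise ValueError(f"label index outside [0, {p})")
    w = np.ones(p)
    if weights is not None:
        w = weights.normalized.copy() if isinstance(weights, ClassWeights) else np.asarray(weights, dtype=float).copy()
    if override is not None:
        if isinstance(override, dict):
            for c, mult in override.items():
                w[int(c)] *= float(mult)
        else:
            w = w * np.asarray(override, dtype=float)
    log_z = logsumexp(logits, axis=1)
    nll = log_z - logits[np.arange(n), labels]
    wc = w[labels]
    loss = float(np.mean(wc * nll))
    if not return_grad:
        return loss
    softmax = np.exp(logits - log_z[:, None])
    grad = softmax.copy()
    grad[np.arange(n), labels] -= 1.0
    grad *= wc[:, None] / n
    return loss, grad


class Adam:
    """Adam optimizer over a named-parameter dict."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, g in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            self.params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
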