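"""Training objectives: cosine-margin identity loss, age regression, joint loss.

Identity supervision uses CosFace: embeddings and class weight vectors are
unit-normalized, a fixed margin ``b`` is subtracted from the true-class cosine,
everything is scaled by ``s`` and pushed through softmax cross-entropy.  Age
supervision is a half-mean-squared-error on a linear regressor over the age
code, with raw month labels (1-12) as targets.  The total objective is

    L_w = L_id + alpha * L_grow + beta * L_id_grow

where ``L_id_grow`` is the squared batch correlation from the decorrelation
head; the defaults alpha=0.01, beta=1 are the grid-search optimum.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import nn
from .nn import tensor as F
from .nn.tensor import Tensor

DEFAULT_SCALE = 30.0
DEFAULT_MARGIN = 0.35
DEFAULT_ALPHA = 0.01
DEFAULT_BETA = 1.0
_EPS = 1e-8


class CosFaceHead(nn.Module):
    """Unit-norm class weight matrix plus the (s, b) margin configuration."""

    def __init__(self, rng, n_classes: int, embed_dim: int,
                 s: float = DEFAULT_SCALE, b: float = DEFAULT_MARGIN):
        super().__init__()
        if s <= 0:
            raise ValueError("scale s must be positive")
        if b < 0:
            raise ValueError("margin b must be nonnegative")
        self.s, self.b = float(s), float(b)
        self.n_classes = n_classes
        self.weight = nn.Parameter(
            rng.normal(0, 1.0 / np.sqrt(embed_dim), size=(n_classes, embed_dim)))

    def cosines(self, x_id) -> Tensor:
        """Cosine similarities between unit embeddings and unit class vectors."""
        x = x_id if isinstance(x_id, Tensor) else Tensor(x_id)
        xn = x / (F.sqrt((x * x).sum(axis=1, keepdims=True)) + _EPS)
        w = self.weight
        wn = w / (F.sqrt((w * w).sum(axis=1, keepdims=True)) + _EPS)
        return F.matmul(xn, transpose(wn))


def transpose(t: Tensor) -> Tensor:
    data = t.data.T

    def backward(g):
        t._accumulate(g.T)

    out = Tensor(data)
    if t.requires_grad:
        out.requires_grad = True
        out._parents = (t,)
        out._backward = backward
    return out


def cosface_loss(x_id, head: CosFaceHead, labels) -> Tensor:
    """Batch-averaged CosFace loss (margin on the true-class cosine only)."""
    labels = np.asarray(labels, dtype=int)
    if labels.size == 0:
        raise ValueError("empty batch")
    if labels.min() < 0 or labels.max() >= head.n_classes:
        raise ValueError("label out of range")
    cos = head.cosines(x_id)
    n = cos.shape[0]
    onehot = np.zeros((n, head.n_classes), dtype=np.float32)
    onehot[np.arange(n), labels] = 1.0
    logits = (cos - head.b * onehot) * head.s
    m = logits.data.max(axis=1, keepdims=True)  # constant for stability
    lse = F.log(F.exp(logits - m).sum(axis=1)) + m[:, 0]
    picked = (logits * onehot).sum(axis=1)
    return (lse - picked).mean()


class AgeRegressor(nn.Module):
    """Linear map from the age code to predicted age in months."""

    def __init__(self, rng, age_dim: int):
        super().__init__()
        self.linear = nn.Linear(rng, age_dim, 1)

    def forward(self, x_age) -> Tensor:
        x = x_age if isinstance(x_age, Tensor) else Tensor(x_age)
        return self.linear(x).reshape(-1)


def age_loss(x_age, regressor: AgeRegressor, ages) -> Tensor:
    """Half-mean-squared error: ``(1/(2m)) * sum (F_age(x_age_i) - z_i)^2``."""
    ages = np.asarray(ages, dtype=np.float32)
    if ages.size == 0:
        raise ValueError("empty batch")
    pred = regressor(x_age)
    err = pred - Tensor(ages)
    return (err * err).sum() * (1.0 / (2.0 * ages.size))


def age_rmse(x_age, regressor: AgeRegressor, ages) -> float:
    """Root-mean-squared error in months (reporting metric, not the loss)."""
    ages = np.asarray(ages, dtype=np.float64)
    with nn.no_grad():
        pred = regressor(x_age).data.astype(np.float64)
    return float(np.sqrt(np.mean((pred - ages) ** 2)))


@dataclasses.dataclass
class LossBundle:
    l_id: float
    l_grow: float
    l_corr: float
    alpha: float
    beta: float

    @property
    def l_total(self) -> float:
        return joint_loss(self.l_id, self.l_grow, self.l_corr, self.alpha, self.beta)


def joint_loss(l_id, l_grow, l_corr, alpha: float = DEFAULT_ALPHA,
               beta: float = DEFAULT_BETA):
    """Weighted combination ``l_id + alpha * l_grow + beta * l_corr``.

    Works on plain floats and on autodiff tensors alike.
    """
    return l_id + alpha * l_grow + beta * l_corr
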