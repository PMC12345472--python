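"""Attention, age/identity feature decoupling and adversarial correlation analysis.

Three pieces live here:

* **ECBAM** — channel attention computed from globally average- and max-pooled
  channel statistics through two *unshared* 1-D convolutions along the channel
  axis, blended by a trainable scalar ``alpha`` and squashed by a sigmoid,
  followed by a 7x7 spatial attention map.  A classic CBAM (shared two-layer
  MLP for the channel gate) is provided for ablations.

* **Decoupler** — the age code ``x_age`` is read off the attended feature map
  by an MLP; a second MLP maps it back to embedding space as the age residual
  ``r``, and the identity code is ``x_id = x - r``.  The bundle therefore
  satisfies ``x_id + r = x`` by construction.

* **CorrModule** — kernelized canonical-correlation head: one-hidden-layer
  perceptron maps for each code, projection vectors, and a batch Pearson
  correlation.  During training its parameters are driven by gradient *ascent*
  on the squared correlation (with a Gaussian prior realized as an L2 pull
  toward zero), while the encoder descends on the same quantity — the
  adversarial decorrelation game.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from . import nn
from .nn import tensor as F
from .nn.tensor import Tensor


def _inv_sqrt(mat: np.ndarray) -> np.ndarray:
    """Inverse matrix square root of a symmetric positive-definite matrix."""
    vals, vecs = np.linalg.eigh(mat)
    vals = np.maximum(vals, 1e-12)
    return vecs @ np.diag(vals ** -0.5) @ vecs.T


def eca_kernel_size(channels: int, gamma: int = 2, b: int = 1) -> int:
    """Adaptive odd kernel size for channel-axis convolution.

    ``t = floor((log2(C) + b) / gamma)``, rounded up to the next odd integer
    and clamped to at least 3.
    """
    if channels < 2:
        raise ValueError("need at least 2 channels")
    t = int(math.floor((math.log2(channels) + b) / gamma))
    k = t if t % 2 == 1 else t + 1
    return max(k, 3)


class ECBAM(nn.Module):
    """Efficient channel attention (two unshared 1-D convs) + spatial attention."""

    def __init__(self, rng, channels: int, spatial_kernel: int = 7,
                 gamma: int = 2, b: int = 1):
        super().__init__()
        k = eca_kernel_size(channels, gamma, b)
        if spatial_kernel % 2 == 0:
            raise ValueError("spatial kernel size must be odd")
        std = 1.0 / math.sqrt(k)
        self.conv_avg = nn.Parameter(rng.uniform(-std, std, size=k))
        self.conv_max = nn.Parameter(rng.uniform(-std, std, size=k))
        self.alpha = nn.Parameter(np.array(0.5))
        self.spatial_conv = nn.Conv2d(rng, 2, 1, spatial_kernel,
                                      pad=spatial_kernel // 2, bias=True)

    def channel_gate(self, x: Tensor) -> Tensor:
        a = F.conv1d_channels(F.global_avg_pool(x), self.conv_avg)
        m = F.conv1d_channels(F.global_max_pool(x), self.conv_max)
        mix = self.alpha * a + (1.0 - self.alpha) * m
        return F.sigmoid(mix)

    def spatial_gate(self, x: Tensor) -> Tensor:
        maps = F.concat([F.channel_mean_map(x), F.channel_max_map(x)], axis=1)
        return F.sigmoid(self.spatial_conv(maps))

    def forward(self, x) -> Tensor:
        x = x if isinstance(x, Tensor) else Tensor(x)
        g = self.channel_gate(x)
        n, c = g.shape
        xc = x * g.reshape(n, c, 1, 1)
        return xc * self.spatial_gate(xc)


class CBAM(nn.Module):
    """Classic convolutional block attention (shared-MLP channel gate + SAM)."""

    def __init__(self, rng, channels: int, reduction: int = 16,
                 spatial_kernel: int = 7):
        super().__init__()
        hidden = max(channels // reduction, 2)
        self.w1 = nn.Parameter(nn.he_init(rng, (channels, hidden), hidden))
        self.w2 = nn.Parameter(nn.he_init(rng, (hidden, channels), channels))
        self.spatial_conv = nn.Conv2d(rng, 2, 1, spatial_kernel,
                                      pad=spatial_kernel // 2, bias=True)

    def channel_gate(self, x: Tensor) -> Tensor:
        def mlp(z):
            return F.matmul(F.relu(F.matmul(z, self.w1)), self.w2)
        return F.sigmoid(mlp(F.global_avg_pool(x)) + mlp(F.global_max_pool(x)))

    def forward(self, x) -> Tensor:
        x = x if isinstance(x, Tensor) else Tensor(x)
        g = self.channel_gate(x)
        n, c = g.shape
        xc = x * g.reshape(n, c, 1, 1)
        maps = F.concat([F.channel_mean_map(xc), F.channel_max_map(xc)], axis=1)
        return xc * F.sigmoid(self.spatial_conv(maps))


def ecam_gate(feature_map, module: ECBAM) -> Tensor:
    """Channel gate vector in (0,1)^C for a feature map."""
    x = feature_map if isinstance(feature_map, Tensor) else Tensor(feature_map)
    return module.channel_gate(x)


def sam_gate(feature_map, module: ECBAM) -> Tensor:
    """Spatial gate map in (0,1)^(h x w)."""
    x = feature_map if isinstance(feature_map, Tensor) else Tensor(feature_map)
    return module.spatial_gate(x)


def ecbam(feature_map, module: ECBAM) -> Tensor:
    """Channel attention first, spatial attention second."""
    return module(feature_map)


@dataclasses.dataclass
class FeatureBundle:
    """Forward-pass artifacts: feature map, embedding and the decoupled codes.

    ``x`` is stored as the sum ``x_id + r`` evaluated once, so the
    conservation invariant holds bitwise.
    """

    F: Tensor
    x: Tensor
    x_age: Tensor
    r: Tensor
    x_id: Tensor


class Decoupler(nn.Module):
    """Nonlinear age/identity decoupling over a backbone's outputs.

    ``attention`` in {"none", "cbam", "ecbam"} gates the feature map feeding
    the age branch; ``mode`` in {"mlp", "linear", "none"} selects the residual
    map (two-layer MLP, single linear map, or no decoupling at all, in which
    case ``x_id = x``).
    """

    def __init__(self, rng, embed_dim: int, age_dim: int = 128,
                 hidden: int = 256, attention: str = "ecbam",
                 mode: str = "mlp", spatial_kernel: int = 7):
        super().__init__()
        if attention not in ("none", "cbam", "ecbam"):
            raise ValueError(f"unknown attention: {attention}")
        if mode not in ("none", "linear", "mlp"):
            raise ValueError(f"unknown decoupling mode: {mode}")
        self.mode = mode
        self.age_dim = age_dim
        if attention == "ecbam":
            self.attn = ECBAM(rng, embed_dim, spatial_kernel)
        elif attention == "cbam":
            self.attn = CBAM(rng, embed_dim, spatial_kernel=spatial_kernel)
        else:
            self.attn = None
        self.mlp_age = nn.MLP(rng, [embed_dim, hidden, age_dim])
        # normalize the age code: raw GAP-derived activations are small and
        # poorly scaled for the downstream regression and residual maps
        self.age_bn = nn.BatchNorm(age_dim)
        if mode == "mlp":
            self.mlp_res = nn.MLP(rng, [age_dim, hidden, embed_dim])
        elif mode == "linear":
            self.mlp_res = nn.MLP(rng, [age_dim, embed_dim])
        else:
            self.mlp_res = None

    def forward(self, feature_map, x) -> FeatureBundle:
        fmap = feature_map if isinstance(feature_map, Tensor) else Tensor(feature_map)
        x = x if isinstance(x, Tensor) else Tensor(x)
        attended = self.attn(fmap) if self.attn is not None else fmap
        x_age = self.age_bn(self.mlp_age(F.global_avg_pool(attended)))
        if self.mlp_res is not None:
            r = self.mlp_res(x_age)
            x_id = x - r
        else:
            r = Tensor(np.zeros_like(x.data))
            x_id = x
        x_sum = x_id + r
        return FeatureBundle(F=fmap, x=x_sum, x_age=x_age, r=r, x_id=x_id)


def decouple(feature_map, x, decoupler: Decoupler) -> FeatureBundle:
    """Split an embedding into age code, age residual and identity code."""
    return decoupler(feature_map, x)


class CorrModule(nn.Module):
    """Kernelized correlation head for the adversarial decorrelation game.

    ``n_pairs`` projection pairs are maintained; each contributes a Pearson
    correlation between its scalar summaries of the two codes, and the
    decorrelation loss averages the squared correlations.  A single pair is
    the textbook canonical-correlation adversary; several pairs make the
    adversary harder to fool along directions it is not currently tracking.
    """

    def __init__(self, rng, id_dim: int, age_dim: int, hidden: int = 64,
                 n_pairs: int = 1, prior_strength: float = 1e-4):
        super().__init__()
        self.prior_strength = prior_strength
        self.n_pairs = n_pairs
        self.phi_u = nn.MLP(rng, [id_dim, hidden, hidden])
        self.phi_v = nn.MLP(rng, [age_dim, hidden, hidden])
        scale = 1.0 / math.sqrt(hidden)
        self.w_u = nn.Parameter(rng.normal(0, scale, (hidden, n_pairs)))
        self.w_v = nn.Parameter(rng.normal(0, scale, (hidden, n_pairs)))

    def forward(self, x_id, x_age) -> tuple[Tensor, Tensor]:
        return self.projections(x_id, x_age)

    def projections(self, x_id, x_age) -> tuple[Tensor, Tensor]:
        """Columns of (u, v) are the per-pair scalar projections, shape (n, k)."""
        x_id = x_id if isinstance(x_id, Tensor) else Tensor(x_id)
        x_age = x_age if isinstance(x_age, Tensor) else Tensor(x_age)
        if x_id.shape[0] < 2:
            raise ValueError("need a batch of at least 2")
        u = F.matmul(self.phi_u(x_id), self.w_u)
        v = F.matmul(self.phi_v(x_age), self.w_v)
        if self.n_pairs == 1:
            u = u.reshape(-1)
            v = v.reshape(-1)
        return u, v

    def solve_projections(self, x_id: np.ndarray, x_age: np.ndarray,
                          shrinkage: float = 0.1) -> None:
        """Set the projection vectors to the exact ridge-CCA maximizers.

        The inner maximization of the adversarial game has a closed form for
        fixed kernel maps: with centred kernel outputs ``H_u``, ``H_v`` and
        shrunk covariances ``S_uu``, ``S_vv``, the top-k singular vectors of
        ``S_uu^{-1/2} S_uv S_vv^{-1/2}`` give the canonical directions.  The
        projections are written in place (no gradients involved); by the
        envelope theorem the encoder's gradient through the resulting
        correlations is unaffected by holding them fixed.
        """
        with nn.no_grad():
            hu = self.phi_u(Tensor(x_id)).data.astype(np.float64)
            hv = self.phi_v(Tensor(x_age)).data.astype(np.float64)
        hu = hu - hu.mean(axis=0)
        hv = hv - hv.mean(axis=0)
        n = hu.shape[0]
        suu = hu.T @ hu / n
        svv = hv.T @ hv / n
        suv = hu.T @ hv / n
        for s in (suu, svv):
            lam = shrinkage * max(np.trace(s) / s.shape[0], 1e-8)
            s[np.diag_indices_from(s)] += lam
        iu = _inv_sqrt(suu)
        iv = _inv_sqrt(svv)
        left, _, right = np.linalg.svd(iu @ suv @ iv)
        k = self.n_pairs
        self.w_u.data = (iu @ left[:, :k]).astype(np.float32)
        self.w_v.data = (iv @ right.T[:, :k]).astype(np.float32)


def kernel_projections(x_id, x_age, corr: CorrModule):
    """Scalar projections (u, v) of the two codes through the kernel maps."""
    return corr.projections(x_id, x_age)


def batch_correlation(u, v, eps: float = 1e-8):
    """Pearson correlation of two projection vectors, in [-1, 1].

    Inputs are mean-centred before correlating.  A batch with (numerically)
    zero variance on either side yields a correlation of exactly 0, detached
    from the graph, so degenerate batches contribute no gradient.
    Returns ``(rho, degenerate_flag)``.
    """
    u = u if isinstance(u, Tensor) else Tensor(u)
    v = v if isinstance(v, Tensor) else Tensor(v)
    if u.shape != v.shape:
        raise ValueError("length mismatch")
    n = u.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples")
    uc = u - u.mean()
    vc = v - v.mean()
    su = float((uc.data ** 2).sum())
    sv = float((vc.data ** 2).sum())
    if su < eps or sv < eps:
        return Tensor(np.zeros(())), True
    denom = F.sqrt((uc * uc).sum() * (vc * vc).sum() + eps)
    rho = (uc * vc).sum() / denom
    return rho, False


def correlation_loss(rho):
    """Squared correlation — the decorrelation term of the joint loss."""
    if isinstance(rho, Tensor):
        return rho * rho
    return float(rho) ** 2


def correlation_objective(u, v, eps: float = 1e-8) -> tuple[Tensor, float]:
    """Mean squared correlation over projection pairs, plus the largest |rho|.

    For 1-D inputs this reduces to ``correlation_loss(batch_correlation(u, v))``;
    for (n, k) inputs each column pair contributes one Pearson correlation and
    the loss is their squared mean, staying in [0, 1].
    """
    u = u if isinstance(u, Tensor) else Tensor(u)
    v = v if isinstance(v, Tensor) else Tensor(v)
    if u.ndim == 1:
        rho, _ = batch_correlation(u, v, eps)
        return correlation_loss(rho), abs(float(rho.data))
    uc = u - u.mean(axis=0, keepdims=True)
    vc = v - v.mean(axis=0, keepdims=True)
    num = (uc * vc).sum(axis=0)
    den = F.sqrt((uc * uc).sum(axis=0) * (vc * vc).sum(axis=0) + eps)
    rho = num / den
    return (rho * rho).mean(), float(np.abs(rho.data).max())
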