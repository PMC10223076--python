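"""Detector-side attention operators as pure array-to-array forward passes.

Three blocks, each consuming an N x C x H x W feature map:

* **global-context fusion** — per sample, a Gram matrix over channels
  (channel vectors flattened across spatial positions) captures pairwise
  channel correlations; it is applied to the globally average-pooled
  feature, yielding an N x C x 1 x 1 fused descriptor. The block returns
  the fusion; how it is composed with the trunk (add or multiply) is the
  caller's choice.
* **omni-dimensional dynamic convolution** — a bank of candidate kernels is
  collapsed into one effective kernel by four attention factors (spatial
  position, input channel, output channel, kernel index) generated from the
  pooled input through a squeeze-excite bottleneck, then applied as a
  standard 'same' convolution.
* **coordinate attention** — directional average pooling along H and W,
  a shared channel-reducing 1x1 conv on the concatenated descriptors,
  per-direction 1x1 expansions and sigmoids, output = input re-weighted by
  both directional attention maps.

Weights, where a block has any, are seeded at construction; all operators
are deterministic.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "gcnet_fusion",
    "OdconvKernelBank",
    "odconv_forward",
    "conv2d_same",
    "CoordinateAttention",
    "coord_attention",
]


def _check_feature_map(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 4:
        raise ValueError(f"feature map must be 4-D (N,C,H,W), got ndim {x.ndim}")
    if min(x.shape) < 1:
        raise ValueError("all feature-map dimensions must be >= 1")
    if not np.all(np.isfinite(x)):
        raise ValueError("feature map must be finite")
    return x


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


# ---------------------------------------------------------------------------
# Global-context fusion
# ---------------------------------------------------------------------------

def gcnet_fusion(x: np.ndarray) -> np.ndarray:
    """Gram-matrix global-context fusion, N x C x H x W -> N x C x 1 x 1.

    Per sample: ``F_local = X X^T`` (C x C, with X the C x HW matrix of
    channel vectors), ``F_global`` the global average pool (C-vector),
    ``F_fusion = F_local @ F_global``. Cubic in the input scale.
    """
    x = _check_feature_map(x)
    n, c, h, w = x.shape
    flat = x.reshape(n, c, h * w)
    local = flat @ flat.transpose(0, 2, 1)          # (n, c, c) Gram
    global_ = flat.mean(axis=2)                      # (n, c) GAP
    fusion = np.einsum("ncd,nd->nc", local, global_)
    return fusion.reshape(n, c, 1, 1)


# ---------------------------------------------------------------------------
# Omni-dimensional dynamic convolution
# ---------------------------------------------------------------------------

def conv2d_same(x: np.ndarray, weight: np.ndarray) -> np.ndarray:
    """Plain stride-1 'same' cross-correlation. x: (N, C_in, H, W);
    weight: (C_out, C_in, k, k) with odd k."""
    n, c_in, h, w = x.shape
    c_out, c_in_w, k, _ = weight.shape
    if c_in_w != c_in:
        raise ValueError(f"kernel expects {c_in_w} input channels, got {c_in}")
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    out = np.zeros((n, c_out, h, w))
    for di in range(k):
        for dj in range(k):
            patch = xp[:, :, di:di + h, dj:dj + w]
            out += np.einsum("ncij,oc->noij", patch, weight[:, :, di, dj])
    return out


class OdconvKernelBank:
    """Bank of n candidate kernels plus the four attention generators.

    Attentions are computed from the globally pooled input through a linear
    squeeze (reduction ratio 1/16, floor 1) with ReLU, then four linear
    heads: sigmoid on the spatial (k x k), input-channel (C_in) and
    output-channel (C_out) heads, softmax on the kernel head (n).
    """

    def __init__(self, n_kernels: int, c_in: int, c_out: int, k: int = 3,
                 reduction: int = 16, seed: int = 0):
        if n_kernels < 1 or c_in < 1 or c_out < 1 or k < 1:
            raise ValueError("kernel bank dimensions must be >= 1")
        rng = np.random.default_rng(seed)
        self.n_kernels, self.c_in, self.c_out, self.k = n_kernels, c_in, c_out, k
        fan_in = c_in * k * k
        self.kernels = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                                  size=(n_kernels, c_out, c_in, k, k))
        hidden = max(1, c_in // reduction)
        self.w_squeeze = rng.normal(0.0, np.sqrt(2.0 / c_in), size=(hidden, c_in))
        scale = np.sqrt(1.0 / hidden)
        self.w_spatial = rng.normal(0.0, scale, size=(k * k, hidden))
        self.w_in = rng.normal(0.0, scale, size=(c_in, hidden))
        self.w_out = rng.normal(0.0, scale, size=(c_out, hidden))
        self.w_kernel = rng.normal(0.0, scale, size=(n_kernels, hidden))

    def attentions(self, x: np.ndarray):
        """Per-sample attention factors from the pooled input.

        Returns (alpha_spatial (n,k,k), alpha_in (n,C_in), alpha_out
        (n,C_out), alpha_kernel (n,n_kernels))."""
        pooled = x.mean(axis=(2, 3))                    # (N, C_in)
        hidden = np.maximum(pooled @ self.w_squeeze.T, 0.0)
        a_spatial = _sigmoid(hidden @ self.w_spatial.T).reshape(-1, self.k, self.k)
        a_in = _sigmoid(hidden @ self.w_in.T)
        a_out = _sigmoid(hidden @ self.w_out.T)
        logits = hidden @ self.w_kernel.T
        logits -= logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        a_kernel = e / e.sum(axis=1, keepdims=True)
        return a_spatial, a_in, a_out, a_kernel


def odconv_forward(x: np.ndarray, bank: OdconvKernelBank,
                   attentions=None) -> np.ndarray:
    """Dynamic convolution with four-way kernel attention.

    Effective kernel per sample:
    ``W_eff = sum_i alpha_kernel[i] * (alpha_spatial * alpha_in * alpha_out
    * W_i)`` with the factors broadcast over (C_out, C_in, k, k); the output
    is the plain 'same' convolution of the sample with its W_eff.

    ``attentions`` may override the generated factors (e.g. all-ones to
    recover a static convolution); it takes the tuple layout returned by
    :meth:`OdconvKernelBank.attentions`.
    """
    x = _check_feature_map(x)
    if x.shape[1] != bank.c_in:
        raise ValueError(f"input has {x.shape[1]} channels, bank expects {bank.c_in}")
    n = x.shape[0]
    a_spatial, a_in, a_out, a_kernel = (
        bank.attentions(x) if attentions is None else attentions
    )
    out = np.empty((n, bank.c_out) + x.shape[2:])
    for s in range(n):
        modulated = (bank.kernels
                     * a_spatial[s][None, None, None, :, :]
                     * a_in[s][None, None, :, None, None]
                     * a_out[s][None, :, None, None, None])
        w_eff = np.tensordot(a_kernel[s], modulated, axes=(0, 0))
        out[s] = conv2d_same(x[s:s + 1], w_eff)[0]
    return out


# ---------------------------------------------------------------------------
# Coordinate attention
# ---------------------------------------------------------------------------

class CoordinateAttention:
    """Direction-aware channel attention with reduction ratio r (default 32)."""

    def __init__(self, channels: int, reduction: int = 32, seed: int = 0):
        if channels < reduction:
            raise ValueError(
                f"channels ({channels}) must be >= reduction ratio ({reduction})"
            )
        rng = np.random.default_rng(seed)
        hidden = max(1, channels // reduction)
        self.channels = channels
        self.w_reduce = rng.normal(0.0, np.sqrt(2.0 / channels), size=(hidden, channels))
        self.w_h = rng.normal(0.0, np.sqrt(1.0 / hidden), size=(channels, hidden))
        self.w_w = rng.normal(0.0, np.sqrt(1.0 / hidden), size=(channels, hidden))

    def __call__(self, x: np.ndarray) -> np.ndarray:
        x = _check_feature_map(x)
        n, c, h, w = x.shape
        if c != self.channels:
            raise ValueError(f"input has {c} channels, block expects {self.channels}")
        pool_h = x.mean(axis=3)                     # (n, c, h): pooled along W
        pool_w = x.mean(axis=2)                     # (n, c, w): pooled along H
        cat = np.concatenate([pool_h, pool_w], axis=2)   # (n, c, h + w)
        reduced = np.maximum(
            np.einsum("ncl,dc->ndl", cat, self.w_reduce), 0.0
        )                                            # (n, hidden, h + w)
        red_h, red_w = reduced[:, :, :h], reduced[:, :, h:]
        a_h = _sigmoid(np.einsum("ndl,cd->ncl", red_h, self.w_h))  # (n, c, h)
        a_w = _sigmoid(np.einsum("ndl,cd->ncl", red_w, self.w_w))  # (n, c, w)
        return x * a_h[:, :, :, None] * a_w[:, :, None, :]


def coord_attention(x: np.ndarray, reduction: int = 32, seed: int = 0) -> np.ndarray:
    """Functional wrapper: build a seeded block for the input's channel
    count and apply it. The reduction ratio is clamped to the channel count
    so small maps remain usable."""
    x = _check_feature_map(x)
    r = min(reduction, x.shape[1])
    return CoordinateAttention(x.shape[1], reduction=r, seed=seed)(x)
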