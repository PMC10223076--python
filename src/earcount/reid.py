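"""Appearance-embedding providers.

Three things live here: the ``EmbeddingProvider`` contract the tracker
consumes, the residual-network re-identification architecture (a 128x64 crop
in, a batch-normalized 512-dim feature out) with an exact per-layer shape
trace, and a deterministic synthetic embedder used to drive the tracker in
simulation, where identities are known labels rather than image crops.

The ReID network here is an architecture with randomly initialized (seeded)
weights: the tracker's contract is "crop -> unit vector", and any provider
satisfying it — trained or not — plugs in. Training is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "EmbeddingProvider",
    "LayerSpec",
    "ReidArchitecture",
    "REID_LAYER_SPECS",
    "reid_forward_shapes",
    "SyntheticEmbedder",
    "synthetic_embed",
]


class EmbeddingProvider:
    """Contract: ``embed(inputs) -> (n, D) array of unit-norm vectors``,
    deterministic given fixed weights/seed. D is fixed per provider."""

    dim: int

    def embed(self, inputs) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError


# ---------------------------------------------------------------------------
# ReID residual architecture
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LayerSpec:
    name: str
    kind: str          # conv | maxpool | residual | gap | bn
    stride: int = 1
    out_channels: int = 0


#: Layer-by-layer plan: two stride-1 3x3 convs at 32 channels, a stride-2
#: 3x3 max pool, residual stages at 32/64/128/256 channels with stride-2
#: transitions, a 256->512 stride-1 projection stage, then global average
#: pooling and batch normalization of the 512-dim feature.
REID_LAYER_SPECS: tuple[LayerSpec, ...] = (
    LayerSpec("Conv1", "conv", 1, 32),
    LayerSpec("Conv2", "conv", 1, 32),
    LayerSpec("Max Pool 3", "maxpool", 2, 32),
    LayerSpec("Residual 4", "residual", 1, 32),
    LayerSpec("Residual 5", "residual", 1, 32),
    LayerSpec("Residual 6", "residual", 1, 32),
    LayerSpec("Residual 7", "residual", 1, 32),
    LayerSpec("Residual 8", "residual", 2, 64),
    LayerSpec("Residual 9", "residual", 1, 64),
    LayerSpec("Residual 10", "residual", 1, 64),
    LayerSpec("Residual 11", "residual", 1, 64),
    LayerSpec("Residual 12", "residual", 1, 64),
    LayerSpec("Residual 13", "residual", 1, 64),
    LayerSpec("Residual 14", "residual", 2, 128),
    LayerSpec("Residual 15", "residual", 1, 128),
    LayerSpec("Residual 16", "residual", 1, 128),
    LayerSpec("Residual 17", "residual", 1, 128),
    LayerSpec("Residual 18", "residual", 2, 256),
    LayerSpec("Residual 19", "residual", 1, 256),
    LayerSpec("Residual 20", "residual", 1, 512),
    LayerSpec("Residual 21", "residual", 1, 512),
    LayerSpec("AdaptiveAvgPool2d", "gap", 1, 512),
    LayerSpec("Batch and normalization", "bn", 1, 512),
)

REID_INPUT_SHAPE = (3, 128, 64)


def reid_forward_shapes(input_shape=REID_INPUT_SHAPE) -> list[tuple[str, tuple[int, ...]]]:
    """Per-layer output shapes for the ReID network.

    All 3x3 layers use padding 1, so stride-1 layers preserve the spatial
    extent and stride-2 layers halve it. Returns ``(layer name, shape)``
    pairs, with (C, H, W) shapes for spatial layers and (512,) for the
    pooled/normalized feature.
    """
    if tuple(input_shape) != REID_INPUT_SHAPE:
        raise ValueError(
            f"ReID network expects input shape {REID_INPUT_SHAPE}, got {tuple(input_shape)}"
        )
    _, h, w = input_shape
    trace: list[tuple[str, tuple[int, ...]]] = []
    for spec in REID_LAYER_SPECS:
        if spec.kind in ("gap", "bn"):
            trace.append((spec.name, (spec.out_channels,)))
            continue
        if spec.stride == 2:
            h, w = h // 2, w // 2
        trace.append((spec.name, (spec.out_channels, h, w)))
    return trace


def _im2col_conv(x: np.ndarray, weight: np.ndarray, stride: int) -> np.ndarray:
    """3x3 'same' convolution via im2col. x: (C_in, H, W); weight:
    (C_out, C_in, 3, 3); output (C_out, H/stride, W/stride)."""
    c_in, h, w = x.shape
    c_out = weight.shape[0]
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1)))
    h_out, w_out = h // stride, w // stride
    cols = np.empty((c_in * 9, h_out * w_out))
    idx = 0
    for di in range(3):
        for dj in range(3):
            patch = xp[:, di:di + h:stride, dj:dj + w:stride]
            cols[idx * c_in:(idx + 1) * c_in] = patch.reshape(c_in, -1)
            idx += 1
    wmat = weight.transpose(2, 3, 0, 1).reshape(9, c_out, c_in)
    wmat = np.concatenate([wmat[k] for k in range(9)], axis=1)  # (C_out, 9*C_in)
    return (wmat @ cols).reshape(c_out, h_out, w_out)


def _maxpool3x3_s2(x: np.ndarray) -> np.ndarray:
    c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1)), constant_values=-np.inf)
    h_out, w_out = h // 2, w // 2
    out = np.full((c, h_out, w_out), -np.inf)
    for di in range(3):
        for dj in range(3):
            np.maximum(out, xp[:, di:di + h:2, dj:dj + w:2], out=out)
    return out


class ReidArchitecture(EmbeddingProvider):
    """Forward pass of the residual ReID network with seeded random weights.

    Stride-2 residual stages and the channel-expanding stride-1 stages
    (256 -> 512) use a 1x1 projection shortcut; identity shortcut elsewhere.
    Output features are L2-normalized to satisfy the tracker's unit-norm
    contract.
    """

    dim = 512

    def __init__(self, seed: int = 0):
        rng = np.random.default_rng(seed)
        self._weights: dict[str, np.ndarray] = {}
        c_in = 3
        for spec in REID_LAYER_SPECS:
            if spec.kind == "conv":
                self._weights[spec.name] = self._he(rng, (spec.out_channels, c_in, 3, 3))
                c_in = spec.out_channels
            elif spec.kind == "residual":
                self._weights[spec.name + "/a"] = self._he(rng, (spec.out_channels, c_in, 3, 3))
                self._weights[spec.name + "/b"] = self._he(
                    rng, (spec.out_channels, spec.out_channels, 3, 3)
                )
                if spec.stride != 1 or spec.out_channels != c_in:
                    self._weights[spec.name + "/proj"] = self._he(
                        rng, (spec.out_channels, c_in, 1, 1)
                    )
                c_in = spec.out_channels

    @staticmethod
    def _he(rng, shape) -> np.ndarray:
        fan_in = shape[1] * shape[2] * shape[3]
        return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)

    def forward(self, x: np.ndarray) -> np.ndarray:
        """(3, 128, 64) crop -> 512-dim unit feature."""
        x = np.asarray(x, dtype=float)
        if x.shape != REID_INPUT_SHAPE:
            raise ValueError(f"expected input shape {REID_INPUT_SHAPE}, got {x.shape}")
        for spec in REID_LAYER_SPECS:
            if spec.kind == "conv":
                x = np.maximum(_im2col_conv(x, self._weights[spec.name], 1), 0.0)
            elif spec.kind == "maxpool":
                x = _maxpool3x3_s2(x)
            elif spec.kind == "residual":
                y = np.maximum(
                    _im2col_conv(x, self._weights[spec.name + "/a"], spec.stride), 0.0
                )
                y = _im2col_conv(y, self._weights[spec.name + "/b"], 1)
                proj = self._weights.get(spec.name + "/proj")
                if proj is not None:
                    c_out = proj.shape[0]
                    shortcut = np.tensordot(
                        proj.reshape(c_out, -1), x[:, ::spec.stride, ::spec.stride],
                        axes=(1, 0),
                    )
                else:
                    shortcut = x
                x = np.maximum(y + shortcut, 0.0)
            elif spec.kind == "gap":
                x = x.mean(axis=(1, 2))
            elif spec.kind == "bn":
                x = (x - x.mean()) / (x.std() + 1e-8)
        return x / np.linalg.norm(x)

    def embed(self, crops) -> np.ndarray:
        return np.stack([self.forward(c) for c in crops])


# ---------------------------------------------------------------------------
# Synthetic embedder
# ---------------------------------------------------------------------------

class SyntheticEmbedder(EmbeddingProvider):
    """Deterministic per-identity embeddings for simulation.

    Each identity gets a fixed anchor direction drawn from a seeded
    generator; a draw returns the anchor perturbed by an isotropic Gaussian
    of expected *norm* ``kappa`` (per-component std kappa/sqrt(dim)) and
    re-normalized, so within-identity cosine distance is O(kappa^2/2)
    independent of dimension. In high dimension random anchors are nearly
    orthogonal, so between-identity cosine distance concentrates near 1.
    """

    def __init__(self, dim: int = 512, kappa: float = 0.1, seed: int = 0):
        if dim < 1:
            raise ValueError("dim must be >= 1")
        self.dim = dim
        self.kappa = kappa
        self.seed = seed
        self._anchors: dict[int, np.ndarray] = {}

    def anchor(self, identity: int) -> np.ndarray:
        if identity < 0:
            raise ValueError("identity must be >= 0")
        if identity not in self._anchors:
            rng = np.random.default_rng([self.seed, identity])
            v = rng.standard_normal(self.dim)
            self._anchors[identity] = v / np.linalg.norm(v)
        return self._anchors[identity]

    def draw(self, identity: int, draw_index: int = 0) -> np.ndarray:
        """Embedding for (identity, draw_index); same arguments, same vector."""
        a = self.anchor(identity)
        if self.kappa == 0:
            return a.copy()
        rng = np.random.default_rng([self.seed, identity, draw_index, 7919])
        noise = rng.standard_normal(self.dim) / np.sqrt(self.dim)
        v = a + self.kappa * noise
        return v / np.linalg.norm(v)

    def embed(self, identities) -> np.ndarray:
        return np.stack([self.draw(int(i), k) for k, i in enumerate(identities)])


def synthetic_embed(identity: int, seed: int, dim: int = 512,
                    kappa: float = 0.0, draw_index: int = 0) -> np.ndarray:
    """Convenience wrapper: one deterministic unit vector for an identity."""
    return SyntheticEmbedder(dim=dim, kappa=kappa, seed=seed).draw(identity, draw_index)
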