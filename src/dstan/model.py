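"""The deep spatiotemporal attention network (DSTAN).

The classifier stacks L spatiotemporal convolution blocks.  Each block

1. extracts temporal features: per-node 1-D valid convolution along
   time (kernel width ``w``, summed over input channels), ReLU, then
   non-overlapping temporal average pooling of window ``s``;
2. extracts spatial features: graph convolution
   ``relu(S f_t W)`` at every timepoint, where ``S`` is the fixed
   normalized adjacency of the functional brain network;
3. computes a per-node attention map Z in (0,1)^n from the spatial
   features via a squeeze-and-excitation style bottleneck: a learned
   time-collapsing kernel per channel, channel averaging, a
   fully-connected down-map to floor(n/r) units and up-map back to n
   (both rectified), then a sigmoid;
4. reweights the spatial features by Z and fuses temporal and
   (attended) spatial features by element-wise summation.

After the last block a per-channel kernel spanning the full node x time
extent compresses each channel to a scalar, and a fully-connected layer
maps the c_L scalars to two unnormalized class scores (NC vs. MCI).

Everything is written against the in-repo autodiff engine; a model is
deterministic given its config seed.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np

from ._autodiff import Tensor
from .types import NormalizedAdjacency

__all__ = ["ModelConfig", "BlockConfig", "DstanModel", "temporal_conv",
           "graph_conv", "node_attention", "apply_attention", "fuse",
           "compress_head", "pooled_length"]


def pooled_length(T: int, w: int, s: int) -> int:
    """Time length after one block: floor((T - w + 1) / s)."""
    return (T - w + 1) // s


@dataclasses.dataclass(frozen=True)
class BlockConfig:
    """Shape parameters of one spatiotemporal convolution block."""

    w: int
    s: int
    c_in: int
    c_out: int
    t_in: int

    def __post_init__(self):
        if not 1 <= self.w <= self.t_in:
            raise ValueError(f"kernel width w={self.w} must lie in "
                             f"[1, {self.t_in}] (block input length)")
        if not 1 <= self.s <= self.t_in - self.w + 1:
            raise ValueError(f"pool window s={self.s} must lie in "
                             f"[1, {self.t_in - self.w + 1}]")

    @property
    def t_out(self) -> int:
        return pooled_length(self.t_in, self.w, self.s)


@dataclasses.dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters of the full network.

    Defaults follow the study settings: 90 nodes, 80 timepoints,
    channel widths (8, 16, 32) over three blocks, attention
    down-sampling ratio r = 16 (bottleneck width floor(n/r)).
    """

    n_nodes: int = 90
    t_in: int = 80
    channels: tuple[int, ...] = (8, 16, 32)
    w: int = 5
    s: int = 2
    attention_ratio: int = 16
    fuse_raw: bool = False
    use_attention: bool = True
    standardize: bool = True
    n_classes: int = 2
    seed: int = 0

    def __post_init__(self):
        if not self.channels:
            raise ValueError("channels must be non-empty")
        if self.attention_ratio > self.n_nodes:
            raise ValueError(f"attention_ratio {self.attention_ratio} "
                             f"exceeds n_nodes {self.n_nodes}")
        self.block_configs()  # validates the (w, s) shape recursion

    def block_configs(self) -> list[BlockConfig]:
        """Per-block shapes; raises at construction if any block's time
        axis collapses below the kernel width."""
        blocks = []
        t = self.t_in
        c_in = 1
        for c_out in self.channels:
            blk = BlockConfig(w=self.w, s=self.s, c_in=c_in, c_out=c_out,
                              t_in=t)
            if blk.t_out < 1:
                raise ValueError(f"block with t_in={t}, w={self.w}, "
                                 f"s={self.s} pools to zero timepoints")
            blocks.append(blk)
            t = blk.t_out
            c_in = c_out
        return blocks

    @property
    def bottleneck_width(self) -> int:
        return max(1, self.n_nodes // self.attention_ratio)


# ---------------------------------------------------------------------------
# functional layers (Tensor in, Tensor out)
# ---------------------------------------------------------------------------

def temporal_conv(f: Tensor, W: Tensor, b: Tensor, w: int, s: int) -> Tensor:
    """Per-node temporal convolution + ReLU + average pooling.

    ``f``: (B, n, T, c_in); ``W``: (w * c_in, c_out); output
    (B, n, floor((T-w+1)/s), c_out).
    """
    B, n, T, c_in = f.shape
    if T < w:
        raise ValueError(f"time length {T} shorter than kernel width {w}")
    t1 = T - w + 1
    windows = f.unfold_time(w)                      # (B, n, t1, w, c_in)
    flat = windows.reshape(B, n, t1, w * c_in)
    conv = (flat.matmul(W) + b).relu()              # (B, n, t1, c_out)
    tp = t1 // s
    c_out = conv.shape[-1]
    pooled = (conv.slice_axis(2, 0, tp * s)
                  .reshape(B, n, tp, s, c_out)
                  .mean(axis=3))
    return pooled


def _adjacency_values(S) -> np.ndarray:
    """Accept a NormalizedAdjacency, an (n, n) array, or a per-subject
    (B, n, n) stack."""
    values = S.values if isinstance(S, NormalizedAdjacency) else np.asarray(S)
    if values.ndim not in (2, 3) or values.shape[-1] != values.shape[-2]:
        raise ValueError(f"adjacency must be (n, n) or (B, n, n), got "
                         f"shape {values.shape}")
    return values


def graph_conv(f: Tensor, S, W: Tensor, b: Tensor) -> Tensor:
    """Graph convolution relu(S f_t W) at every timepoint.

    ``f``: (B, n, T, c_in); ``W``: (c_in, c_out); shape-preserving in
    node and time axes.  ``S`` may be one shared operator or a
    per-subject stack.
    """
    values = _adjacency_values(S)
    if f.shape[1] != values.shape[-1]:
        raise ValueError(f"node dimension {f.shape[1]} does not match "
                         f"adjacency size {values.shape[-1]}")
    return (f.node_mix(values).matmul(W) + b).relu()


def node_attention(fhat: Tensor, h: Tensor, hb: Tensor, Wd: Tensor,
                   bd: Tensor, Wu: Tensor, bu: Tensor) -> Tensor:
    """Per-node attention map Z in (0,1)^n.

    ``fhat``: (B, n, T', c); ``h``: (T', c) time-collapsing kernel per
    channel; ``Wd``: (n, n_b) / ``Wu``: (n_b, n) bottleneck maps.
    Returns Z of shape (B, n).
    """
    M = ((fhat * h).sum(axis=2) + hb).relu()        # (B, n, c)
    c_avg = M.mean(axis=2)                          # (B, n)
    down = (c_avg.matmul(Wd) + bd).relu()
    up = (down.matmul(Wu) + bu).relu()
    return up.sigmoid()


def apply_attention(Z: Tensor, fhat: Tensor) -> Tensor:
    """Broadcast the per-node map over time and channels."""
    B, n = Z.shape
    return Z.reshape(B, n, 1, 1) * fhat


def fuse(f_temp: Tensor, f_att: Tensor) -> Tensor:
    """Element-wise sum of temporal and spatial feature blocks."""
    if f_temp.shape != f_att.shape:
        raise ValueError(f"fusion shape mismatch: {f_temp.shape} vs "
                         f"{f_att.shape}")
    return f_temp + f_att


def compress_head(hL: Tensor, u: Tensor, fcW: Tensor, fcb: Tensor) -> Tensor:
    """Per-channel global compression then the classification layer.

    ``hL``: (B, n, T_L, c_L); ``u``: (n, T_L, c_L) kernels spanning the
    full node x time extent; returns (B, n_classes) scores.
    """
    scal = (hL * u).sum(axis=(1, 2))                # (B, c_L)
    return scal.matmul(fcW) + fcb


# ---------------------------------------------------------------------------
# the model
# ---------------------------------------------------------------------------

class DstanModel:
    """Parameter container + forward pass.

    Weights are fan-in-scaled uniform, biases zero, drawn from
    ``cfg.seed``.  ``forward`` returns the class-score Tensor and one
    attention-map Tensor per block (constant ones when attention is
    disabled, the ablation arm).
    """

    def __init__(self, cfg: ModelConfig):
        self.cfg = cfg
        self.blocks = cfg.block_configs()
        rng = np.random.default_rng(cfg.seed)
        self.params: dict[str, Tensor] = {}
        n, nb = cfg.n_nodes, cfg.bottleneck_width

        def uniform(name: str, shape: tuple[int, ...], fan_in: int):
            # He-style fan-in scaling keeps activation variance stable
            # through the rectified layers
            bound = np.sqrt(6.0 / fan_in)
            self.params[name] = Tensor(
                rng.uniform(-bound, bound, size=shape), requires_grad=True)

        def zeros(name: str, shape: tuple[int, ...]):
            self.params[name] = Tensor(np.zeros(shape), requires_grad=True)

        for l, blk in enumerate(self.blocks):
            uniform(f"tconv_W{l}", (blk.w * blk.c_in, blk.c_out),
                    blk.w * blk.c_in)
            zeros(f"tconv_b{l}", (blk.c_out,))
            uniform(f"gconv_W{l}", (blk.c_out, blk.c_out), blk.c_out)
            zeros(f"gconv_b{l}", (blk.c_out,))
            if cfg.use_attention:
                uniform(f"att_h{l}", (blk.t_out, blk.c_out), blk.t_out)
                zeros(f"att_hb{l}", (blk.c_out,))
                uniform(f"att_Wd{l}", (n, nb), n)
                zeros(f"att_bd{l}", (nb,))
                uniform(f"att_Wu{l}", (nb, n), nb)
                zeros(f"att_bu{l}", (n,))
        last = self.blocks[-1]
        uniform("head_u", (n, last.t_out, last.c_out), n * last.t_out)
        uniform("head_W", (last.c_out, cfg.n_classes), last.c_out)
        zeros("head_b", (cfg.n_classes,))

    # -- forward ------------------------------------------------------------

    def forward(self, X: np.ndarray, S) -> tuple[Tensor, list[Tensor]]:
        """Run the network on a batch.

        ``X``: (B, T, n) stacked subject matrices (a single subject's
        (T, n) matrix is also accepted).  ``S`` is a shared
        NormalizedAdjacency / (n, n) array, or a per-subject (B, n, n)
        stack.  Returns (scores (B, 2), [Z per block, each (B, n)]).
        """
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 2:
            X = X[None]
        B, T, n = X.shape
        cfg = self.cfg
        if (T, n) != (cfg.t_in, cfg.n_nodes):
            raise ValueError(f"input shape (T={T}, n={n}) does not match "
                             f"config (T={cfg.t_in}, n={cfg.n_nodes})")
        Sv = _adjacency_values(S)
        if n != Sv.shape[-1]:
            raise ValueError("adjacency size does not match input")
        if Sv.ndim == 3 and Sv.shape[0] != B:
            raise ValueError("per-subject adjacency stack does not match "
                             "batch size")
        if cfg.standardize:
            # per-subject, per-ROI z-scoring over time; constant columns
            # pass through as zeros
            mu = X.mean(axis=1, keepdims=True)
            sd = X.std(axis=1, keepdims=True)
            X = (X - mu) / np.where(sd == 0, 1.0, sd)

        f = Tensor(np.transpose(X, (0, 2, 1))[..., None])  # (B, n, T, 1)
        zmaps: list[Tensor] = []
        p = self.params
        for l, blk in enumerate(self.blocks):
            try:
                f_temp = temporal_conv(f, p[f"tconv_W{l}"], p[f"tconv_b{l}"],
                                       blk.w, blk.s)
                fhat = graph_conv(f_temp, S, p[f"gconv_W{l}"],
                                  p[f"gconv_b{l}"])
                if cfg.use_attention:
                    Z = node_attention(fhat, p[f"att_h{l}"], p[f"att_hb{l}"],
                                       p[f"att_Wd{l}"], p[f"att_bd{l}"],
                                       p[f"att_Wu{l}"], p[f"att_bu{l}"])
                    f_spatial = fhat if cfg.fuse_raw else apply_attention(
                        Z, fhat)
                else:
                    Z = Tensor(np.ones((B, n)))
                    f_spatial = fhat
                zmaps.append(Z)
                f = fuse(f_temp, f_spatial)
            except ValueError as err:
                raise ValueError(f"block {l}: {err}") from err
        scores = compress_head(f, p["head_u"], p["head_W"], p["head_b"])
        return scores, zmaps

    def predict(self, X: np.ndarray, S: NormalizedAdjacency) -> np.ndarray:
        """Hard class predictions (ties broken toward class 0)."""
        scores, _ = self.forward(X, S)
        s = scores.data
        return (s[:, 1] > s[:, 0]).astype(np.int64)

    # -- (de)serialization ---------------------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, v in self.params.items():
            if k not in state:
                raise KeyError(f"missing parameter {k} in checkpoint")
            if np.shape(state[k]) != v.data.shape:
                raise ValueError(f"shape mismatch for {k}")
            v.data = np.asarray(state[k], dtype=np.float64).copy()

    def save(self, path) -> None:
        blob = json.dumps(dataclasses.asdict(self.cfg))
        np.savez(path, **self.state_dict(),
                 __config__=np.frombuffer(blob.encode(), dtype=np.uint8))

    @classmethod
    def load(cls, path) -> "DstanModel":
        with np.load(path) as f:
            raw = json.loads(f["__config__"].tobytes().decode())
            raw["channels"] = tuple(raw["channels"])
            model = cls(ModelConfig(**raw))
            model.load_state_dict(
                {k: f[k] for k in f.files if k != "__config__"})
        return model
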