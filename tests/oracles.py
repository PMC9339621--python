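"""Independent brute-force reference implementations.

Everything here is written with explicit Python loops, no shared code
with the package internals, so the fast vectorized paths can be checked
against it on small instances.
"""

import numpy as np


def relu(x):
    return np.maximum(x, 0.0)


def sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def temporal_conv_loop(f, W, b, w, s):
    """f: (B, n, T, c_in); W: (w*c_in, c_out) where the kernel for
    output channel j and tap k on input channel i sits at
    W[k * c_in + i, j]."""
    B, n, T, c_in = f.shape
    c_out = W.shape[1]
    t1 = T - w + 1
    conv = np.zeros((B, n, t1, c_out))
    for bi in range(B):
        for x in range(n):
            for t in range(t1):
                for j in range(c_out):
                    acc = b[j]
                    for k in range(w):
                        for i in range(c_in):
                            acc += f[bi, x, t + k, i] * W[k * c_in + i, j]
                    conv[bi, x, t, j] = max(acc, 0.0)
    tp = t1 // s
    out = np.zeros((B, n, tp, c_out))
    for bi in range(B):
        for x in range(n):
            for t in range(tp):
                for j in range(c_out):
                    out[bi, x, t, j] = conv[bi, x, t * s:(t + 1) * s,
                                            j].mean()
    return out


def graph_conv_loop(f, S, W, b):
    """f: (B, n, T, c_in); S: (n, n); W: (c_in, c_out)."""
    B, n, T, c_in = f.shape
    c_out = W.shape[1]
    out = np.zeros((B, n, T, c_out))
    for bi in range(B):
        for t in range(T):
            mixed = S @ f[bi, :, t, :]          # (n, c_in)
            out[bi, :, t, :] = relu(mixed @ W + b)
    return out


def node_attention_loop(fhat, h, hb, Wd, bd, Wu, bu):
    """fhat: (B, n, T, c); returns Z (B, n)."""
    B, n, T, c = fhat.shape
    M = np.zeros((B, n, c))
    for bi in range(B):
        for x in range(n):
            for j in range(c):
                M[bi, x, j] = max(
                    sum(h[t, j] * fhat[bi, x, t, j] for t in range(T))
                    + hb[j], 0.0)
    c_avg = M.mean(axis=2)
    Z = np.zeros((B, n))
    for bi in range(B):
        down = relu(c_avg[bi] @ Wd + bd)
        up = relu(down @ Wu + bu)
        Z[bi] = sigmoid(up)
    return Z


def apply_attention_loop(Z, fhat):
    B, n, T, c = fhat.shape
    out = np.zeros_like(fhat)
    for bi in range(B):
        for x in range(n):
            for t in range(T):
                for j in range(c):
                    out[bi, x, t, j] = Z[bi, x] * fhat[bi, x, t, j]
    return out


def compress_head_loop(hL, u, fcW, fcb):
    """hL: (B, n, T, c); u: (n, T, c); returns (B, K) scores."""
    B, n, T, c = hL.shape
    scal = np.zeros((B, c))
    for bi in range(B):
        for j in range(c):
            scal[bi, j] = sum(u[x, t, j] * hL[bi, x, t, j]
                              for x in range(n) for t in range(T))
    return scal @ fcW + fcb


def attention_loss_loop(Z):
    """Two-pass mean/population-variance on a single map."""
    n = len(Z)
    m = sum(Z) / n
    v = sum((z - m) ** 2 for z in Z) / n
    return m - v


def cross_entropy_loop(scores, labels):
    """Mean softmax cross-entropy via explicit per-sample softmax."""
    total = 0.0
    for row, y in zip(scores, labels):
        p = np.exp(row - row.max())
        p = p / p.sum()
        total += -np.log(p[y])
    return total / len(labels)


def forward_loop(model, X, S):
    """Full forward pass of a DstanModel with loops only.

    ``X``: (B, T, n) raw input; standardization is applied here when
    the model config asks for it, mirroring the fast path.
    """
    cfg = model.cfg
    X = np.asarray(X, dtype=np.float64)
    if cfg.standardize:
        X = X.copy()
        for bi in range(X.shape[0]):
            for x in range(X.shape[2]):
                col = X[bi, :, x]
                sd = col.std()
                X[bi, :, x] = (col - col.mean()) / (sd if sd > 0 else 1.0)
    f = np.transpose(X, (0, 2, 1))[..., None]
    p = {k: v.data for k, v in model.params.items()}
    zs = []
    for l, blk in enumerate(model.blocks):
        ft = temporal_conv_loop(f, p[f"tconv_W{l}"], p[f"tconv_b{l}"],
                                blk.w, blk.s)
        fh = graph_conv_loop(ft, S, p[f"gconv_W{l}"], p[f"gconv_b{l}"])
        if cfg.use_attention:
            Z = node_attention_loop(fh, p[f"att_h{l}"], p[f"att_hb{l}"],
                                    p[f"att_Wd{l}"], p[f"att_bd{l}"],
                                    p[f"att_Wu{l}"], p[f"att_bu{l}"])
            fa = fh if cfg.fuse_raw else apply_attention_loop(Z, fh)
        else:
            Z = np.ones((X.shape[0], cfg.n_nodes))
            fa = fh
        zs.append(Z)
        f = ft + fa
    scores = compress_head_loop(f, p["head_u"], p["head_W"], p["head_b"])
    return scores, zs
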