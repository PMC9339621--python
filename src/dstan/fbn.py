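"""Functional brain network construction.

Pearson connectivity between ROI time series, proportional
lambda-sparsification (the fraction lambda of weakest-|r| undirected
connections is removed), and the symmetric normalized adjacency
D^{-1/2} (I + |V|) D^{-1/2} used as the graph-convolution propagation
operator.
"""

from __future__ import annotations

import math

import numpy as np

from .types import ConnectivityMatrix, NormalizedAdjacency, RoiTimeSeries

__all__ = ["compute_pearson", "sparsify", "normalize_adjacency",
           "group_connectivity", "edge_count_sweep", "build_adjacency"]


def compute_pearson(ts: RoiTimeSeries) -> ConnectivityMatrix:
    """Dense Pearson correlation matrix of the ROI columns."""
    X = ts.values
    if X.shape[0] < 3:
        raise ValueError(f"need at least 3 timepoints, got {X.shape[0]}")
    sd = X.std(axis=0)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        raise ValueError(f"{ts.subject_id}: constant ROI column(s) at "
                         f"index {zero.tolist()}; Pearson undefined")
    P = np.corrcoef(X, rowvar=False)
    P = np.clip((P + P.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(P, 1.0)
    return ConnectivityMatrix(values=P, sparsity=0.0)


def group_connectivity(subjects: list[RoiTimeSeries]) -> ConnectivityMatrix:
    """Group-level connectivity: the mean of per-subject Pearson
    matrices (the single shared network the classifier propagates
    over)."""
    if not subjects:
        raise ValueError("no subjects given")
    mean = np.mean([compute_pearson(s).values for s in subjects], axis=0)
    mean = np.clip((mean + mean.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(mean, 1.0)
    return ConnectivityMatrix(values=mean, sparsity=0.0)


def sparsify(P: ConnectivityMatrix, lam: float) -> ConnectivityMatrix:
    """Proportional thresholding at sparsity ``lam``.

    Zeroes the diagonal and keeps only the ``ceil((1 - lam) * m)``
    undirected connections of largest |r| (m = n(n-1)/2), with their
    signed values.  Ties at the cut magnitude are broken toward the
    lexicographically smallest (i, j) pair, so the result is unique.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"sparsity must lie in [0, 1], got {lam}")
    if not P.is_dense:
        raise ValueError("input connectivity is already sparsified")
    n = P.n_nodes
    iu, ju = np.triu_indices(n, k=1)
    vals = P.values[iu, ju]
    m = vals.size
    keep = math.ceil((1.0 - lam) * m)
    out = np.zeros((n, n))
    if keep > 0:
        # sort by (-|r|, i, j): lexicographic tie-break on index pairs
        order = np.lexsort((ju, iu, -np.abs(vals)))
        sel = order[:keep]
        out[iu[sel], ju[sel]] = vals[sel]
        out = out + out.T
    return ConnectivityMatrix(values=out, sparsity=lam,
                              node_names=P.node_names)


def normalize_adjacency(Ps: ConnectivityMatrix) -> NormalizedAdjacency:
    """Symmetric normalization of the sparsified network with
    self-loops.

    A_hat = I + |Ps| (absolute edge weights keep the degree matrix
    positive, so its inverse square root exists); D_hat is the row-sum
    degree; the operator D_hat^{-1/2} A_hat D_hat^{-1/2} has spectral
    radius at most 1 and D_hat^{1/2} 1 as an exact eigenvector with
    eigenvalue 1.
    """
    if Ps.is_dense:
        raise ValueError("normalize_adjacency expects a sparsified "
                         "(zero-diagonal) matrix")
    W = np.abs(Ps.values)
    n = Ps.n_nodes
    A_hat = np.eye(n) + W
    d = A_hat.sum(axis=1)
    d_isqrt = 1.0 / np.sqrt(d)
    S = (A_hat * d_isqrt[:, None]) * d_isqrt[None, :]
    S = (S + S.T) / 2.0
    edges = int(np.count_nonzero(np.triu(Ps.values, k=1)))
    return NormalizedAdjacency(values=S, edge_count=edges)


def edge_count_sweep(P: ConnectivityMatrix,
                     lams: np.ndarray | list[float]) -> list[tuple[float, int]]:
    """Edge counts retained across a sparsity sweep (the lambda
    histogram harness)."""
    out = []
    for lam in lams:
        edges = normalize_adjacency(sparsify(P, float(lam))).edge_count
        out.append((float(lam), edges))
    return out


def build_adjacency(subjects: list[RoiTimeSeries],
                    lam: float) -> NormalizedAdjacency:
    """Group connectivity -> sparsify -> normalize, in one call."""
    return normalize_adjacency(sparsify(group_connectivity(subjects), lam))


def subject_adjacencies(subjects: list[RoiTimeSeries],
                        lam: float) -> np.ndarray:
    """Per-subject normalized adjacency stack (B, n, n).

    Each subject's propagation operator is built from their own
    connectivity, so individual network differences feed the graph
    convolution directly (the per-subject alternative to the shared
    group network)."""
    return np.stack([
        normalize_adjacency(sparsify(compute_pearson(s), lam)).values
        for s in subjects])
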