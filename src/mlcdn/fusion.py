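"""Similarity network fusion (SNF) for multi-layer integration.

Single-layer similarity networks are converted to distances (d = 1 - rho),
passed through a locally-scaled Gaussian affinity kernel, and fused by
iterative cross-diffusion: each layer's full kernel is repeatedly propagated
through its own K-nearest-neighbour kernel while averaging over the other
layers, so that strong edges supported by several layers are reinforced and
idiosyncratic edges decay.  The fused matrix is the average of the diffused
kernels.

The procedure is deterministic: no randomness, fixed iteration count,
distance ties broken by entity order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .similarity import SimilarityNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "FusionParams",
    "AffinityMatrix",
    "similarity_to_distance",
    "affinity_matrix",
    "snf_fuse",
    "fuse_networks",
    "spectral_bipartition",
]

_EPS_FLOOR = 1e-12


@dataclass(frozen=True)
class FusionParams:
    """Parameters of the affinity kernel and the diffusion loop.

    K : number of nearest neighbours for the local kernel scale and the
        sparse diffusion kernel (clamped to n-1 for small networks).
    mu : kernel scale multiplier.
    t : number of cross-diffusion iterations (no convergence test).
    """

    K: int = 20
    mu: float = 0.5
    t: int = 20

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if not self.mu > 0:
            raise ValueError("mu must be > 0")
        if self.t < 1:
            raise ValueError("t must be >= 1")

    def clamp(self, n: int) -> "FusionParams":
        if n < 2:
            raise ValueError("need at least 2 entities")
        if self.K > n - 1:
            logger.warning("K=%d clamped to n-1=%d", self.K, n - 1)
            return FusionParams(n - 1, self.mu, self.t)
        return self


@dataclass
class AffinityMatrix:
    """Symmetric nonnegative affinity kernel over one layer's entities."""

    entity_ids: list
    W: np.ndarray
    params: FusionParams

    def __post_init__(self) -> None:
        self.entity_ids = list(self.entity_ids)
        W = np.asarray(self.W, dtype=float)
        n = len(self.entity_ids)
        if W.shape != (n, n):
            raise ValueError(f"affinity shape {W.shape} does not match {n} entities")
        if not np.isfinite(W).all():
            raise ValueError("affinity matrix contains non-finite entries")
        if np.abs(W - W.T).max(initial=0.0) > 1e-10:
            raise ValueError("affinity matrix is not symmetric")
        if (np.diag(W) <= 0).any():
            raise ValueError("affinity diagonal must be strictly positive")
        self.W = W


def similarity_to_distance(s: SimilarityNetwork) -> np.ndarray:
    """Monotone conversion d = 1 - rho (clipped at 0, zero diagonal)."""
    if s.rho.max() > 1.0 + 1e-9:
        raise ValueError("similarity entries must be <= 1")
    d = np.clip(1.0 - s.rho, 0.0, None)
    np.fill_diagonal(d, 0.0)
    return d


def _knn_mean_distance(d: np.ndarray, K: int) -> np.ndarray:
    """Mean distance from each entity to its K nearest neighbours
    (self excluded, ties broken by entity order)."""
    n = d.shape[0]
    masked = d.copy()
    np.fill_diagonal(masked, np.inf)
    out = np.empty(n)
    for i in range(n):
        order = np.argsort(masked[i], kind="stable")
        out[i] = masked[i, order[:K]].mean()
    return out


def affinity_matrix(
    d: np.ndarray,
    params: FusionParams = FusionParams(),
    entity_ids=None,
) -> AffinityMatrix:
    """Locally-scaled Gaussian kernel W(i,j) = exp(-d(i,j)^2 / (mu * eps)),
    eps(i,j) = (mean d(i, kNN(i)) + mean d(j, kNN(j)) + d(i,j)) / 3,
    floored at 1e-12 to keep the kernel defined for identical entities."""
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    if d.ndim != 2 or d.shape[1] != n:
        raise ValueError("distance matrix must be square")
    if n < 3:
        raise ValueError("need at least 3 entities")
    if np.abs(d - d.T).max(initial=0.0) > 1e-10:
        raise ValueError("distance matrix is not symmetric")
    if d.min() < 0:
        raise ValueError("distances must be nonnegative")
    if np.abs(np.diag(d)).max(initial=0.0) > 0:
        raise ValueError("distance diagonal must be zero")
    params = params.clamp(n)
    mean_knn = _knn_mean_distance(d, params.K)
    eps = (mean_knn[:, None] + mean_knn[None, :] + d) / 3.0
    eps = np.maximum(eps, _EPS_FLOOR)
    W = np.exp(-(d * d) / (params.mu * eps))
    W = (W + W.T) / 2.0  # numerically symmetric by construction; enforce
    if entity_ids is None:
        entity_ids = list(range(n))
    return AffinityMatrix(entity_ids, W, params)


def _normalize_half(W: np.ndarray) -> np.ndarray:
    """Row-normalize so off-diagonal entries sum to 1/2 and the diagonal is
    1/2 (keeps the diffusion operator stochastic and well-conditioned)."""
    n = W.shape[0]
    off = W.copy()
    np.fill_diagonal(off, 0.0)
    rowsum = off.sum(axis=1)
    rowsum[rowsum == 0] = 1.0
    P = off / (2.0 * rowsum[:, None])
    np.fill_diagonal(P, 0.5)
    return P


def _knn_kernel(W: np.ndarray, K: int) -> np.ndarray:
    """Row-normalized K-nearest-neighbour truncation of W (self excluded,
    affinity ties broken by entity order)."""
    n = W.shape[0]
    S = np.zeros_like(W)
    masked = W.copy()
    np.fill_diagonal(masked, -np.inf)
    for i in range(n):
        order = np.argsort(-masked[i], kind="stable")
        nn = order[:K]
        total = W[i, nn].sum()
        if total > 0:
            S[i, nn] = W[i, nn] / total
    return S


def snf_fuse(
    affinities: list[AffinityMatrix],
    params: FusionParams = FusionParams(),
    layer_label: str = "fused",
) -> SimilarityNetwork:
    """Fuse affinity matrices over identical entity sets by cross-diffusion.

    Each layer v keeps a full kernel P(v) (half-normalized) and a sparse
    KNN kernel S(v); for t iterations P(v) <- S(v) @ mean of the other
    layers' P @ S(v)', symmetrized and renormalized each step.  The output
    is the symmetrized average of the final P matrices.  A single input is
    self-diffused (the "other layers" average falls back to its own kernel)
    with a warning.
    """
    if not affinities:
        raise ValueError("no affinity matrices supplied")
    ids = affinities[0].entity_ids
    for a in affinities[1:]:
        if a.entity_ids != ids:
            raise ValueError("affinity matrices are defined on mismatched entity sets")
    n = len(ids)
    params = params.clamp(n)
    m = len(affinities)
    if m == 1:
        logger.warning("single affinity matrix supplied; self-diffusion only")

    P = [_normalize_half(a.W) for a in affinities]
    S = [_knn_kernel(a.W, params.K) for a in affinities]

    for _ in range(params.t):
        new_P = []
        for v in range(m):
            if m > 1:
                others = sum(P[u] for u in range(m) if u != v) / (m - 1)
            else:
                others = P[0]
            Q = S[v] @ others @ S[v].T
            Q = (Q + Q.T) / 2.0
            assert np.isfinite(Q).all()
            new_P.append(_normalize_half(Q))
        P = new_P

    fused = sum(P) / m
    fused = (fused + fused.T) / 2.0
    return SimilarityNetwork(ids, fused, layer_label, "snf")


def fuse_networks(
    networks: list[SimilarityNetwork],
    params: FusionParams = FusionParams(),
    layer_label: str = "fused",
) -> SimilarityNetwork:
    """Convenience path: similarity networks -> distances -> affinity
    kernels -> fused network."""
    if not networks:
        raise ValueError("no networks supplied")
    ids = networks[0].entity_ids
    for net in networks[1:]:
        if net.entity_ids != ids:
            raise ValueError(
                "networks are on mismatched entity sets; use align_networks first"
            )
    n = len(ids)
    params = params.clamp(n)
    affinities = [
        affinity_matrix(similarity_to_distance(net), params, entity_ids=ids) for net in networks
    ]
    return snf_fuse(affinities, params, layer_label=layer_label)


def spectral_bipartition(net: SimilarityNetwork) -> np.ndarray:
    """Two-way spectral partition of a similarity network.

    Uses the sign of the Fiedler vector of the symmetric normalized
    Laplacian; deterministic, suitable for checking planted two-block
    structure in fused networks.
    """
    W = np.clip(net.rho, 0.0, None)
    deg = W.sum(axis=1)
    if (deg <= 0).any():
        raise ValueError("isolated entity: zero total similarity")
    dinv = 1.0 / np.sqrt(deg)
    L = np.eye(W.shape[0]) - dinv[:, None] * W * dinv[None, :]
    vals, vecs = np.linalg.eigh(L)
    fiedler = vecs[:, 1]
    return (fiedler >= 0).astype(int)
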