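"""Adaptive, learnable channel adjacency and its regularisation loss.

The adjacency between channels ``m`` and ``n`` is a row-softmax over
negated, rectified, weighted feature distances:

    A[m, n] = softmax_n( -ReLU( w^T |x_m - x_n| ) )

with a learnable band-weight vector ``w``.  Rows sum to one; with
``w >= 0`` the diagonal (zero distance) carries each row's maximum.  The
weight vector is fitted by back-propagation through the joint objective;
its dedicated regulariser is

    L_gcn = tau * sum_{m,n} ||x_m - x_n||^2 A[m, n]  +  ||A||_F^2

(a graph-smoothness term weighted by ``tau`` plus a Frobenius sparsity
term).  A fixed KNN graph and a distance-based initial graph
are provided for ablations and warm starts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = [
    "AdaptiveGraphState",
    "compute_adjacency",
    "graph_regularization_loss",
    "knn_adjacency",
    "distance_initial_adjacency",
]


@dataclass
class AdaptiveGraphState:
    """Learnable weight vector, regularisation weight, and the most recent
    adjacency / loss values (for inspection and export)."""

    w: np.ndarray
    tau: float = 1e-2
    A: np.ndarray | None = None
    L_gcn: float | None = None

    def __post_init__(self):
        self.w = np.asarray(self.w, dtype=np.float64)
        if self.tau < 0:
            raise ValueError(f"tau must be >= 0, got {self.tau}")


# ----------------------------------------------------------------------
# core tensor implementation (batched: x has shape B x N x F_de)

def adjacency_t(x: Tensor, w: Tensor) -> Tensor:
    """Row-softmax adjacency from per-channel feature vectors (batched)."""
    B, N, F = x.shape
    xm = ad.reshape(x, (B, N, 1, F))
    xn = ad.reshape(x, (B, 1, N, F))
    dist = ad.einsum("bmnf,f->bmn", ad.absolute(xm - xn), w)
    return ad.softmax(-ad.relu(dist), axis=-1)


def graph_loss_t(x: Tensor, A: Tensor, tau: float) -> Tensor:
    """Smoothness + Frobenius regulariser, averaged over the batch."""
    B, N, F = x.shape
    diff = ad.reshape(x, (B, N, 1, F)) - ad.reshape(x, (B, 1, N, F))
    sq = ad.einsum("bmnf,bmnf->bmn", diff, diff)
    smooth = ad.tensor_sum(ad.mul(sq, A), axis=(-2, -1))
    frob = ad.tensor_sum(ad.mul(A, A), axis=(-2, -1))
    return ad.mean(tau * smooth + frob)


# ----------------------------------------------------------------------
def _as_node_batch(x) -> tuple[np.ndarray, bool]:
    x = np.asarray(x, dtype=np.float64)
    if x.ndim == 2:
        return x[None], True
    if x.ndim == 3:
        return x, False
    raise ValueError(f"node features must be N x F_de (optionally batched), got {x.shape}")


def compute_adjacency(x, w) -> np.ndarray:
    """Adaptive adjacency ``A`` (rows sum to 1) from node features ``x``.

    ``x`` is ``N x F_de`` (one window's per-channel features, e.g. the
    time average of a window) or a batch thereof.
    """
    xb, squeeze = _as_node_batch(x)
    w = np.asarray(w, dtype=np.float64)
    if w.shape != (xb.shape[2],):
        raise ValueError(f"w must have length F_de={xb.shape[2]}, got shape {w.shape}")
    A = adjacency_t(ad.tensor(xb), ad.tensor(w)).value
    return A[0] if squeeze else A


def graph_regularization_loss(x, A, tau: float) -> float:
    """``tau * sum ||x_m - x_n||^2 A_mn + ||A||_F^2`` (batch mean if batched)."""
    xb, _ = _as_node_batch(x)
    A = np.asarray(A, dtype=np.float64)
    Ab = A[None] if A.ndim == 2 else A
    if Ab.shape != (xb.shape[0], xb.shape[1], xb.shape[1]):
        raise ValueError(f"A shape {A.shape} inconsistent with features {xb.shape}")
    return float(graph_loss_t(ad.tensor(xb), ad.tensor(Ab), tau).value)


# ----------------------------------------------------------------------
def knn_adjacency(x, k: int, mode: str = "binary") -> np.ndarray:
    """Fixed k-nearest-neighbour graph (the non-adaptive ablation).

    Each node connects to its ``k`` nearest Euclidean neighbours (ties
    broken by lowest index; no self-loops); the edge set is symmetrised
    by union; rows are normalised to sum to 1 for drop-in use in place of
    the adaptive adjacency.  ``mode='distance'`` weights edges by a
    Gaussian kernel of the distance before normalising.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 2:
        raise ValueError(f"node features must be N x F_de, got {x.shape}")
    N = x.shape[0]
    if not 1 <= k < N:
        raise ValueError(f"k must satisfy 1 <= k < N={N}, got {k}")
    if mode not in ("binary", "distance"):
        raise ValueError(f"mode must be 'binary' or 'distance', got {mode!r}")

    d2 = ((x[:, None, :] - x[None, :, :]) ** 2).sum(-1)
    mask = np.zeros((N, N), dtype=bool)
    for m in range(N):
        order = [n for n in np.argsort(d2[m], kind="stable") if n != m]
        mask[m, order[:k]] = True
    mask |= mask.T  # union symmetrisation

    if mode == "binary":
        A = mask.astype(np.float64)
    else:
        sel = d2[mask]
        sigma2 = sel.mean() if sel.size and sel.mean() > 0 else 1.0
        A = np.where(mask, np.exp(-d2 / sigma2), 0.0)
    return A / A.sum(axis=1, keepdims=True)


def distance_initial_adjacency(channel_positions, theta: float | None = None) -> np.ndarray:
    """Gaussian-of-distance initial graph from 3-D electrode positions.

    ``A[m,n] ∝ exp(-dist(m,n)^2 / theta^2)``, row-normalised (self-loop
    included with unit kernel weight).  ``theta`` defaults to the mean
    pairwise distance; used only as an optional warm start.
    """
    pos = np.asarray(channel_positions, dtype=np.float64)
    if pos.ndim != 2:
        raise ValueError(f"positions must be N x 3, got {pos.shape}")
    if not np.all(np.isfinite(pos)):
        raise ValueError("positions contain non-finite values")
    d2 = ((pos[:, None, :] - pos[None, :, :]) ** 2).sum(-1)
    if theta is None:
        d = np.sqrt(d2)
        off = d[~np.eye(len(pos), dtype=bool)]
        theta = off.mean() if off.size and off.mean() > 0 else 1.0
    if not np.isfinite(theta) or theta <= 0:
        A = np.ones_like(d2)
    else:
        A = np.exp(-d2 / theta ** 2)
    return A / A.sum(axis=1, keepdims=True)
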