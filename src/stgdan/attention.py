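"""Temporal and spatial attention over a DE-feature window.

A window ``X`` has shape ``T x N x F_de`` (time segments x channels x
bands).  Temporal attention produces a row-stochastic ``T x T`` mixing
matrix ``Q'``; spatial attention produces a row-stochastic ``N x N``
channel-affinity matrix ``P'`` that later masks the graph convolution.

Shape bookkeeping for the bilinear scores (the learnable maps contract
the stated axes; see docs/methods.md for the full shape-trace table):

    temporal:  (X' U1) U2        -> T x N      with X' = T x F x N
               U3 X''            -> N x T      with X'' = N x F x T
               scores = (T x N)(N x T) -> T x T
    spatial:   (X'' W1) W2       -> N x T
               W3 X'             -> T x N
               scores = (N x T)(T x N) -> N x N

Both score matrices pass through a logistic sigmoid, are mixed by the
learnable ``V`` matrix with an additive bias, and are row-softmaxed.

The public functions accept plain numpy arrays (or autodiff Tensors) and
return the same kind; the model reuses the identical tensor code path, so
what the unit tests check is literally what the trained network computes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = [
    "TemporalAttentionParams",
    "SpatialAttentionParams",
    "AttentionOutput",
    "temporal_attention",
    "apply_temporal_attention",
    "spatial_attention",
]


@dataclass
class TemporalAttentionParams:
    """Learnable tensors of the temporal attention score."""

    V_e: np.ndarray  # T x T
    b_e: np.ndarray  # T x T
    U1: np.ndarray   # N
    U2: np.ndarray   # F_de x N
    U3: np.ndarray   # F_de

    @classmethod
    def init(cls, T: int, N: int, F_de: int, rng: np.random.Generator) -> "TemporalAttentionParams":
        """Identity-scaled ``V_e``; fan-in-scaled uniform for the rest.

        At initialisation the attention is near-uniform: a neutral prior.
        """
        return cls(
            V_e=np.eye(T),
            b_e=rng.uniform(-1, 1, (T, T)) / np.sqrt(T),
            U1=rng.uniform(-1, 1, N) / np.sqrt(N),
            U2=rng.uniform(-1, 1, (F_de, N)) / np.sqrt(F_de),
            U3=rng.uniform(-1, 1, F_de) / np.sqrt(F_de),
        )

    def validate(self, T: int, N: int, F_de: int) -> None:
        expect = {"V_e": (T, T), "b_e": (T, T), "U1": (N,), "U2": (F_de, N), "U3": (F_de,)}
        for name, shape in expect.items():
            arr = np.asarray(getattr(self, name))
            if arr.shape != shape:
                raise ValueError(f"temporal attention param {name}: expected {shape}, got {arr.shape}")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"temporal attention param {name} contains non-finite values")


@dataclass
class SpatialAttentionParams:
    """Learnable tensors of the spatial attention score."""

    V_s: np.ndarray  # N x N
    b_s: np.ndarray  # N x N
    W1: np.ndarray   # T
    W2: np.ndarray   # F_de x T
    W3: np.ndarray   # F_de

    @classmethod
    def init(cls, T: int, N: int, F_de: int, rng: np.random.Generator) -> "SpatialAttentionParams":
        return cls(
            V_s=np.eye(N),
            b_s=rng.uniform(-1, 1, (N, N)) / np.sqrt(N),
            W1=rng.uniform(-1, 1, T) / np.sqrt(T),
            W2=rng.uniform(-1, 1, (F_de, T)) / np.sqrt(F_de),
            W3=rng.uniform(-1, 1, F_de) / np.sqrt(F_de),
        )

    def validate(self, T: int, N: int, F_de: int) -> None:
        expect = {"V_s": (N, N), "b_s": (N, N), "W1": (T,), "W2": (F_de, T), "W3": (F_de,)}
        for name, shape in expect.items():
            arr = np.asarray(getattr(self, name))
            if arr.shape != shape:
                raise ValueError(f"spatial attention param {name}: expected {shape}, got {arr.shape}")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"spatial attention param {name} contains non-finite values")


@dataclass
class AttentionOutput:
    """Row-stochastic attention matrices and the temporally re-mixed window."""

    Q_norm: np.ndarray  # T x T
    P_norm: np.ndarray  # N x N
    X_hat: np.ndarray   # T x N x F_de


# ----------------------------------------------------------------------
# core tensor implementations (batched: X has shape B x T x N x F_de)

def temporal_scores(X: Tensor, V_e, b_e, U1, U2, U3) -> Tensor:
    """Row-softmaxed temporal attention ``Q'`` for a batch of windows."""
    left = ad.einsum("btf,fn->btn", ad.einsum("btnf,n->btf", X, U1), U2)   # B,T,N
    right = ad.einsum("btnf,f->bnt", X, U3)                                # B,N,T
    scores = ad.einsum("btn,bns->bts", left, right)                        # B,T,T
    Q = ad.einsum("ts,bsr->btr", ad.tensor(V_e), ad.sigmoid(ad.add(scores, b_e)))
    return ad.softmax(Q, axis=-1)


def apply_temporal(X: Tensor, Q_norm: Tensor) -> Tensor:
    """Mix time slices: ``X_hat[t] = sum_s X[s] * Q'[s, t]``."""
    return ad.einsum("bsnf,bst->btnf", X, Q_norm)


def spatial_scores(X_hat: Tensor, V_s, b_s, W1, W2, W3) -> Tensor:
    """Row-softmaxed spatial attention ``P'`` for a batch of windows."""
    left = ad.einsum("bnf,ft->bnt", ad.einsum("btnf,t->bnf", X_hat, W1), W2)  # B,N,T
    right = ad.einsum("btnf,f->btn", X_hat, W3)                                # B,T,N
    scores = ad.einsum("bnt,btm->bnm", left, right)                            # B,N,N
    P = ad.einsum("nm,bmr->bnr", ad.tensor(V_s), ad.sigmoid(ad.add(scores, b_s)))
    return ad.softmax(P, axis=-1)


# ----------------------------------------------------------------------
def _as_batch(X) -> tuple[Tensor, bool]:
    t = ad.tensor(X)
    if t.ndim == 3:
        return ad.reshape(t, (1,) + t.shape), True
    if t.ndim == 4:
        return t, False
    raise ValueError(f"window must be T x N x F_de (optionally batched), got {t.shape}")


def _check_finite(X) -> None:
    val = X.value if isinstance(X, Tensor) else np.asarray(X)
    if not np.all(np.isfinite(val)):
        raise ValueError("attention input contains non-finite values")


def temporal_attention(X, params: TemporalAttentionParams) -> np.ndarray:
    """Temporal attention matrix ``Q'`` (``T x T``, rows sum to 1)."""
    _check_finite(X)
    Xb, squeezed = _as_batch(X)
    T, N, F = Xb.shape[1:]
    params.validate(T, N, F)
    Q = temporal_scores(Xb, params.V_e, params.b_e, params.U1, params.U2, params.U3)
    out = Q.value
    return out[0] if squeezed else out


def apply_temporal_attention(X, Q_norm) -> np.ndarray:
    """Re-mix the window's time slices by a row-stochastic ``Q'``."""
    Xb, squeezed = _as_batch(X)
    Q = ad.tensor(Q_norm)
    if Q.ndim == 2:
        Q = ad.reshape(Q, (1,) + Q.shape)
    if Q.shape[-2:] != (Xb.shape[1], Xb.shape[1]):
        raise ValueError(
            f"Q_norm shape {Q.shape[-2:]} does not match window length T={Xb.shape[1]}"
        )
    out = apply_temporal(Xb, Q).value
    return out[0] if squeezed else out


def spatial_attention(X_hat, params: SpatialAttentionParams) -> np.ndarray:
    """Spatial attention matrix ``P'`` (``N x N``, rows sum to 1)."""
    _check_finite(X_hat)
    Xb, squeezed = _as_batch(X_hat)
    T, N, F = Xb.shape[1:]
    params.validate(T, N, F)
    P = spatial_scores(Xb, params.V_s, params.b_s, params.W1, params.W2, params.W3)
    out = P.value
    return out[0] if squeezed else out
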