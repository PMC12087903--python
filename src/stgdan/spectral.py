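"""Scaled Laplacian, Chebyshev basis, attention-modulated graph
convolution, and the temporal convolution stage.

Given a symmetric adjacency ``A_sym`` the combinatorial Laplacian is
``L = D - A_sym`` and the scaled Laplacian ``L~ = (2/lambda_max) L - I``
maps the spectrum into ``[-1, 1]`` so the Chebyshev recursion

    xi_0 = I,  xi_1 = L~,  xi_k = 2 L~ xi_{k-1} - xi_{k-2}

is a stable polynomial filter basis (order bound ``K`` aggregates
information up to ``K-1`` hops).  The spatial graph convolution applies,
per time step,

    X_sgc[t] = sum_k ( xi_k ⊙ P' ) X_hat[t] theta_k

where ``P'`` is the spatial attention acting as an edge mask (Hadamard
product) and ``theta_k`` maps the band axis ``F_de -> F_out``.  The
temporal convolution then mixes along time only:

    X_tgc = ReLU( Phi * ReLU(X_sgc) )

with an odd kernel length and zero padding (time length preserved), and
``collapse_time`` mean-pools over time and flattens node-major to the
``N * F_out`` feature vector the extractor consumes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = [
    "SpectralConvParams",
    "ScaledLaplacian",
    "TemporalConvParams",
    "scaled_laplacian",
    "cheb_basis",
    "spatial_graph_conv",
    "temporal_conv",
    "collapse_time",
]

_LAMBDA_FLOOR = 1e-9
_LAMBDA_FALLBACK = 2.0


@dataclass
class SpectralConvParams:
    """Chebyshev order bound ``K`` and coefficients ``theta`` (K x F_de x F_out)."""

    K: int
    theta: np.ndarray
    F_out: int

    @classmethod
    def init(cls, K: int, F_de: int, F_out: int, rng: np.random.Generator) -> "SpectralConvParams":
        if K < 1:
            raise ValueError(f"Chebyshev order bound K must be >= 1, got {K}")
        scale = 1.0 / np.sqrt(F_de * K)
        return cls(K=K, theta=rng.uniform(-scale, scale, (K, F_de, F_out)), F_out=F_out)


@dataclass
class ScaledLaplacian:
    """``L~`` with spectrum in ``[-1, 1]`` and the ``lambda_max`` used."""

    L_tilde: np.ndarray
    lambda_max: float


@dataclass
class TemporalConvParams:
    """Time-axis kernel ``Phi``: k_t taps, each an F_out x F_out map, plus bias."""

    Phi: np.ndarray          # k_t x F_out x F_out
    bias: np.ndarray | None = None

    def __post_init__(self):
        self.Phi = np.asarray(self.Phi, dtype=np.float64)
        if self.Phi.ndim != 3:
            raise ValueError(f"Phi must be k_t x F_out x F_out, got {self.Phi.shape}")
        if self.Phi.shape[0] % 2 != 1:
            raise ValueError(f"temporal kernel length must be odd, got {self.Phi.shape[0]}")
        if self.bias is None:
            self.bias = np.zeros(self.Phi.shape[-1])

    @classmethod
    def init(cls, k_t: int, F_out: int, rng: np.random.Generator) -> "TemporalConvParams":
        scale = 1.0 / np.sqrt(k_t * F_out)
        return cls(Phi=rng.uniform(-scale, scale, (k_t, F_out, F_out)))


# ----------------------------------------------------------------------
# core tensor implementations (batched where noted)

def scaled_laplacian_t(A_sym: Tensor) -> tuple[Tensor, np.ndarray]:
    """Batched scaled Laplacian; ``lambda_max`` is a stop-gradient constant."""
    B, N, _ = A_sym.shape
    eye = np.eye(N)
    rowsum = ad.tensor_sum(A_sym, axis=-1, keepdims=True)   # B,N,1
    L = ad.mul(rowsum, eye) - A_sym                          # diag(rowsum) - A
    lam = np.linalg.eigvalsh(L.value)[..., -1]
    lam = np.where(lam < _LAMBDA_FLOOR, _LAMBDA_FALLBACK, lam)
    scale = (2.0 / lam)[:, None, None]
    return ad.mul(L, scale) - ad.tensor(np.broadcast_to(eye, (B, N, N))), lam


def cheb_basis_t(L_tilde: Tensor, K: int) -> list[Tensor]:
    B, N, _ = L_tilde.shape
    basis = [ad.tensor(np.broadcast_to(np.eye(N), (B, N, N)).copy())]
    if K >= 2:
        basis.append(L_tilde)
    for _ in range(2, K):
        basis.append(2.0 * ad.matmul(L_tilde, basis[-1]) - basis[-2])
    return basis


def spatial_graph_conv_t(X_hat: Tensor, P_norm: Tensor, basis: list[Tensor],
                         theta: Tensor) -> Tensor:
    """``sum_k (xi_k ⊙ P') X_hat[t] theta_k`` for every time step (batched)."""
    out = None
    for k, xi in enumerate(basis):
        masked = ad.mul(xi, P_norm)
        term = ad.einsum("bmn,btnf->btmf", masked, X_hat)
        term = ad.einsum("btmf,fo->btmo", term, theta[k])
        out = term if out is None else out + term
    return out


def temporal_conv_t(X_sgc: Tensor, Phi: Tensor, bias: Tensor) -> Tensor:
    """``ReLU(Phi * ReLU(X_sgc))`` along the time axis, zero-padded (batched)."""
    k_t = Phi.shape[0]
    half = k_t // 2
    T = X_sgc.shape[1]
    y = ad.relu(X_sgc)
    padded = ad.pad(y, [(0, 0), (half, half), (0, 0), (0, 0)])
    out = None
    for j in range(k_t):
        term = ad.einsum("btnc,cd->btnd", padded[:, j:j + T], Phi[j])
        out = term if out is None else out + term
    return ad.relu(out + bias)


def collapse_time_t(X_tgc: Tensor) -> Tensor:
    """Mean over time, flattened node-major to length ``N * F_out`` (batched)."""
    B, T, N, F = X_tgc.shape
    return ad.reshape(ad.mean(X_tgc, axis=1), (B, N * F))


# ----------------------------------------------------------------------
def scaled_laplacian(A_sym) -> ScaledLaplacian:
    """Scaled Laplacian of a symmetric non-negative adjacency.

    Falls back to ``lambda_max = 2`` with a warning for an edgeless graph
    (so ``L~ = -I`` for the zero matrix).
    """
    A = np.asarray(A_sym, dtype=np.float64)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError(f"adjacency must be square, got {A.shape}")
    if not np.allclose(A, A.T, atol=1e-8):
        raise ValueError("adjacency must be symmetric (symmetrise before the Laplacian)")
    if np.any(A < -1e-12):
        raise ValueError("adjacency must be non-negative")
    L = np.diag(A.sum(axis=1)) - A
    lam = float(np.linalg.eigvalsh(L)[-1])
    if lam < _LAMBDA_FLOOR:
        warnings.warn(
            f"edgeless graph: lambda_max={lam:.3g} < {_LAMBDA_FLOOR}; "
            f"falling back to lambda_max={_LAMBDA_FALLBACK}", stacklevel=2
        )
        lam = _LAMBDA_FALLBACK
    return ScaledLaplacian(L_tilde=(2.0 / lam) * L - np.eye(len(A)), lambda_max=lam)


def cheb_basis(L_tilde, K: int) -> list[np.ndarray]:
    """``[xi_0, ..., xi_{K-1}]`` of the Chebyshev recursion in ``L~``."""
    if K < 1:
        raise ValueError(f"K must be >= 1, got {K}")
    Lt = np.asarray(L_tilde, dtype=np.float64)
    out = cheb_basis_t(ad.tensor(Lt[None]), K)
    return [m.value[0] for m in out]


def spatial_graph_conv(X_hat, P_norm, basis, theta) -> np.ndarray:
    """Attention-masked Chebyshev spatial convolution of one window.

    ``X_hat``: T x N x F_de; ``P_norm``: N x N; ``basis``: list of K
    N x N matrices; ``theta``: K x F_de x F_out.  Returns T x N x F_out.
    """
    X = np.asarray(X_hat, dtype=np.float64)
    if X.ndim != 3:
        raise ValueError(f"X_hat must be T x N x F_de, got {X.shape}")
    theta = np.asarray(theta, dtype=np.float64)
    if theta.ndim != 3 or theta.shape[0] != len(basis):
        raise ValueError(
            f"theta must be K x F_de x F_out with K={len(basis)}, got {theta.shape}"
        )
    if theta.shape[1] != X.shape[2]:
        raise ValueError(f"theta band axis {theta.shape[1]} != F_de {X.shape[2]}")
    P = np.asarray(P_norm, dtype=np.float64)
    if P.shape != (X.shape[1], X.shape[1]):
        raise ValueError(f"P_norm must be N x N = {(X.shape[1], X.shape[1])}, got {P.shape}")
    basis_t = [ad.tensor(np.asarray(b)[None]) for b in basis]
    out = spatial_graph_conv_t(ad.tensor(X[None]), ad.tensor(P[None]),
                               basis_t, ad.tensor(theta))
    return out.value[0]


def temporal_conv(X_sgc, params: TemporalConvParams) -> np.ndarray:
    """Temporal convolution of one window (T preserved by zero padding)."""
    X = np.asarray(X_sgc, dtype=np.float64)
    if X.ndim != 3:
        raise ValueError(f"X_sgc must be T x N x F_out, got {X.shape}")
    out = temporal_conv_t(ad.tensor(X[None]), ad.tensor(params.Phi), ad.tensor(params.bias))
    return out.value[0]


def collapse_time(X_tgc) -> np.ndarray:
    """Mean over time then node-major flatten to a length ``N*F_out`` vector."""
    X = np.asarray(X_tgc, dtype=np.float64)
    if X.ndim != 3:
        raise ValueError(f"X_tgc must be T x N x F_out, got {X.shape}")
    return collapse_time_t(ad.tensor(X[None])).value[0]
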