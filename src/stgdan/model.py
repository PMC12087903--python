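"""Assembly of the full adaptive spatial-temporal graph network.

Pipeline for a batch of windows ``X`` (B x T x N x F_de):

    temporal attention Q'  ->  X_hat = mix(X, Q')
    spatial attention P'   (one matrix per window, shared over its T steps)
    adaptive adjacency A   from the time-averaged window features
                           (or a fixed KNN graph under ablation)
    A_sym = (A + A^T)/2    ->  scaled Laplacian  ->  Chebyshev basis
    attention-masked spatial graph conv  ->  temporal conv  ->  time mean
    feature extractor f(.) (N*F_out -> 64 -> 64 -> 64)
    -> classifier head (64 -> C)
    -> gradient reversal -> discriminator (64 -> 64 -> 64 -> 2, softmax)

Ablation flags replace a stage by its neutral element: identity temporal
mixing, an all-ones spatial mask, a fixed KNN graph (graph loss dropped),
or no discriminator branch.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .adversarial import MLP, LambdaSchedule
from .attention import apply_temporal, spatial_scores, temporal_scores
from .graph import adjacency_t, graph_loss_t, knn_adjacency
from .spectral import (
    cheb_basis_t,
    collapse_time_t,
    scaled_laplacian_t,
    spatial_graph_conv_t,
    temporal_conv_t,
)

__all__ = ["ModelConfig", "EmotionGraphModel", "ABLATIONS"]

ABLATIONS = frozenset(
    {"no_discriminator", "knn_graph", "no_temporal_attention", "no_spatial_attention"}
)


@dataclass
class ModelConfig:
    """Hyperparameters of the model and its training.

    Defaults are the reference operating point: context coefficient
    ``d=3`` (window length ``T=7``), Chebyshev bound ``K=2``, spatial-conv
    output width ``F_out=5``, graph regularisation weight ``tau=1e-2``,
    RMSprop with learning rate 1e-3, batch size 96.
    """

    d: int = 3
    K: int = 2
    F_out: int = 5
    tau: float = 1e-2
    lr: float = 1e-3
    batch_size: int = 96
    max_epochs: int = 200
    seed: int = 0
    lambda_schedule: LambdaSchedule = field(default_factory=LambdaSchedule)
    ablation: frozenset = frozenset()
    hidden: int = 64
    temporal_kernel: int = 3
    knn_k: int = 2
    source_trials: int | None = None   # protocol parameter m (None: dataset default)
    early_stop_train_acc: float | None = None
    log_every: int = 1

    def __post_init__(self):
        if self.d < 0:
            raise ValueError(f"d must be >= 0, got {self.d}")
        if self.K < 1:
            raise ValueError(f"K must be >= 1, got {self.K}")
        if self.tau < 0:
            raise ValueError(f"tau must be >= 0, got {self.tau}")
        self.ablation = frozenset(self.ablation)
        unknown = self.ablation - ABLATIONS
        if unknown:
            raise ValueError(f"unknown ablation flags: {sorted(unknown)}")

    @property
    def T(self) -> int:
        return 2 * self.d + 1

    def with_(self, **kw) -> "ModelConfig":
        return replace(self, **kw)

    def to_dict(self) -> dict:
        return {
            "d": self.d, "K": self.K, "F_out": self.F_out, "tau": self.tau,
            "lr": self.lr, "batch_size": self.batch_size,
            "max_epochs": self.max_epochs, "seed": self.seed,
            "lambda_schedule": {"variant": self.lambda_schedule.variant,
                                "gamma": self.lambda_schedule.gamma},
            "ablation": sorted(self.ablation), "hidden": self.hidden,
            "temporal_kernel": self.temporal_kernel, "knn_k": self.knn_k,
            "source_trials": self.source_trials,
            "early_stop_train_acc": self.early_stop_train_acc,
        }


class EmotionGraphModel:
    """The full network, parameterised for ``N`` channels, ``F_de`` bands
    and ``C`` emotion classes."""

    def __init__(self, config: ModelConfig, n_channels: int, n_bands: int,
                 n_classes: int, rng: np.random.Generator | None = None):
        self.config = config
        self.N = int(n_channels)
        self.F_de = int(n_bands)
        self.C = int(n_classes)
        rng = rng or np.random.default_rng(config.seed)
        T, N, F = config.T, self.N, self.F_de

        # temporal attention parameters
        self.V_e = ad.parameter(np.eye(T))
        self.b_e = ad.parameter(rng.uniform(-1, 1, (T, T)) / np.sqrt(T))
        self.U1 = ad.parameter(rng.uniform(-1, 1, N) / np.sqrt(N))
        self.U2 = ad.parameter(rng.uniform(-1, 1, (F, N)) / np.sqrt(F))
        self.U3 = ad.parameter(rng.uniform(-1, 1, F) / np.sqrt(F))
        # spatial attention parameters
        self.V_s = ad.parameter(np.eye(N))
        self.b_s = ad.parameter(rng.uniform(-1, 1, (N, N)) / np.sqrt(N))
        self.W1 = ad.parameter(rng.uniform(-1, 1, T) / np.sqrt(T))
        self.W2 = ad.parameter(rng.uniform(-1, 1, (F, T)) / np.sqrt(F))
        self.W3 = ad.parameter(rng.uniform(-1, 1, F) / np.sqrt(F))
        # adaptive graph weight vector (non-negative start: dissimilarity weights)
        self.w = ad.parameter(rng.uniform(0.0, 0.1, F))
        # Chebyshev coefficients and temporal kernel
        scale = 1.0 / np.sqrt(F * config.K)
        self.theta = ad.parameter(rng.uniform(-scale, scale, (config.K, F, config.F_out)))
        kt = config.temporal_kernel
        tscale = 1.0 / np.sqrt(kt * config.F_out)
        self.Phi = ad.parameter(rng.uniform(-tscale, tscale, (kt, config.F_out, config.F_out)))
        self.Phi_bias = ad.parameter(np.zeros(config.F_out))
        # heads
        in_width = N * config.F_out
        h = config.hidden
        self.extractor = MLP([in_width, h, h, h], rng, relu_out=True)
        self.classifier = MLP([h, self.C], rng)
        self.discriminator = MLP([h, h, h, 2], rng, softmax_out=True)

    # ------------------------------------------------------------------
    def parameters(self, include_discriminator: bool = True) -> list[Tensor]:
        params = [
            self.V_e, self.b_e, self.U1, self.U2, self.U3,
            self.V_s, self.b_s, self.W1, self.W2, self.W3,
            self.w, self.theta, self.Phi, self.Phi_bias,
        ]
        params += self.extractor.parameters() + self.classifier.parameters()
        if include_discriminator and "no_discriminator" not in self.config.ablation:
            params += self.discriminator.parameters()
        return params

    # ------------------------------------------------------------------
    def forward(self, windows: np.ndarray, lam: float = 0.0) -> dict:
        """Run a batch of windows through the network.

        Parameters
        ----------
        windows : array B x T x N x F_de (or a Tensor of that shape).
        lam : gradient-reversal strength for the discriminator branch.

        Returns a dict of Tensors: ``logits`` (B x C), ``features``
        (B x hidden), ``domain_probs`` (B x 2 or None under the
        no-discriminator ablation), ``A`` (B x N x N), ``L_gcn`` (scalar),
        plus ``Q`` and ``P`` for inspection.
        """
        cfg = self.config
        X = windows if isinstance(windows, Tensor) else ad.tensor(np.asarray(windows, dtype=np.float64))
        if X.ndim != 4:
            raise ValueError(f"stage input: expected B x T x N x F_de, got {X.shape}")
        B, T, N, F = X.shape
        if T != cfg.T or N != self.N or F != self.F_de:
            raise ValueError(
                f"stage input: window shape T={T},N={N},F={F} does not match "
                f"model T={cfg.T},N={self.N},F={self.F_de}"
            )

        # --- temporal attention
        if "no_temporal_attention" in cfg.ablation:
            Q = ad.tensor(np.broadcast_to(np.eye(T), (B, T, T)).copy())
            X_hat = X
        else:
            Q = temporal_scores(X, self.V_e, self.b_e, self.U1, self.U2, self.U3)
            X_hat = apply_temporal(X, Q)

        # --- spatial attention (edge mask for the graph convolution)
        if "no_spatial_attention" in cfg.ablation:
            P = ad.tensor(np.ones((B, N, N)))
        else:
            P = spatial_scores(X_hat, self.V_s, self.b_s, self.W1, self.W2, self.W3)

        # --- adjacency from time-averaged window features
        xbar = ad.mean(X_hat, axis=1)  # B x N x F
        if "knn_graph" in cfg.ablation:
            A_val = np.stack([knn_adjacency(xb, k=cfg.knn_k) for xb in xbar.value])
            A = ad.tensor(A_val)
            L_gcn = ad.tensor(0.0)
        else:
            A = adjacency_t(xbar, self.w)
            L_gcn = graph_loss_t(xbar, A, cfg.tau)

        # --- spectral convolution on the symmetrised graph
        A_sym = ad.mul(A + ad.transpose(A, (0, 2, 1)), 0.5)
        L_tilde, _ = scaled_laplacian_t(A_sym)
        basis = cheb_basis_t(L_tilde, cfg.K)
        X_sgc = spatial_graph_conv_t(X_hat, P, basis, self.theta)
        X_tgc = temporal_conv_t(X_sgc, self.Phi, self.Phi_bias)
        flat = collapse_time_t(X_tgc)

        # --- heads
        features = self.extractor(flat)
        logits = self.classifier(features)
        if "no_discriminator" in cfg.ablation:
            domain_probs = None
        else:
            domain_probs = self.discriminator(ad.grad_reverse(features, lam))

        return {
            "logits": logits,
            "features": features,
            "domain_probs": domain_probs,
            "A": A,
            "L_gcn": L_gcn,
            "Q": Q,
            "P": P,
        }

    # ------------------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        """All parameter arrays, keyed by stable names (for persistence)."""
        state = {}
        for name in ("V_e", "b_e", "U1", "U2", "U3", "V_s", "b_s", "W1", "W2",
                     "W3", "w", "theta", "Phi", "Phi_bias"):
            state[name] = getattr(self, name).value.copy()
        for prefix, mlp in (("extractor", self.extractor),
                            ("classifier", self.classifier),
                            ("discriminator", self.discriminator)):
            for i, (W, b) in enumerate(zip(mlp.weights, mlp.biases)):
                state[f"{prefix}.W{i}"] = W.value.copy()
                state[f"{prefix}.b{i}"] = b.value.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name in ("V_e", "b_e", "U1", "U2", "U3", "V_s", "b_s", "W1", "W2",
                     "W3", "w", "theta", "Phi", "Phi_bias"):
            getattr(self, name).value = np.array(state[name], dtype=np.float64)
        for prefix, mlp in (("extractor", self.extractor),
                            ("classifier", self.classifier),
                            ("discriminator", self.discriminator)):
            for i, (W, b) in enumerate(zip(mlp.weights, mlp.biases)):
                W.value = np.array(state[f"{prefix}.W{i}"], dtype=np.float64)
                b.value = np.array(state[f"{prefix}.b{i}"], dtype=np.float64)
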