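"""Domain-adversarial alignment: discriminator loss, gradient reversal,
the joint objective, and the adversarial balance schedule.

A domain discriminator ``d(.)`` is trained to tell source-subject from
target-subject feature vectors while a gradient-reversal layer (GRL)
feeds its gradient back to the feature extractor with the sign flipped
and scaled by ``lambda``; the extractor is thereby pushed to make the
two domains indistinguishable.  The realised min-max objective is

    extractor/classifier minimise  L_classifier + L_gcn - lambda * L_disc
    discriminator         minimises L_disc

``lambda`` follows an epoch-dependent schedule.  The default variant is
the decreasing form ``lambda(p) = 2/(1 - exp(-p)) - 1`` (``p`` = current
epoch / max epochs; large early to drive alignment first, decaying
towards 1), with the standard increasing DANN ramp
``2/(1 + exp(-gamma p)) - 1`` available as an alternative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = [
    "LambdaSchedule",
    "lambda_schedule",
    "discriminator_loss",
    "gradient_reversal",
    "total_loss",
    "MLP",
]

_PROB_EPS = 1e-7


@dataclass
class LambdaSchedule:
    """Adversarial balance schedule.

    variant 'paper_decreasing': lambda = 2/(1 - exp(-p)) - 1, p in (0, 1]
        (pole at p = 0: start counting epochs at 1).
    variant 'dann_increasing':  lambda = 2/(1 + exp(-gamma p)) - 1, p >= 0.
    """

    variant: str = "paper_decreasing"
    gamma: float = 10.0

    def __post_init__(self):
        if self.variant not in ("paper_decreasing", "dann_increasing"):
            raise ValueError(f"unknown lambda schedule variant {self.variant!r}")
        if self.gamma <= 0:
            raise ValueError(f"gamma must be > 0, got {self.gamma}")

    def __call__(self, p: float) -> float:
        return lambda_schedule(p, self)


def lambda_schedule(p: float, schedule: LambdaSchedule | None = None) -> float:
    """Evaluate the adversarial weight at training progress ``p``."""
    schedule = schedule or LambdaSchedule()
    if schedule.variant == "paper_decreasing":
        if p <= 0:
            raise ValueError(
                f"paper_decreasing schedule has a pole at p=0 (got p={p}); "
                "training progress must start at epoch 1"
            )
        return 2.0 / (1.0 - math.exp(-p)) - 1.0
    if p < 0:
        raise ValueError(f"p must be >= 0, got {p}")
    return 2.0 / (1.0 + math.exp(-schedule.gamma * p)) - 1.0


# ----------------------------------------------------------------------
def discriminator_loss(d_source, d_target, reduction: str = "sum") -> float:
    """Binary adversarial loss of discriminator outputs.

    ``d_source``/``d_target`` are lists/arrays of 2-simplex outputs;
    component 0 is the probability assigned to "source".  The loss is

        - sum_s log d_s[0] - sum_t log(1 - d_t[0])

    with probabilities clamped at 1e-7.  ``reduction='mean'`` averages
    each sum over its own batch (the batch-size-independent form used by
    the training loop).
    """
    ps = np.atleast_2d(np.asarray(d_source, dtype=np.float64))
    pt = np.atleast_2d(np.asarray(d_target, dtype=np.float64))
    if ps.size == 0 or pt.size == 0:
        raise ValueError("discriminator loss requires non-empty source and target batches")
    if reduction not in ("sum", "mean"):
        raise ValueError(f"reduction must be 'sum' or 'mean', got {reduction!r}")
    s = np.clip(ps[:, 0], _PROB_EPS, 1.0 - _PROB_EPS)
    t = np.clip(pt[:, 0], _PROB_EPS, 1.0 - _PROB_EPS)
    src_term, tgt_term = -np.log(s), -np.log(1.0 - t)
    if reduction == "mean":
        return float(src_term.mean() + tgt_term.mean())
    return float(src_term.sum() + tgt_term.sum())


def disc_loss_t(probs_source: Tensor, probs_target: Tensor) -> Tensor:
    """Differentiable per-domain-mean discriminator loss (training form)."""
    s = ad.clamp(probs_source[:, 0], _PROB_EPS, 1.0 - _PROB_EPS)
    t = ad.clamp(probs_target[:, 0], _PROB_EPS, 1.0 - _PROB_EPS)
    return -ad.mean(ad.log(s)) - ad.mean(ad.log(1.0 - t))


def gradient_reversal(x, lam: float = 1.0):
    """Identity forward; gradient multiplied by ``-lam`` in the backward pass.

    Accepts a plain array (returns a copy; the contract is only visible
    through autodiff) or a :class:`~stgdan.autodiff.Tensor`.
    """
    if isinstance(x, Tensor):
        return ad.grad_reverse(x, lam)
    return np.array(x, dtype=np.float64, copy=True)


def total_loss(L_classifier, L_gcn, L_disc, lam: float):
    """Extractor-side scalar of the min-max objective:
    ``L_classifier + L_gcn - lam * L_disc``."""
    return L_classifier + L_gcn - lam * L_disc


# ----------------------------------------------------------------------
class MLP:
    """Fully connected stack with ReLU between layers.

    ``softmax_out`` appends a softmax (discriminator head); otherwise the
    final layer returns raw logits/features.  ``relu_out`` applies ReLU
    after the last layer (feature extractor).
    """

    def __init__(self, widths: list[int], rng: np.random.Generator,
                 softmax_out: bool = False, relu_out: bool = False):
        self.widths = list(widths)
        self.softmax_out = softmax_out
        self.relu_out = relu_out
        self.weights: list[Tensor] = []
        self.biases: list[Tensor] = []
        for fan_in, fan_out in zip(widths[:-1], widths[1:]):
            scale = np.sqrt(2.0 / fan_in)
            self.weights.append(ad.parameter(rng.normal(0.0, scale, (fan_in, fan_out))))
            self.biases.append(ad.parameter(np.zeros(fan_out)))

    def parameters(self) -> list[Tensor]:
        return self.weights + self.biases

    def __call__(self, x: Tensor) -> Tensor:
        h = x
        last = len(self.weights) - 1
        for i, (W, b) in enumerate(zip(self.weights, self.biases)):
            h = ad.matmul(h, W) + b
            if i < last or self.relu_out:
                h = ad.relu(h)
        if self.softmax_out:
            h = ad.softmax(h, axis=-1)
        return h
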