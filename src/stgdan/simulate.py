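"""Synthetic multi-subject DE-feature generator.

The generator emits datasets with exactly the statistical structure the
model is built to exploit, so every stage and protocol is testable
without any download:

* trial-level class labels with class-dependent channel patterns
  (class mean patterns separated by ``class_sep``, in units of the
  unit-variance structured noise);
* temporal smoothness within a trial (AR(1) with coefficient
  ``ar_coef`` and unit stationary variance);
* graph-structured inter-channel correlation (innovations correlated
  ``block_corr`` within channel blocks, independent across blocks);
* subject-level distribution shift (per-subject affine perturbation:
  gain ~ N(1, shift^2) and offset ~ N(0, shift^2) per channel/band),
  so domain adaptation has something to align.

Feature sample at time t of a trial with class c, subject s:

    features[t] = gain_s ⊙ (mu_c + z_t) + offset_s + eps_t

with ``z`` the block-correlated AR(1) process and ``eps`` iid
N(0, noise_sd^2) measurement noise.  DE features are simulated directly
(Gaussian with structure) rather than via raw EEG synthesis: the model
consumes DE features, and this isolates the method under test.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .data import DatasetContainer, TrialFeatures

__all__ = [
    "SimConfig",
    "generate_dataset",
    "ground_truth_affinity",
    "make_fixture",
    "fixture_config",
    "FIXTURES",
]


def _default_blocks(n_channels: int) -> list[list[int]]:
    half = n_channels // 2
    return [list(range(half)), list(range(half, n_channels))]


@dataclass
class SimConfig:
    """Generator parameters; defaults give a moderately hard 3-class,
    8-channel problem without subject shift."""

    n_subjects: int = 1
    n_trials_per_subject: int = 15
    trial_length: int = 30          # L: per-second DE samples per trial
    n_channels: int = 8
    n_bands: int = 5
    n_classes: int = 3
    class_sep: float = 2.0          # distance scale of class means, in noise-SD units
    ar_coef: float = 0.5            # temporal AR(1) coefficient, in [0, 1)
    graph_blocks: list[list[int]] | None = None  # default: two equal blocks
    block_corr: float = 0.6         # within-block innovation correlation
    subject_shift: float = 0.0      # SD of per-subject gain/offset perturbations
    noise_sd: float = 0.3           # iid measurement noise SD
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.ar_coef < 1:
            raise ValueError(f"ar_coef must be in [0, 1), got {self.ar_coef}")
        for name in ("class_sep", "block_corr", "subject_shift", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.graph_blocks is None:
            self.graph_blocks = _default_blocks(self.n_channels)
        flat = sorted(ch for block in self.graph_blocks for ch in block)
        if flat != list(range(self.n_channels)):
            raise ValueError(
                f"graph_blocks must partition channels 0..{self.n_channels - 1}, "
                f"got {self.graph_blocks}"
            )

    def with_(self, **kw) -> "SimConfig":
        return replace(self, **kw)


def _block_chol(cfg: SimConfig) -> np.ndarray:
    cov = np.eye(cfg.n_channels)
    for block in cfg.graph_blocks:
        for m in block:
            for n in block:
                if m != n:
                    cov[m, n] = cfg.block_corr
    return np.linalg.cholesky(cov)


def generate_dataset(cfg: SimConfig) -> tuple[DatasetContainer, dict]:
    """Generate a dataset and its ground truth, reproducibly from the seed.

    Returns ``(container, ground_truth)`` where the ground truth carries
    the class mean patterns, the channel block partition (and its binary
    affinity matrix), and each subject's affine transform.
    """
    rng = np.random.default_rng(cfg.seed)
    N, F, C = cfg.n_channels, cfg.n_bands, cfg.n_classes
    mu = cfg.class_sep * rng.standard_normal((C, N, F))
    chol = _block_chol(cfg)
    innov_scale = np.sqrt(1.0 - cfg.ar_coef ** 2)

    trials: list[TrialFeatures] = []
    gains, offsets = {}, {}
    for s in range(cfg.n_subjects):
        sid = f"S{s:02d}"
        gain = 1.0 + cfg.subject_shift * rng.standard_normal((N, F))
        offset = cfg.subject_shift * rng.standard_normal((N, F))
        gains[sid], offsets[sid] = gain, offset
        for trial_idx in range(cfg.n_trials_per_subject):
            label = trial_idx % C  # balanced labels, trial-level
            z = chol @ rng.standard_normal((N, F))
            feats = np.empty((cfg.trial_length, N, F))
            for t in range(cfg.trial_length):
                if t > 0:
                    z = cfg.ar_coef * z + innov_scale * (chol @ rng.standard_normal((N, F)))
                eps = cfg.noise_sd * rng.standard_normal((N, F))
                feats[t] = gain * (mu[label] + z) + offset + eps
            trials.append(TrialFeatures(features=feats, label=label, subject_id=sid))

    container = DatasetContainer(
        trials, N, F, class_names=[f"class{i}" for i in range(C)]
    )
    ground_truth = {
        "class_means": mu,
        "blocks": [list(b) for b in cfg.graph_blocks],
        "affinity": ground_truth_affinity(cfg.graph_blocks, N),
        "gains": gains,
        "offsets": offsets,
        "config": cfg,
    }
    return container, ground_truth


def ground_truth_affinity(blocks: list[list[int]], n_channels: int | None = None) -> np.ndarray:
    """Binary within-block affinity matrix (zero diagonal)."""
    if n_channels is None:
        n_channels = sum(len(b) for b in blocks)
    flat = sorted(ch for block in blocks for ch in block)
    if flat != list(range(n_channels)):
        raise ValueError(f"blocks must partition channels 0..{n_channels - 1}")
    A = np.zeros((n_channels, n_channels))
    for block in blocks:
        for m in block:
            for n in block:
                if m != n:
                    A[m, n] = 1.0
    return A


# ----------------------------------------------------------------------
# named presets used throughout the test suite and the CLI

FIXTURES: dict[str, SimConfig] = {
    # one subject, clearly separable, no shift: capacity / within-subject runs
    "tiny_within": SimConfig(
        n_subjects=1, n_trials_per_subject=15, trial_length=30,
        n_channels=8, n_bands=5, n_classes=3,
        class_sep=3.0, ar_coef=0.5, block_corr=0.6,
        subject_shift=0.0, noise_sd=0.3,
    ),
    # four interchangeable subjects (no shift): null control for adaptation.
    # class separation is modest (0.6 of the total noise SD) so transfer is
    # genuinely hard: at large separations the decision boundary generalises
    # across any affine shift and adaptation has nothing left to do.
    "tiny_cross": SimConfig(
        n_subjects=4, n_trials_per_subject=6, trial_length=18,
        n_channels=8, n_bands=5, n_classes=3,
        class_sep=0.6, ar_coef=0.5, block_corr=0.6,
        subject_shift=0.0, noise_sd=1.0,
    ),
    # four subjects with a substantial affine shift: adaptation has work to do
    "shifted_cross": SimConfig(
        n_subjects=4, n_trials_per_subject=6, trial_length=18,
        n_channels=8, n_bands=5, n_classes=3,
        class_sep=0.6, ar_coef=0.5, block_corr=0.6,
        subject_shift=0.5, noise_sd=1.0,
    ),
}


def fixture_config(kind: str, seed: int = 0) -> SimConfig:
    """The :class:`SimConfig` behind a named preset."""
    if kind not in FIXTURES:
        raise ValueError(f"unknown fixture {kind!r}; choose from {sorted(FIXTURES)}")
    return FIXTURES[kind].with_(seed=seed)


def make_fixture(kind: str, seed: int = 0) -> DatasetContainer:
    """Generate a named preset dataset (see :data:`FIXTURES`)."""
    container, _ = generate_dataset(fixture_config(kind, seed))
    return container
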