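"""Training with the joint adversarial objective, evaluation, and the two
cross-validation protocols (within-subject and leave-one-subject-out).

Per epoch the loop shuffles the labelled source windows, pairs each
source batch with a (cyclically resampled) unlabelled target batch, and
takes one RMSprop step on

    L_classifier + L_gcn + L_disc(grl(features))

where the gradient-reversal layer inside the discriminator branch makes
this a single-pass realisation of the min-max objective: the
discriminator descends L_disc while everything upstream ascends it with
weight ``lambda``.  Target windows contribute only to the discriminator
loss; their labels are never used during training.

Everything is deterministic given the config seed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .adversarial import disc_loss_t, lambda_schedule, total_loss
from .data import DatasetContainer, TrialFeatures, WindowSample, make_windows
from .model import EmotionGraphModel, ModelConfig

__all__ = [
    "EvalReport",
    "train",
    "evaluate",
    "run_within_subject",
    "run_cross_subject",
    "sweep",
]


@dataclass
class EvalReport:
    """Per-fold accuracies (%) with mean/std, pooled confusion counts, and
    an echo of the configuration that produced them."""

    per_fold_accuracy: list[float]
    mean_accuracy: float
    std_accuracy: float
    confusion: list[list[int]]
    config_echo: dict
    fold_names: list[str] = field(default_factory=list)
    per_fold_majority_accuracy: list[float] | None = None

    @classmethod
    def from_folds(cls, accs: list[float], confusions: list[np.ndarray],
                   config_echo: dict, fold_names: list[str],
                   majority: list[float] | None = None) -> "EvalReport":
        total = np.sum(confusions, axis=0) if confusions else np.zeros((0, 0))
        return cls(
            per_fold_accuracy=[float(a) for a in accs],
            mean_accuracy=float(np.mean(accs)),
            std_accuracy=float(np.std(accs)),
            confusion=np.asarray(total, dtype=int).tolist(),
            config_echo=config_echo,
            fold_names=list(fold_names),
            per_fold_majority_accuracy=(None if majority is None
                                        else [float(a) for a in majority]),
        )

    def to_json(self) -> str:
        payload = {
            "per_fold_accuracy": self.per_fold_accuracy,
            "mean_accuracy": self.mean_accuracy,
            "std_accuracy": self.std_accuracy,
            "confusion": self.confusion,
            "config_echo": self.config_echo,
            "fold_names": self.fold_names,
            "per_fold_majority_accuracy": self.per_fold_majority_accuracy,
        }
        return json.dumps(payload, sort_keys=True, indent=2)


# ----------------------------------------------------------------------
def _stack(windows: list[WindowSample]) -> tuple[np.ndarray, np.ndarray]:
    X = np.stack([w.tensor for w in windows])
    y = np.array([w.label for w in windows], dtype=int)
    return X, y


def _cross_entropy(logits, labels: np.ndarray, n_classes: int):
    onehot = np.eye(n_classes)[labels]
    return -ad.mean(ad.tensor_sum(ad.mul(ad.log_softmax(logits, axis=-1), onehot), axis=-1))


def train(source: list[WindowSample], target: list[WindowSample],
          config: ModelConfig, n_classes: int | None = None,
          model: EmotionGraphModel | None = None,
          rng: np.random.Generator | None = None,
          ) -> tuple[EmotionGraphModel, list[dict]]:
    """Fit the model on labelled source windows with unlabelled target
    windows for adversarial alignment.

    Returns the fitted model and a per-epoch training log (list of dicts
    with every loss component, the adversarial weight, and the source
    training accuracy).
    """
    if not source:
        raise ValueError("source window list is empty")
    cfg = config
    use_disc = "no_discriminator" not in cfg.ablation
    if use_disc and not target:
        raise ValueError(
            "target window list is empty; pass target windows or enable the "
            "no_discriminator ablation"
        )

    Xs, ys = _stack(source)
    n_classes = n_classes or int(ys.max()) + 1
    T, N, F = Xs.shape[1:]
    if model is None:
        model = EmotionGraphModel(cfg, N, F, n_classes,
                                  rng=np.random.default_rng(cfg.seed))
    rng = rng or np.random.default_rng(cfg.seed + 1)

    Xt = np.stack([w.tensor for w in target]) if target else None
    opt = ad.RMSprop(model.parameters(), lr=cfg.lr)
    log: list[dict] = []
    n_src = len(source)
    bs = min(cfg.batch_size, n_src)

    for epoch in range(1, cfg.max_epochs + 1):
        p = epoch / cfg.max_epochs
        lam = lambda_schedule(p, cfg.lambda_schedule) if use_disc else 0.0
        perm = rng.permutation(n_src)
        if use_disc:
            tgt_order = rng.permutation(len(target))
        epoch_cls = epoch_gcn = epoch_disc = 0.0
        n_batches = 0
        correct = 0
        tpos = 0
        for start in range(0, n_src, bs):
            idx = perm[start:start + bs]
            out = model.forward(Xs[idx], lam=lam)
            L_cls = _cross_entropy(out["logits"], ys[idx], n_classes)
            loss = L_cls + out["L_gcn"]
            L_disc_val = 0.0
            if use_disc:
                take = [tgt_order[(tpos + j) % len(target)] for j in range(len(idx))]
                tpos += len(idx)
                out_t = model.forward(Xt[np.array(take)], lam=lam)
                L_disc = disc_loss_t(out["domain_probs"], out_t["domain_probs"])
                loss = loss + L_disc
                L_disc_val = float(L_disc.value)
            if not np.isfinite(loss.value):
                raise RuntimeError(
                    f"training diverged at epoch {epoch}: non-finite loss "
                    f"(cls={float(L_cls.value):.4g}, gcn={float(out['L_gcn'].value):.4g}, "
                    f"disc={L_disc_val:.4g})"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_cls += float(L_cls.value)
            epoch_gcn += float(out["L_gcn"].value)
            epoch_disc += L_disc_val
            correct += int((out["logits"].value.argmax(-1) == ys[idx]).sum())
            n_batches += 1

        cls_m, gcn_m, disc_m = (epoch_cls / n_batches, epoch_gcn / n_batches,
                                epoch_disc / n_batches)
        acc = correct / n_src
        entry = {
            "epoch": epoch,
            "L_classifier": cls_m,
            "L_gcn": gcn_m,
            "train_accuracy": acc,
        }
        if use_disc:
            entry["L_disc"] = disc_m
            entry["lambda"] = lam
            entry["total"] = total_loss(cls_m, gcn_m, disc_m, lam)
        else:
            entry["total"] = cls_m + gcn_m
        log.append(entry)
        if cfg.early_stop_train_acc is not None and acc >= cfg.early_stop_train_acc:
            break
    return model, log


# ----------------------------------------------------------------------
def evaluate(model: EmotionGraphModel, windows: list[WindowSample],
             batch_size: int = 256) -> dict:
    """Window-level argmax accuracy (ties broken by lowest class index,
    numpy argmax convention), pooled confusion counts, and — when windows
    carry a parent-trial key — trial-level majority-vote accuracy."""
    if not windows:
        raise ValueError("cannot evaluate on an empty window list")
    X, y = _stack(windows)
    preds = np.empty(len(windows), dtype=int)
    for start in range(0, len(windows), batch_size):
        out = model.forward(X[start:start + batch_size], lam=0.0)
        preds[start:start + batch_size] = out["logits"].value.argmax(-1)
    acc = float((preds == y).mean())
    C = model.C
    confusion = np.zeros((C, C), dtype=int)
    for t, p in zip(y, preds):
        confusion[t, p] += 1

    majority = None
    keys = [w.trial_key for w in windows]
    if all(k is not None for k in keys):
        votes: dict[str, list[int]] = {}
        truth: dict[str, int] = {}
        for wdw, pred in zip(windows, preds):
            votes.setdefault(wdw.trial_key, []).append(int(pred))
            truth[wdw.trial_key] = wdw.label
        hits = [int(np.bincount(v, minlength=C).argmax() == truth[k])
                for k, v in votes.items()]
        majority = float(np.mean(hits))
    return {
        "window_accuracy": acc,
        "majority_accuracy": majority,
        "confusion": confusion,
        "n_windows": len(windows),
        "predictions": preds,
    }


# ----------------------------------------------------------------------
def _subject_windows(trials: list[TrialFeatures], d: int, domain: str,
                     key_prefix: str) -> list[WindowSample]:
    out = []
    for i, t in enumerate(trials):
        out.extend(make_windows(t, d, domain=domain,
                                trial_key=f"{key_prefix}/{t.session_id}/{i}"))
    return out


def _default_m(n_trials: int) -> int:
    # dataset conventions: 9 of 15, 16 of 24; otherwise ~60% rounded
    if n_trials == 15:
        return 9
    if n_trials == 24:
        return 16
    return max(1, int(round(0.6 * n_trials)))


def run_within_subject(dataset: DatasetContainer, config: ModelConfig) -> EvalReport:
    """Within-subject protocol: per subject, the first ``m`` trials are the
    labelled source domain and the remaining trials the unlabelled target
    domain, on which accuracy is reported."""
    accs, confs, names, majority = [], [], [], []
    for si, subject in enumerate(dataset.subject_ids):
        trials = dataset.trials_for(subject)
        m = config.source_trials if config.source_trials is not None else _default_m(len(trials))
        if len(trials) < 2:
            warnings.warn(f"subject {subject}: only {len(trials)} trial(s); skipped",
                          stacklevel=2)
            continue
        if m >= len(trials):
            raise ValueError(
                f"subject {subject}: source_trials m={m} leaves no target trials "
                f"out of {len(trials)}"
            )
        src = _subject_windows(trials[:m], config.d, "source", subject)
        tgt = _subject_windows(trials[m:], config.d, "target", subject)
        fold_cfg = config.with_(seed=config.seed + 1000 * si)
        model, _ = train(src, tgt, fold_cfg, n_classes=len(dataset.class_names) or None)
        res = evaluate(model, tgt)
        accs.append(100.0 * res["window_accuracy"])
        confs.append(res["confusion"])
        names.append(subject)
        majority.append(100.0 * res["majority_accuracy"]
                        if res["majority_accuracy"] is not None else np.nan)
    if not accs:
        raise ValueError("no subject had enough trials for the within-subject protocol")
    return EvalReport.from_folds(accs, confs, config.to_dict(), names, majority)


def run_cross_subject(dataset: DatasetContainer, config: ModelConfig) -> EvalReport:
    """Leave-one-subject-out protocol: each subject serves once as the
    unlabelled target/test domain; all others form the labelled source."""
    subjects = dataset.subject_ids
    if len(subjects) < 2:
        raise ValueError(f"cross-subject protocol needs >= 2 subjects, got {len(subjects)}")
    accs, confs, names, majority = [], [], [], []
    for si, held_out in enumerate(subjects):
        src = []
        for other in subjects:
            if other != held_out:
                src.extend(_subject_windows(dataset.trials_for(other), config.d,
                                            "source", other))
        tgt = _subject_windows(dataset.trials_for(held_out), config.d, "target", held_out)
        fold_cfg = config.with_(seed=config.seed + 1000 * si)
        model, _ = train(src, tgt, fold_cfg, n_classes=len(dataset.class_names) or None)
        res = evaluate(model, tgt)
        accs.append(100.0 * res["window_accuracy"])
        confs.append(res["confusion"])
        names.append(held_out)
        majority.append(100.0 * res["majority_accuracy"]
                        if res["majority_accuracy"] is not None else np.nan)
    return EvalReport.from_folds(accs, confs, config.to_dict(), names, majority)


# ----------------------------------------------------------------------
def sweep(dataset: DatasetContainer, config: ModelConfig, param: str,
          values: list, protocol: str = "within") -> list[dict]:
    """Re-run a protocol across a hyperparameter grid.

    Returns tidy rows (param, value, fold, accuracy) suitable for CSV.
    """
    if param not in ("d", "K", "F_out", "tau", "lr", "batch_size", "max_epochs",
                     "temporal_kernel", "knn_k"):
        raise ValueError(f"unknown sweep parameter {param!r}")
    if not values:
        raise ValueError("empty sweep grid")
    runner = {"within": run_within_subject, "cross": run_cross_subject}.get(protocol)
    if runner is None:
        raise ValueError(f"protocol must be 'within' or 'cross', got {protocol!r}")
    rows = []
    for v in values:
        report = runner(dataset, config.with_(**{param: type(getattr(config, param))(v)}))
        for fold, acc in zip(report.fold_names, report.per_fold_accuracy):
            rows.append({"param": param, "value": v, "fold": fold, "accuracy": acc})
    return rows
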