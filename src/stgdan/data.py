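"""Containers and I/O for differential-entropy (DE) EEG feature datasets.

A recording trial is a sequence of per-second DE feature samples, one
``N x F_de`` matrix per second (``N`` channels, ``F_de`` frequency bands).
The model consumes sliding windows of ``T = 2d + 1`` consecutive samples,
where ``d`` is the temporal context coefficient.

Datasets are stored in a single hierarchical HDF5 file (one group per
trial) with a JSON sidecar carrying class names and band definitions.
A tolerant reader for the public SEED "ExtractedFeatures" MAT layout is
provided as an optional convenience; nothing in the package requires it.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
from scipy import signal

__all__ = [
    "TrialFeatures",
    "WindowSample",
    "DatasetContainer",
    "make_windows",
    "compute_de_features",
    "write_container",
    "read_container",
    "read_seed_layout",
]


@dataclass
class TrialFeatures:
    """One EEG trial: an ``L x N x F_de`` array of DE features (nats) plus
    its emotion label and subject/session identity."""

    features: np.ndarray
    label: int
    subject_id: str
    session_id: str = "1"
    channel_names: list[str] | None = None

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=np.float64)
        if self.features.ndim != 3:
            raise ValueError(
                f"features must be L x N x F_de, got shape {self.features.shape}"
            )
        if self.features.shape[0] < 1:
            raise ValueError("trial must contain at least one sample (L >= 1)")
        if not np.all(np.isfinite(self.features)):
            raise ValueError("trial features contain non-finite values")
        if self.label < 0:
            raise ValueError(f"label must be a non-negative class id, got {self.label}")
        if not self.subject_id:
            raise ValueError("subject_id must be non-empty")
        n = self.features.shape[1]
        if self.channel_names is None:
            self.channel_names = [f"ch{i:02d}" for i in range(n)]
        if len(self.channel_names) != n:
            raise ValueError(
                f"channel_names has {len(self.channel_names)} entries for {n} channels"
            )

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    @property
    def n_channels(self) -> int:
        return self.features.shape[1]

    @property
    def n_bands(self) -> int:
        return self.features.shape[2]


@dataclass
class WindowSample:
    """One model input: a ``T x N x F_de`` slice centred on sample
    ``center_index`` of its parent trial, carrying the trial label and a
    source/target domain tag."""

    tensor: np.ndarray
    center_index: int
    label: int
    domain: str = "source"
    trial_key: str | None = None  # parent-trial identity, for majority voting

    def __post_init__(self):
        self.tensor = np.asarray(self.tensor, dtype=np.float64)
        if self.tensor.ndim != 3:
            raise ValueError(f"window must be T x N x F_de, got {self.tensor.shape}")
        if self.domain not in ("source", "target"):
            raise ValueError(f"domain must be 'source' or 'target', got {self.domain!r}")


@dataclass
class DatasetContainer:
    """A list of trials sharing channel count, band count and class set."""

    trials: list[TrialFeatures]
    n_channels: int
    n_bands: int
    class_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        for t in self.trials:
            if t.n_channels != self.n_channels or t.n_bands != self.n_bands:
                raise ValueError(
                    "trial shape mismatch: expected "
                    f"N={self.n_channels}, F={self.n_bands}, got "
                    f"N={t.n_channels}, F={t.n_bands} (subject {t.subject_id})"
                )

    @classmethod
    def from_trials(cls, trials: Sequence[TrialFeatures],
                    class_names: Sequence[str] | None = None) -> "DatasetContainer":
        if not trials:
            raise ValueError("cannot infer dimensions from an empty trial list")
        n, f = trials[0].n_channels, trials[0].n_bands
        if class_names is None:
            n_classes = max(t.label for t in trials) + 1
            class_names = [f"class{i}" for i in range(n_classes)]
        return cls(list(trials), n, f, list(class_names))

    @property
    def subject_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for t in self.trials:
            seen.setdefault(t.subject_id, None)
        return list(seen)

    def trials_for(self, subject_id: str) -> list[TrialFeatures]:
        return [t for t in self.trials if t.subject_id == subject_id]


# ----------------------------------------------------------------------
def make_windows(trial: TrialFeatures, d: int, domain: str = "source",
                 trial_key: str | None = None) -> list[WindowSample]:
    """Slice a trial into its ``L - 2d`` context windows of length ``T=2d+1``.

    Window ``i`` (``d <= i <= L-d-1``) is the contiguous slice
    ``features[i-d : i+d+1]``; the trial label is copied to every window.
    """
    if d < 0:
        raise ValueError(f"context coefficient d must be >= 0, got {d}")
    L = trial.n_samples
    if L <= 2 * d:
        raise ValueError(
            f"trial too short: L={L} samples cannot support context d={d} "
            f"(requires L > 2d = {2 * d})"
        )
    return [
        WindowSample(
            tensor=trial.features[i - d: i + d + 1].copy(),
            center_index=i,
            label=trial.label,
            domain=domain,
            trial_key=trial_key,
        )
        for i in range(d, L - d)
    ]


# ----------------------------------------------------------------------
def compute_de_features(raw: np.ndarray, fs: float,
                        bands: Sequence[tuple[float, float]],
                        epoch_s: float = 1.0,
                        var_floor: float = 1e-12) -> np.ndarray:
    """Differential-entropy features from a raw multi-channel signal.

    The signal is band-pass filtered (zero-phase Butterworth) per band and
    split into non-overlapping epochs of ``epoch_s`` seconds; the DE of an
    epoch is the Gaussian closed form ``0.5 * ln(2*pi*e*var)`` of the
    filtered signal's variance within the epoch.

    Parameters
    ----------
    raw : array, shape (samples, N)
    fs : sampling rate in Hz; must exceed twice the highest band edge.
    bands : list of (low, high) band edges in Hz.
    epoch_s : epoch length in seconds (SEED convention: 1 s).
    var_floor : variance floor for silent epochs (the DE of a constant
        signal is -inf); floored epochs emit a warning.

    Returns
    -------
    array, shape (n_epochs, N, len(bands)) of DE values in nats.
    """
    raw = np.asarray(raw, dtype=np.float64)
    if raw.ndim != 2:
        raise ValueError(f"raw must be samples x channels, got {raw.shape}")
    max_edge = max(high for _, high in bands)
    if fs <= 2 * max_edge:
        raise ValueError(f"fs={fs} Hz must exceed twice the highest band edge {max_edge} Hz")
    n_per = int(round(epoch_s * fs))
    if n_per < 2:
        raise ValueError(f"epoch of {epoch_s}s at {fs} Hz has <2 samples")
    n_epochs = raw.shape[0] // n_per
    if n_epochs < 1:
        raise ValueError("signal shorter than one epoch")

    out = np.empty((n_epochs, raw.shape[1], len(bands)))
    floored = False
    for b, (low, high) in enumerate(bands):
        sos = signal.butter(4, [low, high], btype="bandpass", fs=fs, output="sos")
        filt = signal.sosfiltfilt(sos, raw, axis=0)
        for e in range(n_epochs):
            seg = filt[e * n_per: (e + 1) * n_per]
            var = seg.var(axis=0)
            if np.any(var < var_floor):
                floored = True
                var = np.maximum(var, var_floor)
            out[e, :, b] = 0.5 * np.log(2.0 * np.pi * np.e * var)
    if floored:
        warnings.warn(
            f"zero-variance epoch(s): variance floored at {var_floor}", stacklevel=2
        )
    return out


# ----------------------------------------------------------------------
_FORMAT_VERSION = 1


def write_container(container: DatasetContainer, path,
                    band_definitions: Sequence[tuple[float, float]] | None = None) -> Path:
    """Write a dataset to one hierarchical HDF5 file plus a JSON sidecar.

    Layout: root attrs ``n_channels``/``n_bands``/``class_names``; one group
    ``trials/trial_{i:05d}`` per trial with the feature array and metadata.
    """
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = _FORMAT_VERSION
        f.attrs["n_channels"] = container.n_channels
        f.attrs["n_bands"] = container.n_bands
        f.attrs["class_names"] = json.dumps(list(container.class_names))
        grp = f.create_group("trials")
        for i, t in enumerate(container.trials):
            g = grp.create_group(f"trial_{i:05d}")
            g.create_dataset("features", data=t.features)
            g.attrs["label"] = int(t.label)
            g.attrs["subject_id"] = t.subject_id
            g.attrs["session_id"] = t.session_id
            g.attrs["channel_names"] = json.dumps(t.channel_names)
    sidecar = {
        "class_names": list(container.class_names),
        "n_channels": container.n_channels,
        "n_bands": container.n_bands,
        "band_definitions_hz": [list(b) for b in band_definitions] if band_definitions else None,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))
    return path


def read_container(path) -> DatasetContainer:
    """Read a dataset written by :func:`write_container` (lossless)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with h5py.File(path, "r") as f:
        for key in ("n_channels", "n_bands", "class_names"):
            if key not in f.attrs:
                raise KeyError(f"container schema mismatch: missing root field {key!r}")
        n_channels = int(f.attrs["n_channels"])
        n_bands = int(f.attrs["n_bands"])
        class_names = json.loads(f.attrs["class_names"])
        trials = []
        for name in sorted(f.get("trials", {})):
            g = f["trials"][name]
            if "features" not in g:
                raise KeyError(f"container schema mismatch: missing field 'features' in {name}")
            feats = g["features"][()]
            if feats.shape[1] != n_channels or feats.shape[2] != n_bands:
                raise ValueError(
                    f"container schema mismatch: {name} has shape {feats.shape} "
                    f"but metadata declares N={n_channels}, F={n_bands}"
                )
            trials.append(
                TrialFeatures(
                    features=feats,
                    label=int(g.attrs["label"]),
                    subject_id=str(g.attrs["subject_id"]),
                    session_id=str(g.attrs["session_id"]),
                    channel_names=json.loads(g.attrs["channel_names"]),
                )
            )
    return DatasetContainer(trials, n_channels, n_bands, class_names)


# ----------------------------------------------------------------------
_SEED_KEY = re.compile(r"^de_(?:LDS|movingAve)?(\d+)$")


def read_seed_layout(path, feature_prefix: str = "de_LDS") -> DatasetContainer:
    """Read a directory of per-subject MAT files in the public SEED
    "ExtractedFeatures" layout (optional convenience).

    Expects ``label.mat`` with a ``label`` vector of per-trial labels and
    per-subject files with arrays named ``de_LDS{i}`` (or ``de_movingAve{i}``)
    of shape ``N x L x F_de``.  Labels in {-1,0,1} are shifted to {0,1,2}.
    Non-62-channel files are accepted with a warning.
    """
    from scipy.io import loadmat

    path = Path(path)
    if not path.is_dir():
        raise FileNotFoundError(f"SEED layout directory not found: {path}")
    label_file = path / "label.mat"
    if not label_file.exists():
        raise KeyError(f"missing label file: {label_file}")
    labels = np.ravel(loadmat(str(label_file))["label"]).astype(int)
    if labels.min() < 0:
        labels = labels - labels.min()

    trials: list[TrialFeatures] = []
    for mat_path in sorted(p for p in path.iterdir()
                           if p.suffix == ".mat" and p.name != "label.mat"):
        data = loadmat(str(mat_path))
        subject = mat_path.stem
        found = {}
        for key, arr in data.items():
            m = _SEED_KEY.match(key)
            if m and key.startswith(feature_prefix):
                found[int(m.group(1))] = arr
        if not found:
            raise KeyError(
                f"{mat_path.name}: no feature arrays with prefix {feature_prefix!r}"
            )
        for idx in sorted(found):
            arr = np.asarray(found[idx], dtype=np.float64)  # N x L x F
            if arr.ndim != 3:
                raise ValueError(f"{mat_path.name}:{feature_prefix}{idx} is not 3-D")
            if arr.shape[0] != 62:
                warnings.warn(
                    f"{mat_path.name}: expected 62 channels, got {arr.shape[0]}; "
                    "accepting channel count from the data", stacklevel=2
                )
            if idx - 1 >= len(labels):
                raise KeyError(f"{mat_path.name}: trial {idx} has no entry in label.mat")
            trials.append(
                TrialFeatures(
                    features=arr.transpose(1, 0, 2),  # -> L x N x F
                    label=int(labels[idx - 1]),
                    subject_id=subject,
                )
            )
    if not trials:
        raise FileNotFoundError(f"no subject MAT files found in {path}")
    return DatasetContainer.from_trials(trials)
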