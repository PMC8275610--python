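"""Raw recording -> model-ready 4-channel epochs.

Fixed pipeline order: resample to 50 Hz (shape-preserving piecewise cubic) ->
4th-order zero-phase Butterworth low-pass at 17 Hz -> rotation of the device
frame so mean gravity lies on +y -> magnitude channel -> linear detrend and
per-channel z-scoring over the whole test -> 2.56 s sliding windows with 50 %
overlap (128 samples, step 64).

The magnitude channel is computed from the *aligned, pre-normalisation* signal,
and normalisation is per channel per test (not per epoch). Zero-phase filtering
doubles the Butterworth attenuation, so the effective gain at the 17 Hz cutoff
is 0.5 rather than 1/sqrt(2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.interpolate import PchipInterpolator

from .synthetic import Recording

__all__ = [
    "Epoch",
    "EpochDataset",
    "EPOCH_SAMPLES",
    "EPOCH_STEP",
    "TARGET_FS",
    "resample_to_50hz",
    "lowpass_filter",
    "align_to_global_frame",
    "detrend_normalise",
    "epoch_signal",
    "preprocess_recording",
    "build_epoch_dataset",
    "resample_tests_per_subject",
    "balance_classes",
    "epoch_count",
]

TARGET_FS = 50.0
EPOCH_SAMPLES = 128   # 2.56 s at 50 Hz
EPOCH_STEP = 64       # 50 % overlap
CHANNEL_NAMES = ("ax", "ay", "az", "mag")

LOWPASS_CUTOFF_HZ = 17.0
LOWPASS_ORDER = 4


@dataclass
class Epoch:
    """One model input: a 4 x 128 window (a_x, a_y, a_z, ||a||), normalised units."""

    x: np.ndarray
    subject_id: str
    test_id: str
    start_index: int
    label: str
    fs_hz: float = TARGET_FS

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        if self.x.shape != (4, EPOCH_SAMPLES):
            raise ValueError(f"epoch must be 4x{EPOCH_SAMPLES}, got {self.x.shape}")
        if not np.all(np.isfinite(self.x)):
            raise ValueError("epoch contains non-finite values")


@dataclass
class EpochDataset:
    """Columnar epoch collection.

    ``X`` is (n, 4, 128); ``labels``/``subject_ids``/``test_ids``/``starts``
    are parallel arrays. ``draws`` distinguishes repeated with-replacement test
    draws so (subject, test, draw, start) stays unique.
    """

    X: np.ndarray
    labels: np.ndarray
    subject_ids: np.ndarray
    test_ids: np.ndarray
    starts: np.ndarray
    label_space: tuple[str, ...]
    draws: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        n = len(self.X)
        if self.draws is None:
            self.draws = np.zeros(n, dtype=int)
        for name in ("labels", "subject_ids", "test_ids", "starts", "draws"):
            arr = np.asarray(getattr(self, name))
            if len(arr) != n:
                raise ValueError(f"{name} length {len(arr)} != {n} epochs")
            setattr(self, name, arr)
        unknown = set(np.unique(self.labels)) - set(self.label_space)
        if unknown:
            raise ValueError(f"labels outside label_space: {sorted(unknown)}")
        keys = list(zip(self.subject_ids, self.test_ids, self.draws, self.starts))
        if len(set(keys)) != n:
            raise ValueError("duplicate (subject, test, draw, start) keys")

    def __len__(self) -> int:
        return len(self.X)

    def subset(self, mask: np.ndarray) -> "EpochDataset":
        return EpochDataset(self.X[mask], self.labels[mask],
                            self.subject_ids[mask], self.test_ids[mask],
                            self.starts[mask], self.label_space,
                            self.draws[mask])

    @property
    def subjects(self) -> np.ndarray:
        return np.unique(self.subject_ids)

    def manifest(self) -> pd.DataFrame:
        return pd.DataFrame({"subject_id": self.subject_ids,
                             "test_id": self.test_ids, "draw": self.draws,
                             "start": self.starts, "label": self.labels})

    @classmethod
    def from_epochs(cls, epochs: list[Epoch],
                    label_space: tuple[str, ...] | None = None) -> "EpochDataset":
        if not epochs:
            raise ValueError("no epochs")
        if label_space is None:
            label_space = tuple(sorted({e.label for e in epochs}))
        return cls(np.stack([e.x for e in epochs]),
                   np.array([e.label for e in epochs]),
                   np.array([e.subject_id for e in epochs]),
                   np.array([e.test_id for e in epochs]),
                   np.array([e.start_index for e in epochs]), label_space)

    def save(self, path) -> None:
        np.savez_compressed(path, X=self.X, labels=self.labels,
                            subject_ids=self.subject_ids, test_ids=self.test_ids,
                            starts=self.starts, draws=self.draws,
                            label_space=np.array(self.label_space))

    @classmethod
    def load(cls, path) -> "EpochDataset":
        z = np.load(path, allow_pickle=False)
        return cls(z["X"], z["labels"], z["subject_ids"], z["test_ids"],
                   z["starts"], tuple(z["label_space"]), z["draws"])


# ---------------------------------------------------------------------------
# per-recording stages


def resample_to_50hz(rec: Recording) -> Recording:
    """Shape-preserving (monotone piecewise-cubic) resampling to 50 Hz."""
    if abs(rec.fs_hz - TARGET_FS) < 1e-9:
        return rec
    if rec.n_samples < 4:
        raise ValueError("need at least 4 samples to interpolate")
    t_new = np.arange(rec.t[0], rec.t[-1] + 0.5 / TARGET_FS, 1.0 / TARGET_FS)
    t_new = t_new[t_new <= rec.t[-1] + 1e-12]
    a_new = np.column_stack([
        PchipInterpolator(rec.t, rec.a_xyz[:, i])(t_new) for i in range(3)])
    return replace(rec, fs_hz=TARGET_FS, t=t_new, a_xyz=a_new)


def lowpass_filter(rec: Recording, cutoff_hz: float = LOWPASS_CUTOFF_HZ,
                   order: int = LOWPASS_ORDER) -> Recording:
    """Zero-phase (forward-backward) Butterworth low-pass, 17 Hz, order 4."""
    sos = sps.butter(order, cutoff_hz, btype="low", fs=rec.fs_hz, output="sos")
    if rec.n_samples <= 3 * order:
        raise ValueError("signal shorter than filter warm-up")
    a_new = sps.sosfiltfilt(sos, rec.a_xyz, axis=0)
    return replace(rec, a_xyz=a_new)


def align_to_global_frame(rec: Recording) -> Recording:
    """Rotate the device frame so the mean (gravity) vector maps onto +y.

    The minimal rotation about the axis perpendicular to both vectors is used;
    rotation preserves per-sample magnitude exactly. If the mean vector is
    nearly zero (no identifiable gravity) alignment is skipped with a warning.
    """
    g = rec.a_xyz.mean(axis=0)
    norm = np.linalg.norm(g)
    if norm < 0.1:
        warnings.warn("mean acceleration < 0.1 g; skipping frame alignment")
        return rec
    ghat = g / norm
    ey = np.array([0.0, 1.0, 0.0])
    c = float(np.clip(ghat @ ey, -1.0, 1.0))
    if c > 1 - 1e-12:
        return rec
    if c < -1 + 1e-12:
        # antiparallel: rotate 180 degrees about x
        R = np.diag([1.0, -1.0, -1.0])
    else:
        v = np.cross(ghat, ey)
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        R = np.eye(3) + vx + vx @ vx / (1 + c)  # Rodrigues
    return replace(rec, a_xyz=rec.a_xyz @ R.T)


def detrend_normalise(rec: Recording) -> np.ndarray:
    """Return a (4, N) processed test: detrended, z-scored channels.

    The magnitude channel is computed from the aligned signal *before* any
    normalisation, then all four channels are linearly detrended and scaled to
    zero mean / unit variance over the whole test. A zero-variance channel is
    set to zeros with a warning.
    """
    mag = np.linalg.norm(rec.a_xyz, axis=1)
    x = np.vstack([rec.a_xyz.T, mag[None, :]])
    x = sps.detrend(x, axis=1, type="linear")
    sd = x.std(axis=1, ddof=0)
    out = np.zeros_like(x)
    for i in range(4):
        if sd[i] < 1e-12:
            warnings.warn(f"zero-variance channel {CHANNEL_NAMES[i]}; set to zeros")
            continue
        out[i] = (x[i] - x[i].mean()) / sd[i]
    return out


def epoch_count(n_samples: int) -> int:
    """Number of 128-sample windows at step 64 starting at sample 0."""
    if n_samples < EPOCH_SAMPLES:
        return 0
    return (n_samples - EPOCH_SAMPLES) // EPOCH_STEP + 1


def epoch_signal(x: np.ndarray, rec: Recording) -> list[Epoch]:
    """Slice a processed (4, N) test into 128-sample epochs with 50 % overlap.

    Windows are half-open [start, start+128), starts 0, 64, 128, ...; a
    trailing partial window is discarded.
    """
    n = x.shape[1]
    if n < EPOCH_SAMPLES:
        warnings.warn(f"test {rec.test_id} shorter than one epoch; no epochs")
        return []
    return [
        Epoch(x[:, s:s + EPOCH_SAMPLES], subject_id=rec.subject_id,
              test_id=rec.test_id, start_index=s, label=rec.group)
        for s in range(0, n - EPOCH_SAMPLES + 1, EPOCH_STEP)
    ]


def preprocess_recording(rec: Recording) -> list[Epoch]:
    """Full chain on one recording: resample, filter, align, normalise, epoch."""
    rec = resample_to_50hz(rec)
    rec = lowpass_filter(rec)
    rec = align_to_global_frame(rec)
    x = detrend_normalise(rec)
    return epoch_signal(x, rec)


def build_epoch_dataset(recordings: list[Recording],
                        label_space: tuple[str, ...] | None = None,
                        placement: str | None = "waist_belt") -> EpochDataset:
    """Preprocess a cohort into one EpochDataset.

    ``placement`` keeps only tests recorded with the stated device placement
    (the running-belt criterion of the target study); pass None to keep all.
    """
    epochs: list[Epoch] = []
    for rec in recordings:
        if placement is not None and rec.placement != placement:
            continue
        epochs.extend(preprocess_recording(rec))
    return EpochDataset.from_epochs(epochs, label_space)


# ---------------------------------------------------------------------------
# dataset-level stages


def resample_tests_per_subject(dataset: EpochDataset, m: int = 10,
                               rng: np.random.Generator | int | None = None,
                               ) -> EpochDataset:
    """Sample m tests per subject with replacement (default m = 10).

    Equalises the contribution of subjects with very different numbers of
    repeated tests. Duplicated draws are kept as distinct entries (tagged with
    a draw index). Subjects with zero tests are excluded with a warning.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    parts = []
    for sid in dataset.subjects:
        smask = dataset.subject_ids == sid
        tests = np.unique(dataset.test_ids[smask])
        if tests.size == 0:  # pragma: no cover - subjects come from epochs
            warnings.warn(f"subject {sid} has no tests; excluded")
            continue
        chosen = rng.choice(tests, size=m, replace=True)
        for draw, tid in enumerate(chosen):
            tmask = smask & (dataset.test_ids == tid)
            part = dataset.subset(tmask)
            part.draws = np.full(len(part), draw, dtype=int)
            parts.append(part)
    return _concat(parts, dataset.label_space)


def balance_classes(dataset: EpochDataset,
                    rng: np.random.Generator | int | None = None) -> EpochDataset:
    """Random oversampling with replacement until per-class counts are equal.

    For training/validation splits only — never applied to test data.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    classes, counts = np.unique(dataset.labels, return_counts=True)
    if any(c == 0 for c in counts) or len(classes) == 0:
        raise ValueError("every class needs at least one epoch")
    target = counts.max()
    parts = [dataset]
    next_draw = int(dataset.draws.max()) + 1  # re-tag so duplicates stay unique
    for cls, cnt in zip(classes, counts):
        deficit = target - cnt
        if deficit == 0:
            continue
        idx = np.flatnonzero(dataset.labels == cls)
        sel = rng.choice(idx, size=deficit, replace=True)
        extra = EpochDataset(
            dataset.X[sel], dataset.labels[sel], dataset.subject_ids[sel],
            dataset.test_ids[sel], dataset.starts[sel], dataset.label_space,
            next_draw + np.arange(deficit))
        next_draw += deficit
        parts.append(extra)
    return _concat(parts, dataset.label_space)


def _concat(parts: list[EpochDataset],
            label_space: tuple[str, ...]) -> EpochDataset:
    if not parts:
        raise ValueError("nothing to concatenate")
    return EpochDataset(
        np.concatenate([p.X for p in parts]),
        np.concatenate([p.labels for p in parts]),
        np.concatenate([p.subject_ids for p in parts]),
        np.concatenate([p.test_ids for p in parts]),
        np.concatenate([p.starts for p in parts]),
        label_space,
        np.concatenate([p.draws for p in parts]))
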