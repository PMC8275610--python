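"""Synthetic tri-axial accelerometer recordings for walk tests and activity recognition.

Real remote walk-test sensor data of people with multiple sclerosis is held under
restricted access, so this module generates 50 Hz, three-axis accelerometer
recordings that reproduce the qualitative class structure such an analysis relies
on:

* **HC** (healthy controls): distinct steps at a brisk, consistent cadence, with
  strong gait-band (0.5--3 Hz) energy.
* **PwMSmild** (mildly disabled MS): step harmonics above the gait band
  (> 3.5 Hz) in addition to the fundamental.
* **PwMSmod** (moderately disabled MS): slower, more variable cadence, reduced
  gait-band signal-to-noise, and high-frequency bursts that are time-locked to
  each step.

A second generator emulates a human-activity-recognition (HAR) source domain
with the usual smartphone activity classes (walking, stairs, sitting, standing,
laying, jogging), which serves as the transfer-learning source task.

Every recording is a pure function of a :class:`SubjectProfile` (or activity
label) plus a NumPy generator, so cohorts are byte-reproducible from a config
and one root seed.
"""

from __future__ import annotations

import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SubjectProfile",
    "Recording",
    "GroupDistribution",
    "SyntheticConfig",
    "GROUPS",
    "HAR_ACTIVITIES",
    "generate_gait_recording",
    "generate_har_recording",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
    "subject_rng",
]

GROUPS = ("HC", "PwMSmild", "PwMSmod")

#: HAR label sets of the two emulated source datasets.
HAR_ACTIVITIES = ("walking", "stairs", "sitting", "standing", "laying", "jogging")

GRAVITY_G = 1.0  # constant gravity magnitude, in g


@dataclass(frozen=True)
class SubjectProfile:
    """Generative parameters of one subject's gait.

    All amplitudes are in units of g; ``cadence_hz`` is steps per second.
    ``harmonic_gain`` scales step harmonics that fall above 3.5 Hz, and
    ``perturb_amp_g``/``perturb_freq_hz`` parameterise the exponentially
    decaying high-frequency burst emitted at every step event.
    """

    subject_id: str
    group: str
    cadence_hz: float = 1.9
    step_jitter_s: float = 0.010
    step_amp_g: float = 0.5
    perturb_amp_g: float = 0.0
    perturb_freq_hz: float = 8.0
    harmonic_gain: float = 0.0
    noise_sd_g: float = 0.03

    def __post_init__(self) -> None:
        if self.cadence_hz <= 0:
            raise ValueError("cadence_hz must be positive")
        for name in ("step_amp_g", "perturb_amp_g", "harmonic_gain", "noise_sd_g",
                     "step_jitter_s"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.step_jitter_s >= 1.0 / self.cadence_hz:
            raise ValueError("step_jitter_s must be smaller than the step period")


@dataclass
class Recording:
    """One raw tri-axial accelerometer trace of one test.

    ``a_xyz`` is an (N, 3) array in g; ``t`` the matching time vector in
    seconds (uniform, strictly increasing). ``ground_truth`` keeps the
    generating profile and step times — synthetic provenance only, never used
    by the analysis itself.
    """

    subject_id: str
    test_id: str
    group: str
    fs_hz: float
    t: np.ndarray
    a_xyz: np.ndarray
    placement: str = "waist_belt"
    ground_truth: dict | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.a_xyz = np.asarray(self.a_xyz, dtype=float)
        if self.a_xyz.ndim != 2 or self.a_xyz.shape[1] != 3:
            raise ValueError("a_xyz must be an (N, 3) array")
        if self.a_xyz.shape[0] != self.t.shape[0]:
            raise ValueError("a_xyz and t lengths differ")
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")
        if self.t.size > 1 and np.any(np.diff(self.t) <= 0):
            raise ValueError("t must be strictly increasing")

    @property
    def n_samples(self) -> int:
        return int(self.t.shape[0])

    @property
    def duration_s(self) -> float:
        return float(self.t[-1] - self.t[0]) if self.t.size else 0.0


@dataclass(frozen=True)
class GroupDistribution:
    """Mean/SD of every SubjectProfile field for one group (SD of 0 pins a value)."""

    cadence_hz: tuple[float, float] = (1.9, 0.15)
    step_jitter_s: tuple[float, float] = (0.010, 0.002)
    step_amp_g: tuple[float, float] = (0.50, 0.05)
    perturb_amp_g: tuple[float, float] = (0.0, 0.0)
    perturb_freq_hz: tuple[float, float] = (8.0, 0.0)
    harmonic_gain: tuple[float, float] = (0.0, 0.0)
    noise_sd_g: tuple[float, float] = (0.03, 0.005)


def default_group_distributions() -> dict[str, GroupDistribution]:
    """Per-group generative defaults.

    Healthy walking: ~1.9 Hz cadence, tight (10 ms) step timing. Mild MS: a
    slightly slower cadence and above-gait-band harmonics. Moderate MS:
    markedly slower and more variable cadence, smaller step impulses, 1.5x
    broadband noise (reduced gait-band SNR) and 0.3 g step-locked bursts with
    a 5--12 Hz carrier.
    """
    return {
        "HC": GroupDistribution(),
        "PwMSmild": GroupDistribution(
            cadence_hz=(1.8, 0.2),
            step_jitter_s=(0.015, 0.003),
            step_amp_g=(0.45, 0.05),
            harmonic_gain=(0.3, 0.05),
        ),
        "PwMSmod": GroupDistribution(
            cadence_hz=(1.5, 0.2),
            step_jitter_s=(0.035, 0.005),
            step_amp_g=(0.35, 0.05),
            perturb_amp_g=(0.3, 0.05),
            perturb_freq_hz=(8.5, 1.2),  # bursts within 5-12 Hz
            noise_sd_g=(0.045, 0.005),
        ),
    }


@dataclass
class SyntheticConfig:
    """Cohort-level configuration; fully serialisable so a run is reproducible.

    Defaults mirror the study conditions: 120 s tests (a two-minute walk) at
    50 Hz and a 24 / 52 / 21 subject cohort for HC / PwMSmild / PwMSmod.
    """

    n_subjects: dict[str, int] = field(
        default_factory=lambda: {"HC": 24, "PwMSmild": 52, "PwMSmod": 21})
    tests_per_subject: int = 10
    duration_s: float = 120.0
    fs_hz: float = 50.0
    gravity_g: float = GRAVITY_G
    rng_seed: int = 0
    groups: dict[str, GroupDistribution] = field(
        default_factory=default_group_distributions)

    def __post_init__(self) -> None:
        if self.duration_s <= 2.56:
            raise ValueError("duration_s must exceed one epoch (2.56 s)")
        if any(n < 1 for n in self.n_subjects.values()):
            raise ValueError("n_subjects must be >= 1 per group")
        if self.tests_per_subject < 1:
            raise ValueError("tests_per_subject must be >= 1")
        unknown = set(self.n_subjects) - set(self.groups)
        if unknown:
            raise ValueError(f"groups without distributions: {sorted(unknown)}")

    def to_yaml(self, path: str | Path) -> None:
        payload = asdict(self)
        payload["groups"] = {g: asdict(d) for g, d in self.groups.items()}
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticConfig":
        payload = yaml.safe_load(Path(path).read_text())
        groups = {
            g: GroupDistribution(**{k: tuple(v) for k, v in d.items()})
            for g, d in payload.pop("groups").items()
        }
        return cls(groups=groups, **payload)


def subject_rng(root_seed: int, subject_id: str) -> np.random.Generator:
    """Child generator for one subject, stable under cohort extension.

    The child seed is derived by hashing the subject id (CRC-32) together with
    the root seed, so adding subjects never reshuffles existing ones.
    """
    key = zlib.crc32(str(subject_id).encode())
    return np.random.default_rng(np.random.SeedSequence([int(root_seed), key]))


# ---------------------------------------------------------------------------
# signal construction


def _step_times(cadence_hz: float, jitter_s: float, duration_s: float,
                rng: np.random.Generator) -> np.ndarray:
    period = 1.0 / cadence_hz
    k = np.arange(1, int(np.floor(duration_s * cadence_hz)))
    times = k * period + rng.normal(0.0, jitter_s, size=k.size)
    return times[(times > 0) & (times < duration_s)]


def _step_train(t: np.ndarray, step_times: np.ndarray, amp: float,
                cadence_hz: float) -> np.ndarray:
    """Sum of Gaussian-windowed single-cycle sinusoids, one per step.

    Window SD = 0.25 / cadence keeps each impulse band-limited around the
    cadence fundamental while still looking like a discrete step.
    """
    sigma = 0.25 / cadence_hz
    out = np.zeros_like(t)
    for t_k in step_times:
        dt = t - t_k
        # evaluate only near the step (5 sigma) to keep cost linear
        sel = np.abs(dt) < 5 * sigma
        d = dt[sel]
        out[sel] += amp * np.exp(-0.5 * (d / sigma) ** 2) * np.sin(
            2 * np.pi * cadence_hz * d)
    return out


def _perturbation_train(t: np.ndarray, step_times: np.ndarray, amp: float,
                        freq_hz: float, tau_s: float = 0.15) -> np.ndarray:
    """Exponentially decaying high-frequency burst launched at every step.

    The decay constant (0.15 s, about a quarter of a slow step period) keeps
    each burst visible as a step-locked disturbance in a time-frequency view
    rather than a single-sample click.
    """
    out = np.zeros_like(t)
    for t_k in step_times:
        dt = t - t_k
        sel = (dt >= 0) & (dt < 6 * tau_s)
        d = dt[sel]
        out[sel] += amp * np.exp(-d / tau_s) * np.sin(2 * np.pi * freq_hz * d)
    return out


def _harmonics(t: np.ndarray, step_times: np.ndarray, profile: SubjectProfile,
               fs_hz: float) -> np.ndarray:
    """Step-locked harmonics of the cadence that fall above the gait band (>3.5 Hz)."""
    out = np.zeros_like(t)
    if profile.harmonic_gain <= 0:
        return out
    sigma = 0.5 / profile.cadence_hz
    for k in range(2, 6):
        f = k * profile.cadence_hz
        if f <= 3.5 or f >= fs_hz / 2:
            continue
        amp = profile.harmonic_gain * profile.step_amp_g / (k - 1)
        for t_k in step_times:
            dt = t - t_k
            sel = np.abs(dt) < 3 * sigma
            d = dt[sel]
            out[sel] += amp * np.exp(-0.5 * (d / sigma) ** 2) * np.sin(
                2 * np.pi * f * d)
    return out


def generate_gait_recording(profile: SubjectProfile, duration_s: float = 120.0,
                            fs_hz: float = 50.0,
                            rng: np.random.Generator | None = None,
                            test_id: str = "t0",
                            gravity_g: float = GRAVITY_G,
                            placement: str = "waist_belt") -> Recording:
    """Simulate one walk test.

    The vertical (y) axis carries gravity plus the step-impulse train, any
    above-gait-band harmonics, and any step-locked perturbation bursts; the
    horizontal axes carry attenuated, quarter-period phase-shifted copies of
    the step train. Broadband Gaussian noise with SD ``noise_sd_g`` is added
    to all three axes.
    """
    if duration_s < 5:
        raise ValueError("duration_s must be >= 5 s")
    if fs_hz <= 0:
        raise ValueError("fs_hz must be positive")
    rng = np.random.default_rng() if rng is None else rng

    n = int(round(duration_s * fs_hz))
    t = np.arange(n) / fs_hz
    steps = _step_times(profile.cadence_hz, profile.step_jitter_s, duration_s, rng)

    vertical = _step_train(t, steps, profile.step_amp_g, profile.cadence_hz)
    vertical = vertical + _harmonics(t, steps, profile, fs_hz)
    perturb = np.zeros_like(t)
    if profile.perturb_amp_g > 0:
        perturb = _perturbation_train(t, steps, profile.perturb_amp_g,
                                      profile.perturb_freq_hz)
        vertical = vertical + perturb

    shift = int(round(0.25 / profile.cadence_hz * fs_hz))  # quarter step period
    ax = 0.40 * np.roll(vertical, shift)
    az = 0.25 * np.roll(vertical, -shift)
    ay = gravity_g + vertical

    a = np.stack([ax, ay, az], axis=1)
    if profile.noise_sd_g > 0:
        a = a + rng.normal(0.0, profile.noise_sd_g, size=a.shape)

    return Recording(
        subject_id=profile.subject_id, test_id=test_id, group=profile.group,
        fs_hz=fs_hz, t=t, a_xyz=a, placement=placement,
        ground_truth={"profile": asdict(profile), "step_times": steps,
                      "perturbation": perturb},
    )


_STATIC_ORIENTATIONS = {
    # unit gravity direction in the device frame while static
    "standing": np.array([0.0, 1.0, 0.0]),
    "sitting": np.array([np.sin(np.pi / 4), np.cos(np.pi / 4), 0.0]),
    "laying": np.array([1.0, 0.0, 0.0]),
}

_HAR_GAIT = {
    # cadence_hz, step_amp_g for the dynamic activities
    "walking": (2.0, 0.45),
    "jogging": (2.7, 0.85),
    "stairs": (1.8, 0.50),
}


def generate_har_recording(activity: str, duration_s: float = 12.0,
                           fs_hz: float = 50.0,
                           rng: np.random.Generator | None = None,
                           subject_id: str = "har0", test_id: str = "t0",
                           noise_sd_g: float = 0.03,
                           gravity_g: float = GRAVITY_G) -> Recording:
    """Simulate one recording of a smartphone activity-recognition class.

    Static activities are gravity along an activity-specific orientation plus
    low noise; walking/jogging reuse the gait model at ~2.0 / ~2.7 Hz cadence
    (jogging with larger impulses); stairs are walking whose step amplitude
    alternates at half the cadence (one leg leading).
    """
    if activity not in HAR_ACTIVITIES:
        raise ValueError(f"unknown activity {activity!r}; expected one of {HAR_ACTIVITIES}")
    rng = np.random.default_rng() if rng is None else rng

    if activity in _STATIC_ORIENTATIONS:
        n = int(round(duration_s * fs_hz))
        t = np.arange(n) / fs_hz
        a = np.tile(gravity_g * _STATIC_ORIENTATIONS[activity], (n, 1))
        if noise_sd_g > 0:
            a = a + rng.normal(0.0, noise_sd_g, size=a.shape)
        return Recording(subject_id=subject_id, test_id=test_id, group=activity,
                         fs_hz=fs_hz, t=t, a_xyz=a, placement="pocket")

    cadence, amp = _HAR_GAIT[activity]
    cadence = cadence * float(rng.normal(1.0, 0.04))
    profile = SubjectProfile(subject_id=subject_id, group=activity,
                             cadence_hz=cadence, step_amp_g=amp,
                             step_jitter_s=0.012, noise_sd_g=noise_sd_g)
    rec = generate_gait_recording(profile, duration_s=duration_s, fs_hz=fs_hz,
                                  rng=rng, test_id=test_id, gravity_g=gravity_g,
                                  placement="pocket")
    if activity == "stairs":
        # alternating step-amplitude modulation at cadence/2
        mod = 1.0 + 0.35 * np.sin(np.pi * cadence * rec.t)
        vertical = rec.a_xyz[:, 1] - gravity_g
        rec.a_xyz[:, 1] = gravity_g + vertical * mod
    rec.group = activity
    return rec


def _draw_profile(subject_id: str, group: str, dist: GroupDistribution,
                  rng: np.random.Generator) -> SubjectProfile:
    vals = {}
    for name in ("cadence_hz", "step_jitter_s", "step_amp_g", "perturb_amp_g",
                 "perturb_freq_hz", "harmonic_gain", "noise_sd_g"):
        mean, sd = getattr(dist, name)
        vals[name] = float(rng.normal(mean, sd)) if sd > 0 else float(mean)
    vals["cadence_hz"] = max(vals["cadence_hz"], 0.5)
    for name in ("step_jitter_s", "step_amp_g", "perturb_amp_g",
                 "harmonic_gain", "noise_sd_g"):
        vals[name] = max(vals[name], 0.0)
    vals["step_jitter_s"] = min(vals["step_jitter_s"],
                                0.5 / vals["cadence_hz"])
    return SubjectProfile(subject_id=subject_id, group=group, **vals)


def generate_cohort(cfg: SyntheticConfig) -> tuple[list[Recording], pd.DataFrame]:
    """Generate a full cohort and its manifest.

    One profile is drawn per subject from the group distributions, then
    ``tests_per_subject`` recordings are generated per subject. Per-subject
    child seeds are derived by stable hashing, so the cohort is fully
    determined by the config and extensible without reshuffling.
    """
    recordings: list[Recording] = []
    rows = []
    for group in cfg.n_subjects:
        dist = cfg.groups[group]
        for i in range(cfg.n_subjects[group]):
            sid = f"{group}_s{i:03d}"
            rng = subject_rng(cfg.rng_seed, sid)
            profile = _draw_profile(sid, group, dist, rng)
            for j in range(cfg.tests_per_subject):
                tid = f"{sid}_t{j:02d}"
                rec = generate_gait_recording(
                    profile, duration_s=cfg.duration_s, fs_hz=cfg.fs_hz,
                    rng=rng, test_id=tid, gravity_g=cfg.gravity_g)
                recordings.append(rec)
                rows.append({"subject_id": sid, "test_id": tid, "group": group,
                             "placement": rec.placement})
    manifest = pd.DataFrame(rows)
    return recordings, manifest


def generate_har_cohort(n_subjects: int = 10, tests_per_activity: int = 2,
                        duration_s: float = 12.0, fs_hz: float = 50.0,
                        activities: Iterable[str] = HAR_ACTIVITIES,
                        rng_seed: int = 0) -> tuple[list[Recording], pd.DataFrame]:
    """HAR source-domain cohort: every subject performs every activity."""
    recordings: list[Recording] = []
    rows = []
    for i in range(n_subjects):
        sid = f"har_s{i:03d}"
        rng = subject_rng(rng_seed, sid)
        for act in activities:
            for j in range(tests_per_activity):
                tid = f"{sid}_{act}_t{j:02d}"
                rec = generate_har_recording(act, duration_s=duration_s,
                                             fs_hz=fs_hz, rng=rng,
                                             subject_id=sid, test_id=tid)
                recordings.append(rec)
                rows.append({"subject_id": sid, "test_id": tid, "group": act,
                             "placement": rec.placement})
    return recordings, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# on-disk layout: one CSV per test plus a cohort manifest CSV


def write_cohort(recordings: list[Recording], manifest: pd.DataFrame,
                 out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = []
    for rec in recordings:
        fname = f"{rec.test_id}.csv"
        df = pd.DataFrame({"t": rec.t, "ax": rec.a_xyz[:, 0],
                           "ay": rec.a_xyz[:, 1], "az": rec.a_xyz[:, 2]})
        df.to_csv(out / fname, index=False)
        files.append(fname)
    manifest = manifest.copy()
    manifest["file"] = files
    manifest_path = out / "manifest.csv"
    manifest.to_csv(manifest_path, index=False)
    return manifest_path


def read_cohort(manifest_path: str | Path) -> tuple[list[Recording], pd.DataFrame]:
    manifest_path = Path(manifest_path)
    manifest = pd.read_csv(manifest_path)
    recordings = []
    for row in manifest.itertuples(index=False):
        df = pd.read_csv(manifest_path.parent / row.file)
        t = df["t"].to_numpy()
        fs = 1.0 / float(np.median(np.diff(t))) if len(t) > 1 else 50.0
        recordings.append(Recording(
            subject_id=row.subject_id, test_id=row.test_id, group=row.group,
            fs_hz=round(fs, 6), t=t,
            a_xyz=df[["ax", "ay", "az"]].to_numpy(),
            placement=getattr(row, "placement", "waist_belt")))
    return recordings, manifest
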