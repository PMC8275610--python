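"""Morlet-wavelet scalograms and gait-band energy summaries.

Walking concentrates energy in the 0.5--3 Hz "gait band" (with brisk healthy
gait at 1.5--3 Hz); disease-related perturbations show up as energy above
3.5 Hz that is time-locked to step events. The continuous wavelet transform
with a Morlet analysing wavelet resolves both at once, and band energies E_s
summarise the scalogram over configurable frequency bands.

The default frequency grid is 64 log-spaced voices over 0.25--17 Hz — fine
enough to resolve the gait band and reaching the low-pass filter edge.
Magnitudes |CWT| are stored; squaring happens only inside band energies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt

__all__ = ["Scalogram", "DEFAULT_BANDS", "cwt_scalogram", "band_energy",
           "render_panel"]

#: Band edges in Hz: the gait domain, the brisk-gait upper half, and the
#: above-gait perturbation band (up to the 17 Hz filter edge).
DEFAULT_BANDS = {"gait": (0.5, 3.0), "fast_gait": (1.5, 3.0),
                 "perturbation": (3.5, 17.0)}

_WAVELET = "morl"


@dataclass
class Scalogram:
    """|CWT| magnitude over a (frequency x time) grid, plus band energies."""

    coefficients: np.ndarray      # (n_freqs, n_samples), magnitudes >= 0
    freqs_hz: np.ndarray          # monotone increasing
    t_s: np.ndarray
    band_energies: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any(self.coefficients < 0):
            raise ValueError("scalogram magnitudes must be non-negative")
        if np.any(np.diff(self.freqs_hz) <= 0):
            raise ValueError("frequency axis must be strictly increasing")


def default_freqs(fs_hz: float = 50.0, n_voices: int = 64,
                  f_min: float = 0.25, f_max: float = 17.0) -> np.ndarray:
    f_max = min(f_max, 0.499 * fs_hz)
    return np.geomspace(f_min, f_max, n_voices)


def cwt_scalogram(signal: np.ndarray, fs: float,
                  freqs: np.ndarray | None = None) -> Scalogram:
    """Discretised Morlet CWT at scales mapped from a frequency grid.

    Scales follow the Morlet centre-frequency relation
    scale = f_c * fs / f, so a pure tone at f produces a time-averaged ridge
    at the nearest grid frequency.
    """
    signal = np.asarray(signal, dtype=float)
    if signal.size == 0:
        raise ValueError("empty signal")
    if fs <= 0:
        raise ValueError("fs must be positive")
    freqs = default_freqs(fs) if freqs is None else np.asarray(freqs, dtype=float)
    if np.any(freqs <= 0) or np.any(freqs >= fs / 2):
        raise ValueError("requested frequencies must lie in (0, fs/2)")
    freqs = np.sort(freqs)
    scales = pywt.frequency2scale(_WAVELET, freqs / fs)
    coef, actual = pywt.cwt(signal, scales, _WAVELET, sampling_period=1.0 / fs)
    scal = Scalogram(coefficients=np.abs(coef), freqs_hz=np.asarray(actual),
                     t_s=np.arange(signal.size) / fs)
    for name, band in DEFAULT_BANDS.items():
        lo, hi = band
        if lo < scal.freqs_hz[-1] and hi > scal.freqs_hz[0]:
            scal.band_energies[name] = band_energy(scal, band)
    return scal


def band_energy(scal: Scalogram, band_hz: tuple[float, float]) -> float:
    """Mean squared |CWT| magnitude over a band x time region (E_s).

    Normalised by the region size so bands of different widths are
    comparable; a band that covers no grid frequencies is an error.
    """
    lo, hi = band_hz
    mask = (scal.freqs_hz >= lo) & (scal.freqs_hz <= hi)
    if not mask.any():
        raise ValueError(f"band {band_hz} covers no frequency bins")
    region = scal.coefficients[mask, :]
    return float(np.mean(region ** 2))


def render_panel(recording, predictions, scalogram: Scalogram, epoch,
                 relevance, out, har_predictions=None):
    """Composite interpretation panel for one test.

    Three aligned rows — raw 3-axis trace with the magnitude in bold, the
    scalogram top view, and per-epoch class probabilities — plus a zoomed
    subplot of one shaded epoch with its relevance overlay.

    ``predictions`` is a sequence of (start_index, probability-vector) pairs;
    ``epoch``/``relevance`` select the zoomed window.
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from matplotlib.colors import LinearSegmentedColormap, Normalize

    fs = recording.fs_hz
    t = recording.t
    if abs(scalogram.t_s[-1] - (t[-1] - t[0])) > 2.0 / fs + 1e-9:
        raise ValueError("scalogram and recording time bases are inconsistent")

    fig = plt.figure(figsize=(10, 9))
    gs = fig.add_gridspec(4, 1, height_ratios=[1.2, 1.2, 0.8, 1.6], hspace=0.45)

    ax0 = fig.add_subplot(gs[0])
    mag = np.linalg.norm(recording.a_xyz, axis=1)
    for i, lab in enumerate(("$a_x$", "$a_y$", "$a_z$")):
        ax0.plot(t, recording.a_xyz[:, i], lw=0.6, alpha=0.7, label=lab)
    ax0.plot(t, mag, lw=1.6, color="k", label=r"$\|a\|$")
    ax0.legend(ncol=4, fontsize=8)
    ax0.set_ylabel("acc [g]")

    ax1 = fig.add_subplot(gs[1], sharex=ax0)
    ax1.pcolormesh(scalogram.t_s + t[0], scalogram.freqs_hz,
                   scalogram.coefficients, shading="auto", cmap="magma")
    ax1.set_yscale("log")
    ax1.set_ylabel("freq [Hz]")

    ax2 = fig.add_subplot(gs[2], sharex=ax0)
    starts = np.array([p[0] for p in predictions])
    probs = np.stack([np.asarray(p[1]) for p in predictions])
    centers = t[0] + (starts + 64) / fs
    for j in range(probs.shape[1]):
        ax2.plot(centers, probs[:, j], marker="o", ms=3, lw=0.8, label=str(j))
    ax2.set_ylim(-0.05, 1.05)
    ax2.set_ylabel("p(class)")
    ax2.set_xlabel("time [s]")

    # shaded epoch window: [start, start + 2.56 s)
    start_s = t[0] + epoch.start_index / fs
    for ax in (ax0, ax1, ax2):
        ax.axvspan(start_s, start_s + 128 / fs, color="0.5", alpha=0.3)

    ax3 = fig.add_subplot(gs[3])
    cmap = LinearSegmentedColormap.from_list(
        "relevance", ["#0033ff", "#000000", "#ff2200"])
    vmax = float(np.max(np.abs(relevance.R))) or 1.0
    norm = Normalize(-vmax, vmax)
    tz = start_s + np.arange(128) / fs
    for i in range(4):
        offset = 3.0 * (3 - i)
        ax3.plot(tz, epoch.x[i] + offset, color="0.75", lw=0.7)
        ax3.scatter(tz, epoch.x[i] + offset, c=relevance.R[i], cmap=cmap,
                    norm=norm, s=7)
    ax3.set_yticks([3.0 * (3 - i) for i in range(4)],
                   ["$a_x$", "$a_y$", "$a_z$", r"$\|a\|$"])
    ax3.set_xlabel("time [s]")
    ax3.set_title(f"epoch relevance toward {relevance.target_label!r}")

    fig.savefig(out, dpi=120)
    plt.close(fig)
    return out
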