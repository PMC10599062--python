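"""Averaged power spectra and per-band topographic difference values.

Reproduces the qualitative spectral comparison between the deep-hypnosis
and wakefulness periods of a session: Welch power spectral densities
averaged over labelled intervals, integrated into the seven conventional
EEG bands, and differenced DEEP minus WAKE per channel (µV²). An optional
matplotlib scalp-map renderer sits on top; the numeric table is the
tested product.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import signal as sps

from .io import EEGRecording, LabelTrack, State

__all__ = [
    "FIG_BANDS",
    "interval_psd",
    "band_power",
    "band_power_table",
    "band_power_difference",
    "plot_topomap",
]

#: Conventional band set for the topographic comparison (Hz):
#: delta, theta, alpha, sensorimotor/low beta, beta1, beta2, gamma.
FIG_BANDS: tuple[tuple[float, float], ...] = (
    (1.5, 4.0),
    (4.0, 8.0),
    (8.0, 12.0),
    (12.0, 15.0),
    (15.0, 18.0),
    (18.0, 25.0),
    (25.0, 45.0),
)

_WELCH_SEG_S = 4.0  # Hann windows, 50% overlap — matches the epoch scale


def interval_psd(
    rec: EEGRecording, intervals: list[tuple[float, float]]
) -> tuple[np.ndarray, np.ndarray]:
    """Welch PSD per channel, averaged over the given intervals.

    Returns ``(freqs, psd)`` with ``psd`` of shape (n_channels, n_freqs)
    in µV²/Hz. Each interval is estimated with 4 s Hann segments at 50%
    overlap; interval estimates are combined weighted by their usable
    segment counts. Frequency resolution is 1/4 Hz.

    Raises if no interval is at least one Welch segment long.
    """
    if not intervals:
        raise ValueError("interval list is empty")
    nperseg = int(round(_WELCH_SEG_S * rec.fs))
    psds, weights = [], []
    freqs = None
    for t0, t1 in intervals:
        i0 = int(round((t0 - rec.start_time) * rec.fs))
        i1 = int(round((t1 - rec.start_time) * rec.fs))
        i0, i1 = max(i0, 0), min(i1, rec.n_samples)
        if i1 - i0 < nperseg:
            continue
        freqs, p = sps.welch(
            rec.samples[:, i0:i1],
            fs=rec.fs,
            window="hann",
            nperseg=nperseg,
            noverlap=nperseg // 2,
            axis=1,
        )
        n_segments = 1 + (i1 - i0 - nperseg) // (nperseg // 2)
        psds.append(p)
        weights.append(n_segments)
    if not psds:
        raise ValueError(
            f"no interval reaches the {_WELCH_SEG_S} s PSD segment length"
        )
    w = np.asarray(weights, dtype=float)
    psd = np.tensordot(w / w.sum(), np.stack(psds), axes=1)
    return freqs, psd


def band_power(
    freqs: np.ndarray, psd: np.ndarray, band: tuple[float, float]
) -> np.ndarray:
    """Integrated power (µV²) of each channel over ``band``."""
    lo, hi = band
    mask = (freqs >= lo) & (freqs <= hi)
    if mask.sum() < 2:
        raise ValueError(f"band {band} spans fewer than two frequency bins")
    return np.trapezoid(psd[..., mask], freqs[mask], axis=-1)


def band_power_table(
    rec: EEGRecording,
    intervals: list[tuple[float, float]],
    bands: tuple[tuple[float, float], ...] = FIG_BANDS,
) -> pd.DataFrame:
    """Channel x band table of integrated powers (µV²) over intervals."""
    freqs, psd = interval_psd(rec, intervals)
    cols = {f"{lo:g}-{hi:g}Hz": band_power(freqs, psd, (lo, hi)) for lo, hi in bands}
    return pd.DataFrame(cols, index=rec.montage)


def band_power_difference(
    rec: EEGRecording,
    labels: LabelTrack,
    bands: tuple[tuple[float, float], ...] = FIG_BANDS,
) -> pd.DataFrame:
    """Per channel x band power difference, DEEP minus WAKE (µV²).

    Positive values mean more power in the deep-hypnosis intervals; the
    slow-wave rows are expected positive and posterior alpha negative for
    the default synthetic deepening pattern.
    """
    missing = {State.WAKE, State.DEEP} - labels.states()
    if missing:
        raise ValueError(
            f"label track lacks {sorted(s.value for s in missing)} intervals"
        )
    deep = band_power_table(rec, labels.intervals_for(State.DEEP), bands)
    wake = band_power_table(rec, labels.intervals_for(State.WAKE), bands)
    return deep - wake


# approximate 2-D positions of the 10-20 electrodes (unit head circle)
_POS_1020 = {
    "Fp1": (-0.31, 0.95), "Fp2": (0.31, 0.95),
    "F7": (-0.81, 0.59), "F3": (-0.40, 0.51), "Fz": (0.0, 0.50),
    "F4": (0.40, 0.51), "F8": (0.81, 0.59),
    "T3": (-1.0, 0.0), "C3": (-0.50, 0.0), "Cz": (0.0, 0.0),
    "C4": (0.50, 0.0), "T4": (1.0, 0.0),
    "T5": (-0.81, -0.59), "P3": (-0.40, -0.51), "Pz": (0.0, -0.50),
    "P4": (0.40, -0.51), "T6": (0.81, -0.59),
    "O1": (-0.31, -0.95), "O2": (0.31, -0.95),
}


def plot_topomap(table: pd.DataFrame, out_path=None):
    """Render a row of scalp maps, one per band column of ``table``.

    Thin optional layer over matplotlib; channels without a known 10-20
    position are drawn as an annotated strip instead. Returns the Figure.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from scipy.interpolate import griddata

    known = [ch for ch in table.index if ch in _POS_1020]
    n_bands = table.shape[1]
    fig, axes = plt.subplots(1, n_bands, figsize=(2.2 * n_bands, 2.6))
    axes = np.atleast_1d(axes)
    vmax = np.nanmax(np.abs(table.values)) or 1.0
    grid = np.linspace(-1.1, 1.1, 101)
    gx, gy = np.meshgrid(grid, grid)
    for ax, col in zip(axes, table.columns):
        if len(known) >= 4:
            pts = np.array([_POS_1020[ch] for ch in known])
            vals = table.loc[known, col].values
            img = griddata(pts, vals, (gx, gy), method="cubic")
            img[np.hypot(gx, gy) > 1.05] = np.nan
            ax.imshow(
                img, extent=[-1.1, 1.1, -1.1, 1.1], origin="lower",
                cmap="RdBu_r", vmin=-vmax, vmax=vmax,
            )
            ax.scatter(pts[:, 0], pts[:, 1], s=4, c="k")
        else:
            ax.bar(range(len(table.index)), table[col].values)
        ax.set_title(col, fontsize=8)
        ax.set_xticks([])
        ax.set_yticks([])
    fig.suptitle("band power, DEEP minus WAKE (µV²)", fontsize=10)
    fig.tight_layout()
    if out_path is not None:
        fig.savefig(out_path, dpi=120)
    return fig
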