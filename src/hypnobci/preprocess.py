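"""Band-pass filtering and overlapping epoch extraction.

Filtering is a 4th-order Butterworth band-pass. Offline mode applies it
forward-backward (zero phase, effective order 8); streaming mode applies a
single causal pass whose group delay is roughly ``2/(pi * band_low)``
seconds at the low band edge — the price of causality in real-time use.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .io import EEGRecording, LabelTrack, State

__all__ = ["EpochSet", "bandpass", "design_bandpass", "epoch", "reject_artifacts"]


def design_bandpass(band: tuple[float, float], fs: float, order: int = 4) -> np.ndarray:
    """Second-order sections of the Butterworth band-pass used throughout."""
    low, high = band
    if not (0 < low < high < fs / 2):
        raise ValueError(
            f"band ({low}, {high}) Hz must satisfy 0 < low < high < fs/2 = {fs / 2}"
        )
    return signal.butter(order, (low, high), btype="bandpass", fs=fs, output="sos")


def bandpass(
    rec: EEGRecording, band: tuple[float, float], mode: str = "offline"
) -> EEGRecording:
    """Band-pass filter every channel.

    Parameters
    ----------
    mode : {"offline", "streaming"}
        ``offline`` is zero-phase (forward-backward); ``streaming`` is a
        single causal pass, suitable for sample-by-sample replay.
    """
    sos = design_bandpass(band, rec.fs)
    if mode == "offline":
        out = signal.sosfiltfilt(sos, rec.samples, axis=1)
    elif mode == "streaming":
        out = signal.sosfilt(sos, rec.samples, axis=1)
    else:
        raise ValueError(f"unknown filter mode {mode!r}")
    return rec.copy_with(samples=np.ascontiguousarray(out))


@dataclass
class EpochSet:
    """Overlapping fixed-length windows cut from one recording.

    ``windows[i]`` is the exact sample slice starting at
    ``start_indices[i]``; ``labels[i]`` is a :class:`State` when the
    window lies wholly inside one labelled interval, else None.
    """

    windows: np.ndarray  # (n_epochs, n_channels, n_window_samples)
    t_centers: np.ndarray  # seconds
    start_indices: np.ndarray
    epoch_length: float
    stride: float
    fs: float
    labels: list[State | None] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.labels) == 0:
            self.labels = [None] * len(self.windows)
        if len(self.labels) != len(self.windows):
            raise ValueError("labels length must match epoch count")
        if np.any(np.diff(self.t_centers) <= 0):
            raise ValueError("epoch centers must be strictly increasing")

    def __len__(self) -> int:
        return len(self.windows)

    def indices_of(self, state: State) -> np.ndarray:
        state = State(state)
        return np.array(
            [i for i, s in enumerate(self.labels) if s is state], dtype=int
        )

    def class_windows(self, state: State) -> np.ndarray:
        return self.windows[self.indices_of(state)]

    def labelled_indices(self) -> np.ndarray:
        return np.array([i for i, s in enumerate(self.labels) if s is not None], int)


def epoch(
    rec: EEGRecording,
    epoch_length: float,
    stride: float,
    labels: LabelTrack | None = None,
) -> EpochSet:
    """Cut overlapping epochs of ``epoch_length`` s every ``stride`` s.

    The epoch count is ``floor((duration - epoch_length)/stride) + 1``.
    With a label track given, an epoch fully contained in one WAKE or DEEP
    interval inherits that state; epochs straddling a boundary or covering
    unlabelled time stay unlabelled.
    """
    if epoch_length <= 0 or stride <= 0:
        raise ValueError("epoch_length and stride must be positive")
    n_len = int(round(epoch_length * rec.fs))
    if n_len > rec.n_samples:
        raise ValueError(
            f"epoch of {epoch_length} s exceeds the {rec.duration:.3f} s recording"
        )
    n_epochs = int(np.floor((rec.duration - epoch_length) / stride + 1e-9)) + 1
    starts = np.array([int(round(i * stride * rec.fs)) for i in range(n_epochs)])
    starts = starts[starts + n_len <= rec.n_samples]

    windows = np.stack([rec.samples[:, s : s + n_len] for s in starts])
    t0 = starts / rec.fs + rec.start_time
    t_centers = t0 + epoch_length / 2.0

    ep_labels: list[State | None] = [None] * len(starts)
    if labels is not None:
        for i, s in enumerate(starts):
            a = s / rec.fs + rec.start_time
            ep_labels[i] = labels.label_for_window(a, a + epoch_length)

    return EpochSet(
        windows=windows,
        t_centers=t_centers,
        start_indices=starts,
        epoch_length=epoch_length,
        stride=stride,
        fs=rec.fs,
        labels=ep_labels,
    )


def reject_artifacts(epochs: EpochSet, amplitude_uv: float) -> EpochSet:
    """Drop epochs whose peak absolute amplitude exceeds ``amplitude_uv``.

    Off by default in every pipeline; provided for recordings with burst
    artefacts. Returns a new EpochSet with the offending epochs removed.
    """
    keep = np.array(
        [np.max(np.abs(w)) <= amplitude_uv for w in epochs.windows], dtype=bool
    )
    return EpochSet(
        windows=epochs.windows[keep],
        t_centers=epochs.t_centers[keep],
        start_indices=epochs.start_indices[keep],
        epoch_length=epochs.epoch_length,
        stride=epochs.stride,
        fs=epochs.fs,
        labels=[l for l, k in zip(epochs.labels, keep) if k],
    )
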