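"""Probability curves: streamed Predictive and post-hoc Native traces.

A session is replayed through a trained model as a stream of overlapping
epochs; each epoch yields the Probability Value P(DEEP) and the trace is
smoothed with a trailing moving average over ``smoothing_epochs`` windows
(default 50 epochs of 4 s emitted every 0.5 s, i.e. a ~24.5 s trailing
window). Smoothing is "immediate": the first epochs average whatever is
available, so the curve starts with the first epoch instead of after a
warm-up gap.

The Predictive curve applies a model trained on the calibration (first)
session to a later session; the Native curve trains an auxiliary model on
the session's own labels and rescoring the same recording gives the
best-case reference trace. Both use the causal (streaming) band-pass so
each value depends only on samples up to that epoch's end.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import EEGRecording, LabelTrack, RunConfig
from .models import TrainedModel, features_from_windows, probability_value
from .preprocess import bandpass, epoch

__all__ = [
    "ProbabilityCurve",
    "smooth",
    "predictive_curve",
    "native_curve",
    "summarize_curve",
]


def smooth(raw: np.ndarray, k: int) -> np.ndarray:
    """Trailing moving average over up to ``k`` points.

    ``out[i]`` is the mean of the last ``min(k, i + 1)`` raw values, so
    output exists from the first point onward. ``k = 1`` is the identity.
    """
    if k < 1:
        raise ValueError("smoothing window must be >= 1 epoch")
    raw = np.asarray(raw, dtype=float)
    if raw.size == 0 or k == 1:
        return raw.copy()
    csum = np.concatenate([[0.0], np.cumsum(raw)])
    n = raw.size
    idx = np.arange(1, n + 1)
    lo = np.maximum(idx - k, 0)
    return (csum[idx] - csum[lo]) / (idx - lo)


@dataclass
class ProbabilityCurve:
    """P(DEEP) per epoch over a session, raw and smoothed, in [0, 1]."""

    times: np.ndarray  # epoch centers, seconds
    raw_values: np.ndarray
    smoothed_values: np.ndarray
    smoothing_epochs: int

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.raw_values = np.asarray(self.raw_values, dtype=float)
        self.smoothed_values = np.asarray(self.smoothed_values, dtype=float)
        if not (
            len(self.times) == len(self.raw_values) == len(self.smoothed_values)
        ):
            raise ValueError("curve arrays must share one length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("curve times must be strictly increasing")
        for v in (self.raw_values, self.smoothed_values):
            if v.size and (v.min() < -1e-12 or v.max() > 1 + 1e-12):
                raise ValueError("probability values must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def stride(self) -> float:
        return float(np.median(np.diff(self.times))) if len(self.times) > 1 else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.times,
                "raw": self.raw_values,
                "smoothed": self.smoothed_values,
            }
        )


def predictive_curve(
    model: TrainedModel, rec: EEGRecording, config: RunConfig | None = None
) -> ProbabilityCurve:
    """Stream a session through a trained model in simulated real time.

    The recording is filtered causally and cut into overlapping epochs at
    the configured stride; every Probability Value uses only samples up
    to its epoch's end, and smoothing is the online trailing average, so
    the curve equals what a live replay (chunk = stride) would display.
    """
    cfg = config or model.config
    model.check_compatible(rec.fs, rec.montage)
    cfg.validate_for_fs(rec.fs)
    filtered = bandpass(rec, model.config.band, mode="streaming")
    eps = epoch(filtered, cfg.epoch_length, cfg.epoch_stride)
    feats = features_from_windows(model.csp, eps.windows, cfg.drift_offset)
    raw = np.asarray(probability_value(model.lda, feats))
    return ProbabilityCurve(
        times=eps.t_centers,
        raw_values=raw,
        smoothed_values=smooth(raw, cfg.smoothing_epochs),
        smoothing_epochs=cfg.smoothing_epochs,
    )


def native_curve(
    rec: EEGRecording, labels: LabelTrack, config: RunConfig
) -> tuple[ProbabilityCurve, TrainedModel]:
    """Train an auxiliary model on a session's own labels and rescore it.

    The returned curve is the best-case trace the session admits; the
    auxiliary model is returned alongside for persistence or per-session
    cross-validation.
    """
    from .evaluation import train_model  # local import avoids a cycle

    aux = train_model(rec, labels, config)
    return predictive_curve(aux, rec, config), aux


def summarize_curve(
    curve: ProbabilityCurve, deep_threshold: float = 0.7
) -> tuple[list[tuple[float, float]], float]:
    """Maximal intervals where the smoothed curve is at/above threshold.

    Returns half-open ``[t_start, t_end)`` intervals (epoch-center times,
    extended one stride past the last qualifying epoch) and the percent
    of curve time they cover. The 0.7 default is the heuristic reading
    level for "consistently deep" stretches; it depends on the smoothing
    settings and is exposed in the run configuration.
    """
    if len(curve) == 0:
        raise ValueError("empty curve")
    above = curve.smoothed_values >= deep_threshold
    stride = curve.stride or 1.0
    intervals: list[tuple[float, float]] = []
    start = None
    for t, flag in zip(curve.times, above):
        if flag and start is None:
            start = t
        elif not flag and start is not None:
            intervals.append((start, prev + stride))
            start = None
        prev = t
    if start is not None:
        intervals.append((start, curve.times[-1] + stride))

    total = sum(t1 - t0 for t0, t1 in intervals)
    span = curve.times[-1] + stride - curve.times[0]
    occupancy = 100.0 * total / span if span > 0 else 0.0
    return intervals, occupancy
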