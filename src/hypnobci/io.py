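"""EDF input/output, WAKE/DEEP state-label sidecars and run configuration.

Signals are held as channels x time matrices in microvolts (µV). All times
are seconds from recording start; label intervals are half-open
``[t_start, t_end)``.

The EDF layer implements the plain 16-bit European Data Format: a
fixed-width ASCII header followed by little-endian int16 data records,
with the usual linear mapping between digital and physical values. Files
written here are readable by standard EDF tools. Because a recording's
length is rarely an exact multiple of the 1 s record duration, the final
record is zero-padded and the true sample count is stored in the header's
free-text reserved field (``NSAMP=<n>``); readers unaware of the tag simply
see trailing zeros.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
import numpy as np
import yaml

__all__ = [
    "State",
    "EEGRecording",
    "LabelTrack",
    "RunConfig",
    "read_edf",
    "write_edf",
    "read_labels",
    "write_labels",
    "PAPER_BANDS",
]

#: The four candidate training bands (Hz) evaluated for model accuracy.
PAPER_BANDS: tuple[tuple[float, float], ...] = (
    (1.5, 45.0),
    (1.5, 8.0),
    (1.5, 14.0),
    (4.0, 15.0),
)


class State(str, enum.Enum):
    """The two labelled extremes of the hypnotic-depth continuum."""

    WAKE = "WAKE"
    DEEP = "DEEP"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass
class EEGRecording:
    """Multichannel EEG signal.

    Parameters
    ----------
    samples : ndarray, shape (n_channels, n_samples)
        Signal in µV.
    fs : float
        Sampling rate in Hz.
    montage : sequence of str
        Ordered channel labels, one per row of ``samples``.
    start_time : float
        Offset of the first sample, seconds (default 0).
    """

    samples: np.ndarray
    fs: float
    montage: list[str]
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.montage = list(self.montage)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D channels x time array")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if len(self.montage) != self.samples.shape[0]:
            raise ValueError(
                f"montage has {len(self.montage)} labels but samples has "
                f"{self.samples.shape[0]} channels"
            )
        if len(set(self.montage)) != len(self.montage):
            raise ValueError("montage labels must be unique")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples contain non-finite values")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs

    def copy_with(self, **kw) -> "EEGRecording":
        return replace(self, **kw)


@dataclass
class LabelTrack:
    """Non-overlapping, half-open WAKE/DEEP intervals in seconds."""

    intervals: list[tuple[float, float, State]] = field(default_factory=list)

    def __post_init__(self) -> None:
        norm = []
        for t0, t1, s in self.intervals:
            s = State(s)
            if not (t0 < t1):
                raise ValueError(f"interval ({t0}, {t1}) must satisfy t_start < t_end")
            norm.append((float(t0), float(t1), s))
        norm.sort(key=lambda iv: iv[0])
        for (a0, a1, _), (b0, _b1, _s) in zip(norm, norm[1:]):
            if b0 < a1:
                raise ValueError(
                    f"intervals overlap: [{a0}, {a1}) and [{b0}, {_b1})"
                )
        self.intervals = norm

    def __len__(self) -> int:
        return len(self.intervals)

    def states(self) -> set[State]:
        return {s for _, _, s in self.intervals}

    def intervals_for(self, state: State) -> list[tuple[float, float]]:
        state = State(state)
        return [(t0, t1) for t0, t1, s in self.intervals if s is state]

    def state_at(self, t: float) -> State | None:
        """State covering time ``t``, or None for unlabelled time."""
        for t0, t1, s in self.intervals:
            if t0 <= t < t1:
                return s
        return None

    def label_for_window(self, t0: float, t1: float) -> State | None:
        """Label of a window fully inside one interval, else None.

        Windows straddling an interval boundary or touching unlabelled
        time get no label (mixed-state windows are never trained on).
        """
        for a0, a1, s in self.intervals:
            if a0 <= t0 and t1 <= a1:
                return s
        return None


# --------------------------------------------------------------------------
# Run configuration
# --------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Configuration of one processing run.

    Defaults follow the study setup: 4 s analysis epochs emitted every
    0.5 s, probability smoothed over 50 epochs, candidate training band
    1.5-14 Hz, decision threshold 0.5.
    """

    band: tuple[float, float] = (1.5, 14.0)
    epoch_length: float = 4.0
    epoch_stride: float = 0.5
    smoothing_epochs: int = 50
    csp_pairs: int = 3
    drift_offset: float = 0.0
    decision_threshold: float = 0.5
    seed: int = 0
    filter_mode: str = "offline"  # offline (zero-phase) | streaming (causal)
    partition_mode: str = "blocked"  # blocked | shuffled 10-fold CV

    def __post_init__(self) -> None:
        self.band = (float(self.band[0]), float(self.band[1]))
        if not (0 < self.band[0] < self.band[1]):
            raise ValueError(f"invalid band {self.band}")
        if self.epoch_length <= 0 or self.epoch_stride <= 0:
            raise ValueError("epoch_length and epoch_stride must be positive")
        if self.smoothing_epochs < 1:
            raise ValueError("smoothing_epochs must be >= 1")
        if not (0 < self.decision_threshold < 1):
            raise ValueError("decision_threshold must lie in (0, 1)")
        if self.csp_pairs < 1:
            raise ValueError("csp_pairs must be >= 1")
        if self.filter_mode not in ("offline", "streaming"):
            raise ValueError(f"unknown filter_mode {self.filter_mode!r}")
        if self.partition_mode not in ("blocked", "shuffled"):
            raise ValueError(f"unknown partition_mode {self.partition_mode!r}")

    def validate_for_fs(self, fs: float) -> None:
        if not self.band[1] < fs / 2:
            raise ValueError(
                f"band {self.band} exceeds the Nyquist frequency {fs / 2} Hz"
            )

    def to_dict(self) -> dict:
        return {
            "band": list(self.band),
            "epoch_length": self.epoch_length,
            "epoch_stride": self.epoch_stride,
            "smoothing_epochs": self.smoothing_epochs,
            "csp_pairs": self.csp_pairs,
            "drift_offset": self.drift_offset,
            "decision_threshold": self.decision_threshold,
            "seed": self.seed,
            "filter_mode": self.filter_mode,
            "partition_mode": self.partition_mode,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "band" in d:
            d["band"] = tuple(d["band"])
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


# --------------------------------------------------------------------------
# EDF read / write
# --------------------------------------------------------------------------

_DIG_MIN, _DIG_MAX = -32768, 32767


def _ascii_field(text: str, width: int) -> bytes:
    b = text.encode("ascii")
    if len(b) > width:
        raise ValueError(f"EDF header field {text!r} exceeds {width} bytes")
    return b.ljust(width)


def _fmt_number(x: float, width: int = 8) -> str:
    """Shortest decimal representation of ``x`` fitting an EDF field."""
    for prec in range(7, -1, -1):
        s = f"{x:.{prec}g}"
        if len(s) <= width and "e" not in s and "E" not in s:
            return s
    s = f"{x:.1e}"
    if len(s) > width:
        raise ValueError(f"cannot represent {x} in {width} EDF header bytes")
    return s


def write_edf(rec: EEGRecording, path: str | Path) -> None:
    """Write a recording as a plain 16-bit EDF file.

    The physical range of each channel is chosen to cover its signal with
    a small margin, so the quantization step adapts to the data. Signals
    with non-finite values are rejected rather than clipped.
    """
    if rec.n_samples == 0 or rec.n_channels == 0:
        raise ValueError("cannot write an empty recording")
    if not np.all(np.isfinite(rec.samples)):
        raise ValueError("recording contains non-finite samples")
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError(
            f"EDF writer requires an integer sampling rate per 1 s record, got {fs}"
        )
    spr = int(round(fs))  # samples per 1 s data record
    n_ch, n_samp = rec.n_channels, rec.n_samples
    n_records = math.ceil(n_samp / spr)

    # per-channel physical range with 0.1% headroom; degenerate flat
    # channels get a unit range so the mapping stays invertible
    pmaxs, pmins, scaled = [], [], []
    for ch in range(n_ch):
        x = rec.samples[ch]
        amp = float(np.max(np.abs(x)))
        pmax = amp * 1.001 if amp > 0 else 1.0
        # 7 chars so the negated value also fits its 8-byte header field
        pmax = float(_fmt_number(pmax, width=7))
        if pmax < amp:
            raise ValueError("physical range does not cover the signal")
        pmin = -pmax
        gain = (_DIG_MAX - _DIG_MIN) / (pmax - pmin)
        dig = np.round((x - pmin) * gain + _DIG_MIN)
        if dig.min() < _DIG_MIN or dig.max() > _DIG_MAX:
            raise ValueError(
                f"channel {rec.montage[ch]!r} exceeds the representable EDF range"
            )
        pad = n_records * spr - n_samp
        dig_pad = np.concatenate([dig, np.full(pad, round(-pmin * gain + _DIG_MIN))])
        pmaxs.append(pmax)
        pmins.append(pmin)
        scaled.append(dig_pad.astype("<i2"))

    header = b""
    header += _ascii_field("0", 8)  # version
    header += _ascii_field("X X X X", 80)  # patient id (anonymous)
    header += _ascii_field("Startdate 01-JAN-2000", 80)  # recording id
    header += _ascii_field("01.01.00", 8)
    header += _ascii_field("00.00.00", 8)
    header += _ascii_field(str(256 * (n_ch + 1)), 8)
    header += _ascii_field(f"NSAMP={n_samp}", 44)
    header += _ascii_field(str(n_records), 8)
    header += _ascii_field("1", 8)  # record duration, seconds
    header += _ascii_field(str(n_ch), 4)
    for label in rec.montage:
        header += _ascii_field(label[:16], 16)
    header += b"".join(_ascii_field("", 80) for _ in range(n_ch))  # transducer
    header += b"".join(_ascii_field("uV", 8) for _ in range(n_ch))
    header += b"".join(_ascii_field(_fmt_number(p), 8) for p in pmins)
    header += b"".join(_ascii_field(_fmt_number(p), 8) for p in pmaxs)
    header += b"".join(_ascii_field(str(_DIG_MIN), 8) for _ in range(n_ch))
    header += b"".join(_ascii_field(str(_DIG_MAX), 8) for _ in range(n_ch))
    header += b"".join(_ascii_field("", 80) for _ in range(n_ch))  # prefilter
    header += b"".join(_ascii_field(str(spr), 8) for _ in range(n_ch))
    header += b"".join(_ascii_field("", 32) for _ in range(n_ch))  # reserved

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_records):
            for ch in range(n_ch):
                fh.write(scaled[ch][r * spr : (r + 1) * spr].tobytes())


def read_edf(path: str | Path) -> EEGRecording:
    """Read a 16-bit EDF file into an :class:`EEGRecording` (µV).

    All channels must share one sampling rate; mixed-rate files are
    rejected with the offending channels named.
    """
    path = Path(path)
    with open(path, "rb") as fh:
        head = fh.read(256)
        if len(head) < 256:
            raise ValueError(f"{path}: truncated EDF header")

        def _f(off: int, width: int) -> str:
            return head[off : off + width].decode("ascii", "replace").strip()

        try:
            n_records = int(_f(236, 8))
            record_dur = float(_f(244, 8))
            n_ch = int(_f(252, 4))
        except ValueError as exc:
            raise ValueError(f"{path}: malformed EDF header ({exc})") from None
        reserved = _f(192, 44)

        sig = fh.read(256 * n_ch)
        if len(sig) < 256 * n_ch:
            raise ValueError(f"{path}: truncated EDF signal headers")

        def _sf(block: int, width: int, ch: int) -> str:
            off = block + ch * width
            return sig[off : off + width].decode("ascii", "replace").strip()

        labels = [_sf(0, 16, c) for c in range(n_ch)]
        base = 16 * n_ch + 80 * n_ch + 8 * n_ch
        try:
            pmin = [float(_sf(base, 8, c)) for c in range(n_ch)]
            pmax = [float(_sf(base + 8 * n_ch, 8, c)) for c in range(n_ch)]
            dmin = [int(_sf(base + 16 * n_ch, 8, c)) for c in range(n_ch)]
            dmax = [int(_sf(base + 24 * n_ch, 8, c)) for c in range(n_ch)]
            spr = [
                int(_sf(base + 32 * n_ch + 80 * n_ch, 8, c)) for c in range(n_ch)
            ]
        except ValueError as exc:
            raise ValueError(f"{path}: malformed EDF signal header ({exc})") from None

        if len(set(spr)) > 1:
            rates = sorted(set(spr))
            names = {
                r: [labels[c] for c in range(n_ch) if spr[c] == r] for r in rates
            }
            raise ValueError(
                f"{path}: mixed sampling rates across channels: "
                + "; ".join(f"{r / record_dur:g} Hz: {names[r]}" for r in rates)
            )
        spr0 = spr[0]
        fs = spr0 / record_dur

        raw = np.frombuffer(fh.read(), dtype="<i2")
    expected = n_records * n_ch * spr0
    if raw.size < expected:
        raise ValueError(f"{path}: truncated EDF data section")
    raw = raw[:expected].reshape(n_records, n_ch, spr0)

    samples = np.empty((n_ch, n_records * spr0))
    for c in range(n_ch):
        gain = (pmax[c] - pmin[c]) / (dmax[c] - dmin[c])
        samples[c] = (raw[:, c, :].reshape(-1).astype(float) - dmin[c]) * gain + pmin[c]

    if reserved.startswith("NSAMP="):
        try:
            n_true = int(reserved[6:])
        except ValueError:
            n_true = samples.shape[1]
        if 0 < n_true <= samples.shape[1]:
            samples = samples[:, :n_true]

    return EEGRecording(samples=samples, fs=fs, montage=labels)


# --------------------------------------------------------------------------
# Label sidecar (TSV)
# --------------------------------------------------------------------------


def write_labels(track: LabelTrack, path: str | Path) -> None:
    """Write a label track as ``t_start<TAB>t_end<TAB>STATE`` lines."""
    with open(path, "w") as fh:
        for t0, t1, s in track.intervals:
            fh.write(f"{t0:.10g}\t{t1:.10g}\t{s.value}\n")


def read_labels(path: str | Path) -> LabelTrack:
    """Read a TSV label sidecar; blank lines and ``#`` comments ignored."""
    intervals: list[tuple[float, float, State]] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) != 3:
                raise ValueError(f"{path}:{ln}: expected 't_start t_end STATE'")
            t0_s, t1_s, tok = parts
            try:
                t0, t1 = float(t0_s), float(t1_s)
            except ValueError:
                raise ValueError(f"{path}:{ln}: non-numeric interval bounds") from None
            try:
                state = State(tok)
            except ValueError:
                raise ValueError(
                    f"{path}:{ln}: unknown state token {tok!r} "
                    f"(expected WAKE or DEEP)"
                ) from None
            intervals.append((t0, t1, state))
    return LabelTrack(intervals=intervals)
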