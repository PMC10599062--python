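"""Synthetic two-state EEG with known spectral structure and ground truth.

No EEG recordings from hypnosis sessions are publicly deposited, so every
downstream stage (filtering, CSP, LDA, cross-validation, probability
curves) is exercised on simulated multichannel EEG whose deep-state
signature is a controlled per-channel, per-band power shift over a 1/f
background — the qualitative pattern reported for deep hypnosis (slow-wave
increase, attenuated posterior alpha), with effect sizes chosen for clear
separability rather than physiological fidelity.

Construction
------------
Each gain band contributes one unit-variance band-limited Gaussian noise
process per channel, shared between the two states and scaled by the
respective per-state channel gain; a time-varying coefficient ``c(t)`` in
[0, 1] crossfades WAKE (0) into DEEP (1). Sharing the underlying noise
makes the DEEP/WAKE band-power ratio equal the squared gain ratio by
construction and makes the WAKE-DEEP continuum exactly amplitude-linear.
A 1/f^alpha background (small relative to the rhythm components) is added
per channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import signal as sps

from .io import EEGRecording, LabelTrack, State

__all__ = [
    "StateSignature",
    "Segment",
    "SessionScript",
    "STANDARD_1020",
    "default_signatures",
    "generate_session",
    "add_artifact_bursts",
]

#: 19-channel 10-20 montage in conventional order.
STANDARD_1020: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T3", "C3", "Cz", "C4", "T4",
    "T5", "P3", "Pz", "P4", "T6",
    "O1", "O2",
)

_POSTERIOR = {"O1", "O2", "P3", "Pz", "P4", "T5", "T6"}
_OCCIPITAL = {"O1", "O2"}
_FRONTAL = {"Fp1", "Fp2", "F3", "Fz", "F4", "F7", "F8"}


@dataclass
class StateSignature:
    """Spectral fingerprint of one state.

    ``band_gains`` maps each frequency band (Hz) to per-channel linear
    amplitude multipliers; ``background_exponent`` is the 1/f spectral
    slope of the broadband floor.
    """

    state_name: State
    band_gains: list[tuple[tuple[float, float], np.ndarray]]
    background_exponent: float = 1.0
    background_scale: float = 0.25  # amplitude of the 1/f floor, relative units

    def __post_init__(self) -> None:
        self.state_name = State(self.state_name)
        norm = []
        n_ch = None
        for (lo, hi), gains in self.band_gains:
            gains = np.atleast_1d(np.asarray(gains, dtype=float))
            if n_ch is None:
                n_ch = gains.size
            elif gains.size != n_ch:
                raise ValueError("all bands must carry one gain per channel")
            if np.any(gains < 0):
                raise ValueError("gains must be non-negative")
            if not (0 < lo < hi):
                raise ValueError(f"invalid band ({lo}, {hi})")
            norm.append(((float(lo), float(hi)), gains))
        self.band_gains = norm

    @property
    def n_channels(self) -> int:
        return self.band_gains[0][1].size if self.band_gains else 0

    @property
    def bands(self) -> list[tuple[float, float]]:
        return [b for b, _ in self.band_gains]


@dataclass
class Segment:
    """One scripted stretch of a session.

    ``state`` is WAKE, DEEP or "MIX"; for MIX, ``mix`` gives the DEEP
    coefficient profile over the segment, either a callable of normalized
    time u in [0, 1] or a (start, end) pair interpreted as a linear ramp.
    """

    duration: float
    state: str  # "WAKE" | "DEEP" | "MIX"
    mix: tuple[float, float] | Callable[[np.ndarray], np.ndarray] | None = None

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("segment duration must be positive")
        self.state = str(self.state).upper()
        if self.state not in ("WAKE", "DEEP", "MIX"):
            raise ValueError(f"unknown segment state {self.state!r}")
        if self.state == "MIX" and self.mix is None:
            self.mix = (0.0, 1.0)

    def coefficients(self, n: int) -> np.ndarray:
        """DEEP-mixing coefficient for each of the segment's n samples."""
        if self.state == "WAKE":
            return np.zeros(n)
        if self.state == "DEEP":
            return np.ones(n)
        u = np.arange(n) / max(n - 1, 1)
        if callable(self.mix):
            c = np.asarray(self.mix(u), dtype=float)
        else:
            a, b = self.mix
            c = a + (b - a) * u
        if np.any((c < -1e-9) | (c > 1 + 1e-9)):
            raise ValueError("mix coefficients must lie in [0, 1]")
        return np.clip(c, 0.0, 1.0)


@dataclass
class SessionScript:
    """Ordered segments plus acquisition parameters for one session."""

    segments: list[Segment]
    fs: float = 250.0
    montage: Sequence[str] = STANDARD_1020
    seed: int = 0

    def __post_init__(self) -> None:
        self.montage = list(self.montage)
        if not self.segments:
            raise ValueError("script must contain at least one segment")
        if len(set(self.montage)) != len(self.montage):
            raise ValueError("montage labels must be unique")
        if not self.montage:
            raise ValueError("montage must be non-empty")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def duration(self) -> float:
        return sum(s.duration for s in self.segments)

    def label_track(self) -> LabelTrack:
        """Ground-truth labels: pure-state segments only, MIX unlabelled."""
        intervals = []
        t = 0.0
        for seg in self.segments:
            if seg.state in ("WAKE", "DEEP"):
                intervals.append((t, t + seg.duration, State(seg.state)))
            t += seg.duration
        return LabelTrack(intervals=intervals)

    @classmethod
    def from_dict(cls, d: dict) -> "SessionScript":
        montage = d.get("montage", "standard-19")
        if isinstance(montage, str):
            if montage not in ("standard-19", "10-20"):
                raise ValueError(f"unknown montage shorthand {montage!r}")
            montage = STANDARD_1020
        segs = []
        for s in d.get("segments", []):
            segs.append(
                Segment(
                    duration=float(s["duration"]),
                    state=s["state"],
                    mix=tuple(s["ramp"]) if "ramp" in s else None,
                )
            )
        return cls(
            segments=segs,
            fs=float(d.get("fs", 250.0)),
            montage=montage,
            seed=int(d.get("seed", 0)),
        )


def default_signatures(
    montage: Sequence[str],
) -> tuple[StateSignature, StateSignature]:
    """WAKE and DEEP signatures over delta/theta/alpha for a montage.

    WAKE carries a posterior-dominant alpha rhythm over a weak slow-wave
    floor; DEEP shows the canonical deepening pattern: elevated delta
    (frontally accented) and theta with attenuated alpha. Gains are
    synthetic conventions chosen for clear class separability, not
    measured effect sizes.
    """
    montage = list(montage)
    if not montage:
        raise ValueError("montage must be non-empty")
    n = len(montage)

    def per_channel(base: float, boost: dict[frozenset, float] | None = None):
        g = np.full(n, base)
        if boost:
            for names, val in boost.items():
                for i, ch in enumerate(montage):
                    if ch in names:
                        g[i] = val
        return g

    delta, theta, alpha = (1.5, 4.0), (4.0, 8.0), (8.0, 12.0)

    wake = StateSignature(
        state_name=State.WAKE,
        band_gains=[
            (delta, per_channel(0.6)),
            (theta, per_channel(0.6)),
            (alpha, per_channel(
                0.8,
                {frozenset(_OCCIPITAL): 2.0, frozenset(_POSTERIOR - _OCCIPITAL): 1.6},
            )),
        ],
    )
    deep = StateSignature(
        state_name=State.DEEP,
        band_gains=[
            (delta, per_channel(1.6, {frozenset(_FRONTAL): 2.0})),
            (theta, per_channel(1.8)),
            (alpha, per_channel(0.45)),
        ],
    )
    return wake, deep


def _band_noise(
    rng: np.random.Generator, band: tuple[float, float], n: int, fs: float
) -> np.ndarray:
    """Unit-variance band-limited Gaussian noise of length n."""
    white = rng.standard_normal(n)
    sos = sps.butter(4, band, btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, white)
    sd = x.std()
    if sd == 0:
        raise ValueError(f"degenerate band {band} at fs={fs}")
    return x / sd


def generate_session(
    script: SessionScript,
    wake: StateSignature,
    deep: StateSignature,
    amplitude_uv: float = 10.0,
    mixing_matrix: np.ndarray | None = None,
) -> tuple[EEGRecording, LabelTrack]:
    """Simulate one session and its ground-truth label track.

    Channels are statistically independent unless ``mixing_matrix`` (an
    n_channels x n_channels linear mixing emulating volume conduction) is
    given. Identical (script, signatures) with the same seed reproduce the
    recording bit-exactly.
    """
    n_ch = len(script.montage)
    if wake.n_channels != n_ch or deep.n_channels != n_ch:
        raise ValueError(
            f"signature channel count (WAKE {wake.n_channels}, DEEP "
            f"{deep.n_channels}) must match the {n_ch}-channel montage"
        )
    if wake.bands != deep.bands:
        raise ValueError("WAKE and DEEP signatures must enumerate the same bands")
    for lo, hi in wake.bands:
        if hi >= script.fs / 2:
            raise ValueError(f"band ({lo}, {hi}) exceeds Nyquist {script.fs / 2}")

    n = int(round(script.duration * script.fs))
    if n == 0:
        raise ValueError("script has zero duration")
    rng = np.random.default_rng(script.seed)

    # global DEEP coefficient c(t)
    c = np.empty(n)
    pos = 0
    for seg in script.segments:
        m = int(round(seg.duration * script.fs))
        m = min(m, n - pos)
        c[pos : pos + m] = seg.coefficients(m)
        pos += m
    c[pos:] = c[pos - 1] if pos else 0.0

    x = np.zeros((n_ch, n))
    for (band, g_wake), (_, g_deep) in zip(wake.band_gains, deep.band_gains):
        for ch in range(n_ch):
            noise = _band_noise(rng, band, n, script.fs)
            gain_t = (1.0 - c) * g_wake[ch] + c * g_deep[ch]
            x[ch] += gain_t * noise

    for ch in range(n_ch):
        seed_white = rng.standard_normal(n)
        bg_w = _shaped(seed_white, wake.background_exponent) * wake.background_scale
        if deep.background_exponent == wake.background_exponent:
            bg_d = bg_w * (deep.background_scale / wake.background_scale)
        else:
            bg_d = (
                _shaped(seed_white, deep.background_exponent) * deep.background_scale
            )
        x[ch] += (1.0 - c) * bg_w + c * bg_d

    if mixing_matrix is not None:
        mixing_matrix = np.asarray(mixing_matrix, dtype=float)
        if mixing_matrix.shape != (n_ch, n_ch):
            raise ValueError("mixing_matrix must be n_channels x n_channels")
        x = mixing_matrix @ x

    rec = EEGRecording(
        samples=x * amplitude_uv, fs=script.fs, montage=script.montage
    )
    return rec, script.label_track()


def _shaped(white: np.ndarray, alpha: float) -> np.ndarray:
    """Shape an existing white-noise draw to unit-variance 1/f^alpha."""
    n = white.size
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    shape = np.ones_like(f)
    shape[1:] = f[1:] ** (-alpha / 2.0)
    shape[0] = 0.0
    x = np.fft.irfft(spec * shape, n=n)
    return x / x.std()


def add_artifact_bursts(
    rec: EEGRecording,
    rate_per_min: float = 2.0,
    amplitude_uv: float = 150.0,
    duration_s: float = 0.3,
    seed: int = 0,
) -> EEGRecording:
    """Inject broadband high-amplitude bursts (crude movement artefacts).

    A convenience for drift/robustness experiments; makes no claim of
    mimicking real myographic activity.
    """
    rng = np.random.default_rng(seed)
    out = rec.samples.copy()
    n_bursts = rng.poisson(rate_per_min * rec.duration / 60.0)
    m = int(round(duration_s * rec.fs))
    for _ in range(n_bursts):
        start = rng.integers(0, max(rec.n_samples - m, 1))
        ch = rng.integers(0, rec.n_channels)
        burst = rng.standard_normal(m) * amplitude_uv
        burst *= np.hanning(m)
        out[ch, start : start + m] += burst
    return rec.copy_with(samples=out)
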