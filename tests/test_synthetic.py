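"""Ground-truth contracts of the synthetic two-state EEG generator."""

import numpy as np
import pytest
from scipy.signal import welch

import hypnobci as hb


def _band_power(x, fs, band):
    f, p = welch(x, fs=fs, nperseg=int(4 * fs), noverlap=int(2 * fs))
    m = (f >= band[0]) & (f <= band[1])
    return np.trapezoid(p[..., m], f[m], axis=-1)


def _single_band_signatures(n_ch, band=(4.0, 8.0), wake_gain=1.0, deep_gain=2.0):
    wake = hb.StateSignature("WAKE", [(band, np.full(n_ch, wake_gain))])
    deep = hb.StateSignature("DEEP", [(band, np.full(n_ch, deep_gain))])
    return wake, deep


class TestGenerateSession:
    def test_shape_and_labels_bookkeeping(self):
        script = hb.SessionScript(
            segments=[hb.Segment(10, "WAKE")],
            fs=250.0,
            montage=["c1", "c2", "c3", "c4"],
            seed=0,
        )
        wake, deep = _single_band_signatures(4)
        rec, track = hb.generate_session(script, wake, deep)
        assert rec.samples.shape == (4, 2500)
        assert track.intervals == [(0.0, 10.0, hb.State.WAKE)]

    def test_mix_segments_are_unlabelled(self):
        script = hb.SessionScript(
            segments=[
                hb.Segment(20, "WAKE"),
                hb.Segment(10, "MIX", (0.0, 1.0)),
                hb.Segment(20, "DEEP"),
            ],
            fs=125.0,
            montage=["a"],
            seed=0,
        )
        wake, deep = _single_band_signatures(1)
        _, track = hb.generate_session(script, wake, deep)
        assert track.intervals == [
            (0.0, 20.0, hb.State.WAKE),
            (30.0, 50.0, hb.State.DEEP),
        ]

    def test_determinism_bit_identical(self):
        script = hb.SessionScript(
            segments=[hb.Segment(15, "WAKE"), hb.Segment(15, "DEEP")],
            fs=125.0,
            montage=["a", "b"],
            seed=42,
        )
        wake, deep = _single_band_signatures(2)
        r1, _ = hb.generate_session(script, wake, deep)
        r2, _ = hb.generate_session(script, wake, deep)
        assert np.array_equal(r1.samples, r2.samples)

    def test_zeroed_alpha_gain_suppresses_alpha_power(self):
        """DEEP with alpha gain 0 must show less alpha power than WAKE."""
        n_ch = 3
        alpha = (8.0, 12.0)
        wake = hb.StateSignature("WAKE", [(alpha, np.ones(n_ch))])
        deep = hb.StateSignature("DEEP", [(alpha, np.zeros(n_ch))])
        script = hb.SessionScript(
            segments=[hb.Segment(60, "WAKE"), hb.Segment(60, "DEEP")],
            fs=250.0,
            montage=["a", "b", "c"],
            seed=3,
        )
        rec, _ = hb.generate_session(script, wake, deep)
        half = rec.n_samples // 2
        p_wake = _band_power(rec.samples[:, :half], rec.fs, alpha)
        p_deep = _band_power(rec.samples[:, half:], rec.fs, alpha)
        assert np.all(p_deep < p_wake)

    def test_band_power_ratio_tracks_squared_gain(self):
        """Gain ratio r on an isolated band gives a power ratio near r²."""
        r = 2.0
        wake, deep = _single_band_signatures(2, deep_gain=r)
        script = hb.SessionScript(
            segments=[hb.Segment(90, "WAKE"), hb.Segment(90, "DEEP")],
            fs=250.0,
            montage=["a", "b"],
            seed=8,
        )
        rec, _ = hb.generate_session(script, wake, deep)
        half = rec.n_samples // 2
        ratio = _band_power(rec.samples[:, half:], rec.fs, (4, 8)) / _band_power(
            rec.samples[:, :half], rec.fs, (4, 8)
        )
        assert np.all(np.abs(ratio - r**2) <= 0.2 * r**2)

    @pytest.mark.parametrize("coeff,match_state", [(0.0, "WAKE"), (1.0, "DEEP")])
    def test_mix_extremes_match_pure_states(self, coeff, match_state):
        wake, deep = _single_band_signatures(2)
        script = hb.SessionScript(
            segments=[
                hb.Segment(60, "WAKE"),
                hb.Segment(60, "DEEP"),
                hb.Segment(60, "MIX", (coeff, coeff)),
            ],
            fs=250.0,
            montage=["a", "b"],
            seed=4,
        )
        rec, _ = hb.generate_session(script, wake, deep)
        n = int(60 * rec.fs)
        segs = {
            "WAKE": rec.samples[:, :n],
            "DEEP": rec.samples[:, n : 2 * n],
            "MIX": rec.samples[:, 2 * n :],
        }
        p_mix = _band_power(segs["MIX"], rec.fs, (4, 8))
        p_ref = _band_power(segs[match_state], rec.fs, (4, 8))
        assert np.all(np.abs(p_mix / p_ref - 1.0) < 0.35)

    def test_montage_mismatch_rejected(self):
        script = hb.SessionScript(
            segments=[hb.Segment(5, "WAKE")], fs=125.0, montage=["a", "b"], seed=0
        )
        wake, deep = _single_band_signatures(3)
        with pytest.raises(ValueError, match="montage"):
            hb.generate_session(script, wake, deep)

    def test_zero_duration_segment_rejected(self):
        with pytest.raises(ValueError, match="duration"):
            hb.Segment(0.0, "WAKE")

    def test_mixing_matrix_applies_volume_conduction(self):
        wake, deep = _single_band_signatures(2)
        script = hb.SessionScript(
            segments=[hb.Segment(10, "WAKE")], fs=125.0, montage=["a", "b"], seed=1
        )
        mix = np.array([[1.0, 0.5], [0.5, 1.0]])
        rec_plain, _ = hb.generate_session(script, wake, deep)
        rec_mixed, _ = hb.generate_session(script, wake, deep, mixing_matrix=mix)
        assert np.allclose(rec_mixed.samples, mix @ rec_plain.samples)
        with pytest.raises(ValueError, match="mixing_matrix"):
            hb.generate_session(script, wake, deep, mixing_matrix=np.eye(3))


class TestDefaultSignatures:
    def test_deep_exceeds_wake_theta_on_every_channel(self):
        wake, deep = hb.default_signatures(hb.STANDARD_1020)
        theta_wake = dict(zip([b for b, _ in wake.band_gains],
                              [g for _, g in wake.band_gains]))[(4.0, 8.0)]
        theta_deep = dict(zip([b for b, _ in deep.band_gains],
                              [g for _, g in deep.band_gains]))[(4.0, 8.0)]
        assert np.all(theta_deep > theta_wake)

    def test_deep_alpha_attenuated(self):
        wake, deep = hb.default_signatures(hb.STANDARD_1020)
        alpha_wake = [g for b, g in wake.band_gains if b == (8.0, 12.0)][0]
        alpha_deep = [g for b, g in deep.band_gains if b == (8.0, 12.0)][0]
        assert np.all(alpha_deep < alpha_wake)

    def test_single_channel_montage(self):
        wake, deep = hb.default_signatures(["Cz"])
        assert wake.n_channels == deep.n_channels == 1

    def test_empty_montage_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            hb.default_signatures([])


def test_artifact_bursts_raise_peak_amplitude():
    wake, deep = _single_band_signatures(2)
    script = hb.SessionScript(
        segments=[hb.Segment(60, "WAKE")], fs=125.0, montage=["a", "b"], seed=1
    )
    rec, _ = hb.generate_session(script, wake, deep)
    noisy = hb.add_artifact_bursts(rec, rate_per_min=10, amplitude_uv=500, seed=2)
    assert np.abs(noisy.samples).max() > 3 * np.abs(rec.samples).max()
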