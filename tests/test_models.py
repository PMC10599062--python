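"""CSP eigenstructure, log-variance features, LDA posterior contracts."""

import numpy as np
import pytest
from scipy import linalg

import hypnobci as hb


def _windows_with_covariance(cov, n_epochs=12, n_times=256, seed=0):
    """Epoch windows whose empirical covariance is exactly ``cov``."""
    rng = np.random.default_rng(seed)
    n_ch = cov.shape[0]
    L = np.linalg.cholesky(cov)
    out = []
    for _ in range(n_epochs):
        z = rng.standard_normal((n_ch, n_times))
        z -= z.mean(axis=1, keepdims=True)
        # empirical whitening makes the sample covariance exactly identity
        w = np.linalg.cholesky(z @ z.T / n_times)
        out.append(L @ np.linalg.solve(w, z))
    return np.stack(out)


class TestCSP:
    def test_diagonal_covariances_solved_analytically(self):
        """C_deep=diag(2,1), C_wake=diag(1,2): eigenvalues 2/3 and 1/3."""
        wake = _windows_with_covariance(np.diag([1.0, 2.0]), seed=1)
        deep = _windows_with_covariance(np.diag([2.0, 1.0]), seed=2)
        csp = hb.fit_csp(wake, deep, n_pairs=1)
        assert csp.eigenvalues == pytest.approx([2 / 3, 1 / 3], abs=1e-6)
        # filters aligned with the coordinate axes
        for row in csp.filters:
            assert np.abs(row / np.abs(row).max()).min() < 1e-6

    def test_simultaneous_diagonalization_of_class_covariances(self):
        rng = np.random.default_rng(3)
        wake = rng.standard_normal((20, 8, 300))
        deep = rng.standard_normal((20, 8, 300)) * rng.uniform(0.5, 2.0, (1, 8, 1))
        csp = hb.fit_csp(wake, deep, n_pairs=4)  # full filter set
        cw, cd = hb.class_covariances(wake, deep)
        dw = csp.filters @ cw @ csp.filters.T
        dd = csp.filters @ cd @ csp.filters.T
        for m in (dw, dd):
            off = m - np.diag(np.diag(m))
            assert np.abs(off).max() < 1e-8
        assert np.allclose(np.diag(dw + dd), 1.0, atol=1e-8)

    def test_eigenvalues_match_brute_force_generalized_eig(self):
        """Independent route: scipy.linalg.eig on the same covariances."""
        rng = np.random.default_rng(4)
        wake = rng.standard_normal((15, 19, 250))
        deep = rng.standard_normal((15, 19, 250)) * rng.uniform(0.6, 1.8, (1, 19, 1))
        csp = hb.fit_csp(wake, deep, n_pairs=3)
        cw, cd = hb.class_covariances(wake, deep)
        lam = np.sort(linalg.eig(cd, cd + cw)[0].real)[::-1]
        expected = np.concatenate([lam[:3], lam[-3:]])
        assert np.abs(csp.eigenvalues - expected).max() < 1e-8

    def test_class_swap_maps_eigenvalues_to_complement(self):
        rng = np.random.default_rng(5)
        a = rng.standard_normal((10, 6, 200))
        b = rng.standard_normal((10, 6, 200)) * 1.5
        c1 = hb.fit_csp(a, b, n_pairs=3)
        c2 = hb.fit_csp(b, a, n_pairs=3)
        assert np.allclose(
            np.sort(c1.eigenvalues), np.sort(1.0 - c2.eigenvalues), atol=1e-10
        )
        # same filters up to order and sign
        f1 = np.sort(np.abs(c1.filters), axis=None)
        f2 = np.sort(np.abs(c2.filters), axis=None)
        assert np.allclose(f1, f2, atol=1e-8)

    def test_invariance_to_scaled_orthogonal_mixing_is_exact(self):
        """Rotating and uniformly rescaling the montage leaves features
        unchanged: per-epoch traces are preserved, so the estimator is
        exactly equivariant and projected variances are identical."""
        rng = np.random.default_rng(6)
        wake = rng.standard_normal((15, 5, 300))
        deep = rng.standard_normal((15, 5, 300)) * rng.uniform(0.5, 2, (1, 5, 1))
        q, _ = np.linalg.qr(rng.standard_normal((5, 5)))
        k = 3.0
        mix = k * q
        csp_a = hb.fit_csp(wake, deep, n_pairs=2)
        csp_b = hb.fit_csp(
            np.einsum("ij,ejt->eit", mix, wake),
            np.einsum("ij,ejt->eit", mix, deep),
            n_pairs=2,
        )
        assert np.allclose(csp_a.eigenvalues, csp_b.eigenvalues, atol=1e-10)
        fa = hb.features_from_windows(csp_a, wake)
        fb = hb.features_from_windows(csp_b, np.einsum("ij,ejt->eit", mix, wake))
        # filters are blind to a uniform gain, so every log-variance
        # feature shifts by exactly log(k^2)
        assert np.allclose(fa + np.log(k**2), fb, atol=1e-8)

    def test_general_invertible_mixing_approximately_preserved(self):
        """A general invertible mixing reweights the per-epoch trace
        normalization, so eigenvalues agree only approximately."""
        rng = np.random.default_rng(6)
        wake = rng.standard_normal((15, 5, 300))
        deep = rng.standard_normal((15, 5, 300)) * rng.uniform(0.5, 2, (1, 5, 1))
        mix = rng.standard_normal((5, 5)) + 2 * np.eye(5)
        csp_a = hb.fit_csp(wake, deep, n_pairs=2)
        csp_b = hb.fit_csp(
            np.einsum("ij,ejt->eit", mix, wake),
            np.einsum("ij,ejt->eit", mix, deep),
            n_pairs=2,
        )
        assert np.allclose(csp_a.eigenvalues, csp_b.eigenvalues, atol=0.05)

    def test_insufficient_epochs_rejected(self):
        w = np.random.default_rng(0).standard_normal((1, 4, 100))
        with pytest.raises(ValueError, match="2 epochs"):
            hb.fit_csp(w, np.concatenate([w, w]), n_pairs=1)

    def test_too_many_pairs_rejected(self):
        rng = np.random.default_rng(0)
        w = rng.standard_normal((4, 4, 100))
        with pytest.raises(ValueError, match="exceeds"):
            hb.fit_csp(w, w + 1, n_pairs=3)


@pytest.fixture(scope="module")
def csp():
    rng = np.random.default_rng(7)
    wake = rng.standard_normal((10, 4, 200))
    deep = rng.standard_normal((10, 4, 200)) * 1.4
    return hb.fit_csp(wake, deep, n_pairs=2)


class TestFeatures:

    def test_doubling_amplitude_adds_log4(self, csp):
        rng = np.random.default_rng(8)
        w = rng.standard_normal((4, 200))
        f1 = hb.extract_features(csp, w)
        f2 = hb.extract_features(csp, 2.0 * w)
        assert np.allclose(f2 - f1, np.log(4.0), atol=1e-12)

    def test_drift_offset_shifts_features_exactly(self, csp):
        rng = np.random.default_rng(9)
        w = rng.standard_normal((4, 200))
        f0 = hb.extract_features(csp, w, drift_offset=0.0)
        f15 = hb.extract_features(csp, w, drift_offset=1.5)
        assert np.allclose(f0 - f15, 1.5)

    def test_all_zero_window_rejected(self, csp):
        with pytest.raises(ValueError, match="zero-variance"):
            hb.extract_features(csp, np.zeros((4, 200)))


class TestLDA:
    def _exact_classes(self, mu_w, mu_d, n=200, dim=1, seed=0):
        """Samples whose empirical moments match the target exactly (1-D)."""
        rng = np.random.default_rng(seed)
        z = rng.standard_normal((n, dim))
        z = (z - z.mean(0)) / z.std(0, ddof=1)
        return z + mu_w, z + mu_d

    def test_one_dimensional_boundary_at_midpoint(self):
        fw, fd = self._exact_classes(0.0, 1.0)
        lda = hb.fit_lda(fw, fd)
        assert hb.probability_value(lda, np.array([0.5])) == pytest.approx(
            0.5, abs=1e-9
        )

    def test_posterior_at_deep_mean_with_separation_six(self):
        fw, fd = self._exact_classes(0.0, 6.0)  # Mahalanobis distance 6
        lda = hb.fit_lda(fw, fd)
        assert hb.probability_value(lda, np.array([6.0])) > 0.95

    def test_agreement_with_reference_implementation(self):
        """sklearn LDA with equal priors assigns the same classes."""
        sklearn_da = pytest.importorskip("sklearn.discriminant_analysis")
        rng = np.random.default_rng(10)
        fw = rng.standard_normal((100, 4)) @ np.diag([1, 2, 1, 0.5])
        fd = fw[50:] + np.array([1.0, -0.5, 0.3, 0.8])
        fw = fw[:50]
        lda = hb.fit_lda(fw, fd)
        ref = sklearn_da.LinearDiscriminantAnalysis(priors=[0.5, 0.5])
        X = np.vstack([fw, fd])
        y = np.array([0] * len(fw) + [1] * len(fd))
        ref.fit(X, y)
        rng2 = np.random.default_rng(11)
        pts = rng2.standard_normal((300, 4)) * 2
        ours = hb.probability_value(lda, pts) > 0.5
        disc = lda.discriminant(pts)
        clear = np.abs(disc) > 1e-6
        assert np.array_equal(ours[clear], ref.predict(pts)[clear] == 1)

    def test_posterior_monotone_in_discriminant(self):
        fw, fd = self._exact_classes(0.0, 2.0)
        lda = hb.fit_lda(fw, fd)
        pts = np.linspace(-5, 5, 101)[:, None]
        p = hb.probability_value(lda, pts)
        assert np.all(np.diff(p) > 0)
        assert np.all((p >= 0) & (p <= 1))

    def test_identical_class_means_rejected(self):
        rng = np.random.default_rng(12)
        f = rng.standard_normal((50, 3))
        with pytest.raises(ValueError, match="identical class means"):
            hb.fit_lda(f, f)

    def test_tie_goes_to_wake(self):
        assert hb.decide(np.array([0.5, 0.500001]))[0] is hb.State.WAKE
        assert hb.decide(np.array([0.5, 0.500001]))[1] is hb.State.DEEP


class TestPersistence:
    def test_model_json_round_trip(self, trained, tmp_path):
        path = tmp_path / "model.json"
        hb.save_model(trained, path)
        back = hb.load_model(path)
        assert np.array_equal(back.csp.filters, trained.csp.filters)
        assert np.array_equal(back.lda.weights, trained.lda.weights)
        assert back.lda.bias == trained.lda.bias
        assert back.config == trained.config
        assert back.montage == trained.montage
        assert back.training_fingerprint == trained.training_fingerprint

    def test_version_field_required(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text("{}")
        with pytest.raises(ValueError, match="format_version"):
            hb.load_model(path)
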