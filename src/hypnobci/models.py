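"""CSP spatial filtering and LDA classification with a calibrated posterior.

The core of the subject-calibrated pipeline. Common Spatial Patterns (CSP)
learns spatial filters w solving the generalized eigenproblem

    C_deep w = lambda (C_deep + C_wake) w

on trace-normalized, class-averaged epoch covariances; lambda in [0, 1] is
the fraction of composite variance explained by the DEEP class along w.
The n_pairs largest- and n_pairs smallest-lambda filters are kept. Epoch
features are the log-variance of each filtered signal, optionally shifted
by a scalar drift offset (non-stationarity compensation between sessions).
Linear Discriminant Analysis on those features supplies the Probability
Value: the posterior P(DEEP | features) of an equal-prior, shared-covariance
Gaussian model, in [0, 1], with P(WAKE) its complement.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import linalg
from scipy.special import expit

from .io import RunConfig, State

__all__ = [
    "COV_RIDGE",
    "CSPModel",
    "LDAModel",
    "TrainedModel",
    "class_covariances",
    "fit_csp",
    "extract_features",
    "features_from_windows",
    "fit_lda",
    "probability_value",
    "decide",
    "save_model",
    "load_model",
]

MODEL_FORMAT_VERSION = "1"

#: Diagonal loading applied to each class covariance, as a fraction of the
#: mean diagonal of the composite; part of the covariance estimator, so
#: independent reimplementations must include it to match exactly.
COV_RIDGE = 1e-6
_LDA_RIDGE = 1e-8  # ridge on the pooled feature covariance


@dataclass
class CSPModel:
    """Learned spatial filters.

    ``filters`` has shape (2 * n_pairs, n_channels); rows are ordered by
    descending eigenvalue, so the first n_pairs rows maximize DEEP
    variance and the last n_pairs maximize WAKE variance.
    """

    filters: np.ndarray
    eigenvalues: np.ndarray
    n_pairs: int

    def __post_init__(self) -> None:
        self.filters = np.asarray(self.filters, dtype=float)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        if self.filters.shape[0] != 2 * self.n_pairs:
            raise ValueError("filter count must equal 2 * n_pairs")
        if np.any(np.diff(self.eigenvalues) > 1e-12):
            raise ValueError("eigenvalues must be sorted descending")

    @property
    def n_channels(self) -> int:
        return self.filters.shape[1]


@dataclass
class LDAModel:
    """Two-class linear discriminant; positive discriminant means DEEP."""

    weights: np.ndarray
    bias: float
    class_order: tuple[str, str] = ("WAKE", "DEEP")

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if not np.all(np.isfinite(self.weights)) or not np.isfinite(self.bias):
            raise ValueError("LDA coefficients must be finite")

    def discriminant(self, features: np.ndarray) -> np.ndarray:
        return np.asarray(features) @ self.weights + self.bias


def _class_covariance(windows: np.ndarray) -> np.ndarray:
    """Average of trace-normalized per-epoch sample covariances."""
    covs = []
    for w in windows:
        w = w - w.mean(axis=1, keepdims=True)
        c = (w @ w.T) / w.shape[1]
        tr = np.trace(c)
        if tr <= 0:
            raise ValueError("epoch with zero total variance")
        covs.append(c / tr)
    return np.mean(covs, axis=0)


def class_covariances(
    windows_wake: np.ndarray, windows_deep: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Regularized class covariance estimates used by :func:`fit_csp`.

    Each class covariance is the average of trace-normalized per-epoch
    sample covariances plus symmetric diagonal loading of
    ``COV_RIDGE/2`` times the composite's mean diagonal. The CSP filters
    simultaneously diagonalize exactly these two matrices.
    """
    c_wake = _class_covariance(np.asarray(windows_wake, dtype=float))
    c_deep = _class_covariance(np.asarray(windows_deep, dtype=float))
    n_ch = c_wake.shape[0]
    reg = COV_RIDGE * np.trace(c_wake + c_deep) / (2 * n_ch)
    eye = reg * np.eye(n_ch)
    return c_wake + eye, c_deep + eye


def fit_csp(
    windows_wake: np.ndarray, windows_deep: np.ndarray, n_pairs: int = 3
) -> CSPModel:
    """Fit CSP filters from per-class epoch windows.

    Parameters
    ----------
    windows_wake, windows_deep : ndarray, shape (n_epochs, n_channels, n_times)
        At least two epochs per class, equal channel counts.
    n_pairs : int
        Pairs of filters to keep; ``2 * n_pairs`` must not exceed the
        channel count.

    Filter signs are fixed by making each filter's largest-magnitude
    coefficient positive, so refits are reproducible.
    """
    windows_wake = np.asarray(windows_wake, dtype=float)
    windows_deep = np.asarray(windows_deep, dtype=float)
    if windows_wake.ndim != 3 or windows_deep.ndim != 3:
        raise ValueError("windows must be 3-D (epochs, channels, times)")
    if len(windows_wake) < 2 or len(windows_deep) < 2:
        raise ValueError("need at least 2 epochs per class to estimate covariance")
    if windows_wake.shape[1] != windows_deep.shape[1]:
        raise ValueError("classes disagree on channel count")
    n_ch = windows_wake.shape[1]
    if 2 * n_pairs > n_ch:
        raise ValueError(f"2*n_pairs={2 * n_pairs} exceeds {n_ch} channels")

    c_wake, c_deep = class_covariances(windows_wake, windows_deep)
    composite = c_wake + c_deep

    # guard: composite must be well-conditioned enough to whiten
    ev = linalg.eigvalsh(composite)
    if ev[0] <= 0 or ev[0] / ev[-1] < 1e-12:
        raise ValueError("singular composite covariance; cannot fit CSP")

    lam, vec = linalg.eigh(c_deep, composite)
    order = np.argsort(lam)[::-1]
    lam, vec = lam[order], vec[:, order]
    lam = np.clip(lam, 0.0, 1.0)

    sel = np.concatenate([np.arange(n_pairs), np.arange(n_ch - n_pairs, n_ch)])
    filters = vec[:, sel].T
    eigenvalues = lam[sel]

    for i in range(filters.shape[0]):
        j = np.argmax(np.abs(filters[i]))
        if filters[i, j] < 0:
            filters[i] = -filters[i]

    return CSPModel(filters=filters, eigenvalues=eigenvalues, n_pairs=n_pairs)


def extract_features(
    csp: CSPModel, window: np.ndarray, drift_offset: float = 0.0
) -> np.ndarray:
    """Log-variance feature vector of one epoch window.

    ``feature_i = log(var(w_i^T X)) - drift_offset``, the variance taken
    after mean removal. The drift offset is a session-level scalar
    subtracted elementwise from the feature vector before classification
    (the study applied offsets of 1.5 and 2.5 to recover drifted
    sessions).
    """
    window = np.asarray(window, dtype=float)
    if window.ndim != 2 or window.shape[0] != csp.n_channels:
        raise ValueError(
            f"window must be ({csp.n_channels}, n_times), got {window.shape}"
        )
    proj = csp.filters @ (window - window.mean(axis=1, keepdims=True))
    var = proj.var(axis=1)
    if np.any(var <= 0):
        raise ValueError("zero-variance projected signal (degenerate epoch)")
    return np.log(var) - drift_offset


def features_from_windows(
    csp: CSPModel, windows: np.ndarray, drift_offset: float = 0.0
) -> np.ndarray:
    """Feature matrix (n_epochs, 2*n_pairs) for a stack of windows."""
    return np.stack([extract_features(csp, w, drift_offset) for w in windows])


def fit_lda(features_wake: np.ndarray, features_deep: np.ndarray) -> LDAModel:
    """Closed-form two-class LDA with equal priors.

    weights = pooled_covariance^-1 (mu_deep - mu_wake); the bias places
    the decision surface on the equal-posterior locus, so the calibration
    recording's unequal labelled durations do not bias the Probability
    Value toward the longer class.
    """
    fw = np.atleast_2d(np.asarray(features_wake, dtype=float))
    fd = np.atleast_2d(np.asarray(features_deep, dtype=float))
    if fw.shape[1] != fd.shape[1]:
        raise ValueError("classes disagree on feature length")
    if len(fw) < 2 or len(fd) < 2:
        raise ValueError("need at least 2 samples per class")
    d = fw.shape[1]
    mu_w, mu_d = fw.mean(axis=0), fd.mean(axis=0)
    if np.allclose(mu_w, mu_d, atol=1e-12, rtol=0.0):
        raise ValueError("identical class means; discriminant undefined")

    sw = np.cov(fw, rowvar=False, ddof=1)
    sd = np.cov(fd, rowvar=False, ddof=1)
    nw, nd = len(fw), len(fd)
    pooled = ((nw - 1) * np.atleast_2d(sw) + (nd - 1) * np.atleast_2d(sd)) / (
        nw + nd - 2
    )
    tr = np.trace(pooled)
    if tr <= 0:
        raise ValueError("singular pooled covariance; cannot fit LDA")
    pooled = pooled + _LDA_RIDGE * tr / d * np.eye(d)
    try:
        weights = linalg.solve(pooled, mu_d - mu_w, assume_a="pos")
    except linalg.LinAlgError:
        raise ValueError("singular pooled covariance; cannot fit LDA") from None
    bias = -float(weights @ (mu_d + mu_w) / 2.0)
    return LDAModel(weights=weights, bias=bias)


def probability_value(lda: LDAModel, features: np.ndarray) -> np.ndarray | float:
    """Posterior P(DEEP | features) in [0, 1]; P(WAKE) is its complement."""
    features = np.asarray(features, dtype=float)
    p = expit(lda.discriminant(features))
    return float(p) if p.ndim == 0 else p


def decide(p, threshold: float = 0.5) -> np.ndarray:
    """Threshold posteriors into states; ties go to WAKE (conservative)."""
    p = np.atleast_1d(np.asarray(p, dtype=float))
    # dtype=object keeps the State enums (numpy would flatten str enums)
    return np.array(
        [State.DEEP if v > threshold else State.WAKE for v in p], dtype=object
    )


# --------------------------------------------------------------------------
# Trained model bundle and persistence
# --------------------------------------------------------------------------


@dataclass
class TrainedModel:
    """Everything needed to stream a new session: CSP + LDA + context."""

    csp: CSPModel
    lda: LDAModel
    fs: float
    montage: list[str]
    config: RunConfig
    training_fingerprint: str = ""
    created: float = field(default_factory=time.time)

    def check_compatible(self, fs: float, montage: list[str]) -> None:
        if abs(fs - self.fs) > 1e-9:
            raise ValueError(
                f"model trained at {self.fs} Hz cannot score a {fs} Hz recording"
            )
        if list(montage) != list(self.montage):
            raise ValueError("recording montage differs from the training montage")


def training_fingerprint(*arrays: np.ndarray) -> str:
    h = hashlib.sha256()
    for a in arrays:
        h.update(np.ascontiguousarray(a).tobytes())
    return h.hexdigest()[:16]


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Persist a trained model as a single JSON file (version field mandatory)."""
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "created": model.created,
        "fs": model.fs,
        "montage": list(model.montage),
        "csp": {
            "filters": model.csp.filters.tolist(),
            "eigenvalues": model.csp.eigenvalues.tolist(),
            "n_pairs": model.csp.n_pairs,
        },
        "lda": {
            "weights": model.lda.weights.tolist(),
            "bias": model.lda.bias,
            "class_order": list(model.lda.class_order),
        },
        "config": model.config.to_dict(),
        "training_fingerprint": model.training_fingerprint,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def load_model(path: str | Path) -> TrainedModel:
    with open(path) as fh:
        payload = json.load(fh)
    if "format_version" not in payload:
        raise ValueError(f"{path}: not a model file (missing format_version)")
    if payload["format_version"] != MODEL_FORMAT_VERSION:
        raise ValueError(
            f"{path}: unsupported model format {payload['format_version']!r}"
        )
    csp = CSPModel(
        filters=np.array(payload["csp"]["filters"]),
        eigenvalues=np.array(payload["csp"]["eigenvalues"]),
        n_pairs=payload["csp"]["n_pairs"],
    )
    lda = LDAModel(
        weights=np.array(payload["lda"]["weights"]),
        bias=payload["lda"]["bias"],
        class_order=tuple(payload["lda"]["class_order"]),
    )
    return TrainedModel(
        csp=csp,
        lda=lda,
        fs=payload["fs"],
        montage=payload["montage"],
        config=RunConfig.from_dict(payload["config"]),
        training_fingerprint=payload.get("training_fingerprint", ""),
        created=payload.get("created", 0.0),
    )
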