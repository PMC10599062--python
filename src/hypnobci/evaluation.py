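"""Accuracy procedures: 10-fold CV, cross-session agreement, band sweep.

Two accuracy notions are implemented, mirroring how a subject-calibrated
hypnotic-depth classifier is validated in practice:

* 10-fold cross-validation within one labelled recording — CSP and LDA are
  refitted on 9/10 of the labelled epochs per fold. ``blocked`` folds keep
  contiguous runs of epochs together so overlapping 4 s windows never
  straddle the train/test split; ``shuffled`` folds permute epochs first,
  which leaks shared samples between train and test and reproduces the
  optimistic (up to 100%) figures that per-epoch shuffling yields on
  overlapping epochs.
* per-epoch percent agreement of a previously trained model on a later
  labelled session (with per-state recall).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import PAPER_BANDS, EEGRecording, LabelTrack, RunConfig, State
from .models import (
    TrainedModel,
    decide,
    features_from_windows,
    fit_csp,
    fit_lda,
    probability_value,
    training_fingerprint,
)
from .preprocess import EpochSet, bandpass, epoch

__all__ = [
    "CVResult",
    "AgreementResult",
    "labelled_epochs",
    "train_model",
    "make_folds",
    "cross_validate",
    "cross_validate_epochs",
    "session_agreement",
    "band_sweep",
]


@dataclass
class CVResult:
    """Fold accuracies in percent; mean with sample SD (ddof=1)."""

    fold_accuracies: np.ndarray

    def __post_init__(self) -> None:
        self.fold_accuracies = np.asarray(self.fold_accuracies, dtype=float)

    @property
    def mean(self) -> float:
        return float(self.fold_accuracies.mean())

    @property
    def sd(self) -> float:
        return float(self.fold_accuracies.std(ddof=1))

    def __str__(self) -> str:
        return f"{self.mean:.2f} ± {self.sd:.2f} %"


@dataclass
class AgreementResult:
    """Per-epoch percent agreement on an independently labelled session."""

    n_epochs: int
    n_correct: int
    per_state: dict  # state value -> {"n": int, "correct": int}

    @property
    def accuracy(self) -> float:
        return 100.0 * self.n_correct / self.n_epochs

    def recall(self, state: State) -> float:
        d = self.per_state[State(state).value]
        return 100.0 * d["correct"] / d["n"] if d["n"] else float("nan")

    def __str__(self) -> str:
        return (
            f"{self.accuracy:.2f} % ({self.n_correct}/{self.n_epochs} epochs; "
            f"WAKE recall {self.recall(State.WAKE):.1f} %, "
            f"DEEP recall {self.recall(State.DEEP):.1f} %)"
        )


def labelled_epochs(
    rec: EEGRecording, labels: LabelTrack, config: RunConfig
) -> EpochSet:
    """Band-pass (offline, zero-phase) and epoch a labelled recording."""
    config.validate_for_fs(rec.fs)
    filtered = bandpass(rec, config.band, mode="offline")
    return epoch(filtered, config.epoch_length, config.epoch_stride, labels)


def train_model(
    rec: EEGRecording, labels: LabelTrack, config: RunConfig
) -> TrainedModel:
    """Fit CSP + LDA on every labelled epoch of a calibration recording."""
    eps = labelled_epochs(rec, labels, config)
    w_wake = eps.class_windows(State.WAKE)
    w_deep = eps.class_windows(State.DEEP)
    if len(w_wake) < 2 or len(w_deep) < 2:
        missing = State.WAKE if len(w_wake) < 2 else State.DEEP
        raise ValueError(
            f"calibration labels provide fewer than 2 {missing.value} epochs"
        )
    csp = fit_csp(w_wake, w_deep, n_pairs=config.csp_pairs)
    fw = features_from_windows(csp, w_wake)
    fd = features_from_windows(csp, w_deep)
    lda = fit_lda(fw, fd)
    return TrainedModel(
        csp=csp,
        lda=lda,
        fs=rec.fs,
        montage=list(rec.montage),
        config=config,
        training_fingerprint=training_fingerprint(w_wake, w_deep),
    )


def make_folds(
    labels_per_epoch: list[State | None],
    mode: str = "blocked",
    n_folds: int = 10,
    seed: int = 0,
    purge: int = 0,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Per-fold (train_indices, test_indices) over the labelled epochs.

    ``blocked``: each class's time-ordered epochs are split into
    ``n_folds`` contiguous chunks and training epochs within ``purge``
    index positions of the test chunk are dropped, so windows that share
    samples with a test window never reach the training set (leakage
    control). ``shuffled``: epochs are permuted (deterministic in
    ``seed``) before chunking and nothing is purged, emulating tools
    that shuffle per-epoch — every test window then has overlapping
    neighbours in the training set.
    """
    if mode not in ("blocked", "shuffled"):
        raise ValueError(f"unknown partition mode {mode!r}")
    idx_by_class = {
        s: np.array(
            [i for i, l in enumerate(labels_per_epoch) if l is s], dtype=int
        )
        for s in (State.WAKE, State.DEEP)
    }
    for s, idx in idx_by_class.items():
        if len(idx) < n_folds:
            raise ValueError(
                f"class {s.value} has {len(idx)} labelled epochs; "
                f"need at least {n_folds} for {n_folds}-fold CV"
            )
    rng = np.random.default_rng(seed)
    chunks_by_class = {}
    for s, idx in idx_by_class.items():
        if mode == "shuffled":
            idx = rng.permutation(idx)
        chunks_by_class[s] = np.array_split(idx, n_folds)

    folds = []
    all_idx = np.concatenate(list(idx_by_class.values()))
    for k in range(n_folds):
        test = np.concatenate([chunks_by_class[s][k] for s in idx_by_class])
        train = np.setdiff1d(all_idx, test)
        if mode == "blocked" and purge > 0:
            near = np.abs(train[:, None] - test[None, :]).min(axis=1) <= purge
            train = train[~near]
        folds.append((np.sort(train), np.sort(test)))
    return folds


def _overlap_purge(eps: EpochSet) -> int:
    """Index distance within which two epochs share samples."""
    return int(np.ceil(eps.epoch_length / eps.stride)) - 1


def _fold_accuracy(
    eps: EpochSet,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    config: RunConfig,
) -> float:
    lab = eps.labels
    tw = [i for i in train_idx if lab[i] is State.WAKE]
    td = [i for i in train_idx if lab[i] is State.DEEP]
    csp = fit_csp(eps.windows[tw], eps.windows[td], n_pairs=config.csp_pairs)
    lda = fit_lda(
        features_from_windows(csp, eps.windows[tw]),
        features_from_windows(csp, eps.windows[td]),
    )
    feats = features_from_windows(csp, eps.windows[test_idx], config.drift_offset)
    pred = decide(probability_value(lda, feats), config.decision_threshold)
    truth = np.array([lab[i] for i in test_idx])
    return 100.0 * float(np.mean(pred == truth))


def cross_validate(
    rec: EEGRecording,
    labels: LabelTrack,
    config: RunConfig,
    partition_mode: str | None = None,
    folds: list[tuple[np.ndarray, np.ndarray]] | None = None,
) -> CVResult:
    """10-fold CV of the CSP+LDA pipeline on one labelled recording.

    ``folds`` may be passed to reuse one partition across configurations
    (as the band sweep does); otherwise folds are derived from
    ``partition_mode`` (default: the config's mode) and ``config.seed``.
    """
    eps = labelled_epochs(rec, labels, config)
    return cross_validate_epochs(eps, config, partition_mode, folds)


def cross_validate_epochs(
    eps: EpochSet,
    config: RunConfig,
    partition_mode: str | None = None,
    folds: list[tuple[np.ndarray, np.ndarray]] | None = None,
) -> CVResult:
    """10-fold CV on an already filtered and labelled epoch set."""
    if folds is None:
        folds = make_folds(
            eps.labels,
            partition_mode or config.partition_mode,
            seed=config.seed,
            purge=_overlap_purge(eps),
        )
    accs = [_fold_accuracy(eps, tr, te, config) for tr, te in folds]
    return CVResult(fold_accuracies=np.array(accs))


def session_agreement(
    model: TrainedModel,
    rec: EEGRecording,
    labels: LabelTrack,
    config: RunConfig | None = None,
) -> AgreementResult:
    """Percent agreement of a trained model on a later labelled session.

    Every labelled epoch is classified at the decision threshold; the
    model's band and epoching are used so features match training.
    """
    cfg = config or model.config
    model.check_compatible(rec.fs, rec.montage)
    eps = labelled_epochs(
        rec, labels, RunConfig(**{**cfg.to_dict(), "band": model.config.band})
    )
    idx = eps.labelled_indices()
    if len(idx) == 0:
        raise ValueError("no labelled epochs to evaluate")
    feats = features_from_windows(model.csp, eps.windows[idx], cfg.drift_offset)
    pred = decide(probability_value(model.lda, feats), cfg.decision_threshold)
    truth = np.array([eps.labels[i] for i in idx])

    per_state = {
        s.value: {
            "n": int(np.sum(truth == s)),
            "correct": int(np.sum((truth == s) & (pred == s))),
        }
        for s in (State.WAKE, State.DEEP)
    }
    return AgreementResult(
        n_epochs=len(idx),
        n_correct=int(np.sum(pred == truth)),
        per_state=per_state,
    )


def band_sweep(
    rec: EEGRecording,
    labels: LabelTrack,
    config: RunConfig,
    bands: tuple[tuple[float, float], ...] = PAPER_BANDS,
    partition_mode: str | None = None,
) -> pd.DataFrame:
    """CV accuracy per candidate band, identical fold partitions throughout.

    Returns a DataFrame with one row per band and columns ``mean``/``sd``
    (percent). The epoch grid does not depend on the band, so one fold
    partition (from the first band's epoch labels) is reused for
    comparability.
    """
    mode = partition_mode or config.partition_mode
    first_cfg = RunConfig(**{**config.to_dict(), "band": bands[0]})
    eps = labelled_epochs(rec, labels, first_cfg)
    folds = make_folds(eps.labels, mode, seed=config.seed, purge=_overlap_purge(eps))

    rows = {}
    for band in bands:
        cfg = RunConfig(**{**config.to_dict(), "band": band})
        cv = cross_validate(rec, labels, cfg, folds=folds)
        rows[f"{band[0]:g}-{band[1]:g}Hz"] = {"mean": cv.mean, "sd": cv.sd}
    return pd.DataFrame(rows).T
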