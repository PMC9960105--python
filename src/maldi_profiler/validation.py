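"""Model performance metrics: recognition capability and cross-validation.

Recognition capability (RC) is the percentage of *training* spectra the
trained model classifies correctly — a consistency score, not a
generalization estimate.  Cross-validation (CV) is the mean held-out
accuracy under repeated stratified random subsampling (default 20% held
out, 10 repetitions) with full retraining — including peak-subset
selection — inside every split.  Percentages are rounded to two decimals,
half up.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .core_io import ClassifierModel, PeakMatrix
from .classification import (GAParams, QCParams, SNNParams, Prediction,
                             predict, train_ga, train_qc, train_snn)

_TRAINERS = {"GA": (train_ga, GAParams), "SNN": (train_snn, SNNParams),
             "QC": (train_qc, QCParams)}


def round_half_up(x: float, ndigits: int = 2) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class CVScheme:
    """Descriptor of the cross-validation protocol."""

    kind: str = "subsampling"   # "subsampling" | "kfold"
    test_fraction: float = 0.2
    repeats: int = 10
    n_folds: int = 5

    def describe(self) -> str:
        if self.kind == "subsampling":
            return (f"stratified random subsampling, "
                    f"{self.test_fraction:.0%} held out x {self.repeats}")
        return f"stratified {self.n_folds}-fold"


@dataclass
class ValidationResult:
    model_type: str
    generated_peaks: int
    recognition_capability: float   # percent
    cross_validation: float         # percent (mean)
    cross_validation_sd: float      # percent
    confusion: dict                 # (true, predicted) -> count
    cv_scheme: str = ""
    seed: int = 0
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "model_type": self.model_type,
            "generated_peaks": self.generated_peaks,
            "recognition_capability": self.recognition_capability,
            "cross_validation": self.cross_validation,
            "cross_validation_sd": self.cross_validation_sd,
            "confusion": {f"{t}->{p}": c for (t, p), c in self.confusion.items()},
            "cv_scheme": self.cv_scheme,
            "seed": self.seed,
        }
        d.update(self.extras)
        return d


def confusion_counts(true_labels, predicted) -> dict:
    conf: dict = {}
    for t, p in zip(true_labels, predicted):
        conf[(str(t), str(p))] = conf.get((str(t), str(p)), 0) + 1
    return conf


def recognition_capability(model: ClassifierModel, matrix: PeakMatrix):
    """Percent of training samples classified correctly, with confusion
    counts.  Returns ``(percent, confusion)``."""
    pred: Prediction = predict(model, matrix)
    true = np.asarray(matrix.labels)
    if set(true) - set(model.class_names):
        raise ValueError("matrix contains labels unknown to the model")
    pct = 100.0 * float(np.mean(pred.labels == true)) if len(true) else 0.0
    return round_half_up(pct), confusion_counts(true, pred.labels)


def _stratified_split(labels, test_fraction, rng):
    labels = np.asarray(labels)
    test_idx = []
    for c in dict.fromkeys(labels.tolist()):
        idx = np.flatnonzero(labels == c)
        n_test = max(1, int(round(test_fraction * len(idx))))
        if n_test >= len(idx):
            raise ValueError(f"class {c!r} too small for stratified holdout")
        chosen = rng.permutation(len(idx))[:n_test]
        test_idx.extend(idx[chosen].tolist())
    return np.array(sorted(test_idx), dtype=int)


def cross_validate(model_type: str, matrix: PeakMatrix, params=None,
                   scheme: CVScheme | None = None, seed: int = 0):
    """Held-out accuracy of a model family under repeated stratified
    subsampling (or k-fold), retraining the full selection + classifier
    inside each split.

    Returns ``(mean_percent, sd_percent)``.
    """
    scheme = scheme or CVScheme()
    trainer, param_cls = _TRAINERS[model_type]
    rng = np.random.default_rng(seed)
    labels = np.asarray(matrix.labels)
    accs = []

    def run_split(test_idx: np.ndarray) -> None:
        train_idx = np.setdiff1d(np.arange(matrix.n_samples), test_idx)
        train_m = matrix.subset_rows(train_idx)
        test_m = matrix.subset_rows(test_idx)
        p = params if params is not None else param_cls()
        model = trainer(train_m, p)
        pred = predict(model, test_m)
        accs.append(float(np.mean(pred.labels == labels[test_idx])))

    if scheme.kind == "subsampling":
        for _ in range(scheme.repeats):
            run_split(_stratified_split(labels, scheme.test_fraction, rng))
    elif scheme.kind == "kfold":
        from .classification import _stratified_folds
        for fold in _stratified_folds(labels, scheme.n_folds, rng):
            run_split(fold)
    else:
        raise ValueError(f"unknown CV scheme {scheme.kind!r}")
    accs = np.array(accs)
    return (round_half_up(100.0 * accs.mean()),
            round_half_up(100.0 * accs.std(ddof=1) if len(accs) > 1 else 0.0))


def validate_model(model_type: str, matrix: PeakMatrix, params=None,
                   scheme: CVScheme | None = None, seed: int = 0
                   ) -> ValidationResult:
    """Train on the full matrix, score RC, and cross-validate."""
    scheme = scheme or CVScheme()
    trainer, param_cls = _TRAINERS[model_type]
    p = params if params is not None else param_cls()
    model = trainer(matrix, p)
    rc, conf = recognition_capability(model, matrix)
    cv_mean, cv_sd = cross_validate(model_type, matrix, params=params,
                                    scheme=scheme, seed=seed)
    return ValidationResult(
        model_type=model_type,
        generated_peaks=len(model.peak_indices),
        recognition_capability=rc,
        cross_validation=cv_mean,
        cross_validation_sd=cv_sd,
        confusion=conf,
        cv_scheme=scheme.describe(),
        seed=seed,
    )


def results_table(results, sample_names=None) -> pd.DataFrame:
    """Arrange validation results as a summary table (one row per model)."""
    recs = []
    for i, r in enumerate(results):
        recs.append({
            "Samples": (sample_names[i] if sample_names else ""),
            "Model": r.model_type,
            "Generated Peaks": r.generated_peaks,
            "Cross-Validation (%)": r.cross_validation,
            "Recognition Capability (%)": r.recognition_capability,
        })
    return pd.DataFrame(recs)
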