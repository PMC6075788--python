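"""Cross-validated category decoding from per-layer feature banks.

A linear multi-class support vector machine (one-vs-rest, default
regularization) is trained on exemplar-level activations with stratified
k-fold cross-validation; features are standardized using training-fold
statistics only.  Layers are compared on a shared fold assignment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import t as t_dist
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

from .rdm import FeatureBank

__all__ = ["DecodingResult", "decode_layer", "decode_all_layers", "make_folds"]


@dataclass
class DecodingResult:
    """Cross-validated decoding accuracy for one layer."""

    layer_id: str
    accuracy: float
    fold_accuracies: np.ndarray
    n_classes: int
    confidence_interval: tuple

    def __post_init__(self) -> None:
        self.fold_accuracies = np.asarray(self.fold_accuracies, dtype=float)
        if not np.isclose(self.accuracy, self.fold_accuracies.mean()):
            raise ValueError("accuracy must equal the mean of fold accuracies")

    @property
    def chance(self) -> float:
        return 1.0 / self.n_classes


def make_folds(labels, n_folds: int = 5, seed: int = 0):
    """Stratified fold assignment shared across layers."""
    labels = np.asarray(labels)
    counts = {c: int((labels == c).sum()) for c in np.unique(labels)}
    short = [c for c, n in counts.items() if n < n_folds]
    if short:
        raise ValueError(f"categories with fewer than {n_folds} exemplars: {short}")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=int(seed) % 2**31)
    return list(skf.split(np.zeros(len(labels)), labels))


def _classifier():
    return make_pipeline(
        StandardScaler(),
        LinearSVC(C=1.0, dual=False, max_iter=10000),
    )


def decode_layer(bank: FeatureBank, n_folds: int = 5, seed: int = 0, folds=None) -> DecodingResult:
    """Stratified k-fold linear-SVM decoding of one layer's exemplars."""
    X = bank.activations
    y = bank.labels.astype(str)
    if folds is None:
        folds = make_folds(y, n_folds=n_folds, seed=seed)
    accs = []
    for train, test in folds:
        clf = _classifier()
        clf.fit(X[train], y[train])
        accs.append(float(np.mean(clf.predict(X[test]) == y[test])))
    accs = np.asarray(accs)
    k = len(accs)
    sem = accs.std(ddof=1) / np.sqrt(k) if k > 1 else 0.0
    half = float(t_dist.ppf(0.975, k - 1) * sem) if k > 1 else 0.0
    mean = float(accs.mean())
    return DecodingResult(
        layer_id=bank.layer_id,
        accuracy=mean,
        fold_accuracies=accs,
        n_classes=bank.n_categories,
        confidence_interval=(mean - half, mean + half),
    )


def decode_all_layers(banks, n_folds: int = 5, seed: int = 0) -> list[DecodingResult]:
    """Decode every layer with one shared fold assignment."""
    labels0 = np.asarray(banks[0].labels)
    for bank in banks[1:]:
        if not np.array_equal(np.asarray(bank.labels), labels0):
            raise ValueError("banks must share exemplar labels")
    folds = make_folds(labels0.astype(str), n_folds=n_folds, seed=seed)
    return [decode_layer(bank, n_folds=n_folds, seed=seed, folds=folds) for bank in banks]
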