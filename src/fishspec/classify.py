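"""Cross-validated prediction of postmortem day from preprocessed spectra.

A radial-basis-function support-vector classifier under seeded, stratified
k-fold cross-validation, reported as a fold-pooled confusion matrix with
per-class (row) percentage accuracies; plus a PCA + t-SNE 2-D embedding for
visualisation (and nothing more — no quantitative claim rides on the
embedding geometry).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE
from sklearn.model_selection import StratifiedKFold, cross_val_predict
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .spectra import SpectraSet

__all__ = ["CVReport", "EmbeddingResult", "svm_cv", "tsne_embed", "confusion_to_percent"]


@dataclass
class CVReport:
    """Fold-pooled cross-validation report.

    ``confusion[i, j]`` counts spectra of true class ``classes[i]`` predicted
    as ``classes[j]``; every spectrum is predicted exactly once by a model
    that never saw it.
    """

    classes: np.ndarray
    confusion: np.ndarray
    folds: int
    seed: int
    hyperparams: dict = field(default_factory=dict)

    @property
    def per_class_accuracy(self) -> np.ndarray:
        """Diagonal row percentages, in [0, 100]."""
        rowsum = self.confusion.sum(axis=1)
        return 100.0 * np.diag(self.confusion) / rowsum

    @property
    def overall_accuracy(self) -> float:
        return float(100.0 * np.trace(self.confusion) / self.confusion.sum())

    def to_frame(self) -> pd.DataFrame:
        labels = [f"D{c}" for c in self.classes]
        return pd.DataFrame(self.confusion, index=labels, columns=labels)

    def summary(self) -> str:
        lines = [
            f"SVM {self.folds}-fold CV (seed {self.seed}, "
            + ", ".join(f"{k}={v}" for k, v in self.hyperparams.items()) + ")",
            "=" * 50,
            self.to_frame().to_string(),
            "",
            "per-class accuracy (%): "
            + "  ".join(f"D{c}: {a:.1f}" for c, a in zip(self.classes, self.per_class_accuracy)),
            f"overall accuracy: {self.overall_accuracy:.1f}%",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "classes": self.classes.tolist(),
            "confusion": self.confusion.tolist(),
            "per_class_accuracy": self.per_class_accuracy.tolist(),
            "overall_accuracy": self.overall_accuracy,
            "folds": self.folds,
            "seed": self.seed,
            "hyperparams": dict(self.hyperparams),
        }


@dataclass
class EmbeddingResult:
    coordinates: np.ndarray
    labels: np.ndarray
    perplexity: float
    n_pcs_input: int
    seed: int

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for day in np.unique(self.labels):
            m = self.labels == day
            ax.scatter(*self.coordinates[m].T, s=8, label=f"D{day}")
        ax.legend()
        ax.set_xlabel("t-SNE 1")
        ax.set_ylabel("t-SNE 2")
        return ax


def svm_cv(spectra_set: SpectraSet, folds: int = 10, seed: int = 0,
           C: float = 1.0, gamma="scale") -> CVReport:
    """Stratified k-fold cross-validation of an RBF-kernel SVC.

    Defaults are the conventional workbench settings (C=1, gamma="scale",
    per-feature standardisation fitted inside each training fold). The
    standardisation matters: unit-norm spectra have tiny pairwise distances,
    which would otherwise collapse the RBF kernel towards a constant.
    """
    y = spectra_set.labels
    classes, counts = np.unique(y, return_counts=True)
    thin = classes[counts < folds]
    if thin.size:
        raise ValueError(
            f"class(es) {[f'D{c}' for c in thin]} have fewer members than "
            f"folds={folds}; reduce folds or drop the class"
        )
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    clf = make_pipeline(StandardScaler(), SVC(kernel="rbf", C=C, gamma=gamma))
    pred = cross_val_predict(clf, spectra_set.intensities, y, cv=cv)
    G = classes.size
    confusion = np.zeros((G, G), dtype=int)
    pos = {c: i for i, c in enumerate(classes)}
    for t, p in zip(y, pred):
        confusion[pos[t], pos[p]] += 1
    return CVReport(classes=classes, confusion=confusion, folds=folds, seed=seed,
                    hyperparams={"C": C, "gamma": gamma})


def confusion_to_percent(report: CVReport) -> np.ndarray:
    """Row-percentage confusion matrix; each row sums to 100."""
    rowsum = report.confusion.sum(axis=1, keepdims=True)
    if np.any(rowsum == 0):
        zero = report.classes[np.flatnonzero(rowsum.ravel() == 0)]
        raise ValueError(f"class(es) {zero.tolist()} have zero true samples; "
                         "row percentages undefined")
    return 100.0 * report.confusion / rowsum


def tsne_embed(spectra_set: SpectraSet, n_pcs: int = 5, perplexity: float = 50.0,
               seed: int = 0) -> EmbeddingResult:
    """PCA to ``n_pcs`` components, then a seeded 2-D t-SNE embedding."""
    n = len(spectra_set)
    if perplexity >= n:
        raise ValueError(f"perplexity ({perplexity}) must be < n_spectra ({n})")
    if n < 3 * perplexity:
        warnings.warn(f"n_spectra ({n}) < 3 x perplexity ({perplexity}); "
                      "embedding may be unstable", stacklevel=2)
    T = PCA(n_components=n_pcs, svd_solver="full").fit_transform(spectra_set.intensities)
    coords = TSNE(n_components=2, perplexity=perplexity, random_state=seed,
                  init="pca").fit_transform(T)
    return EmbeddingResult(coordinates=np.asarray(coords, float),
                           labels=spectra_set.labels, perplexity=perplexity,
                           n_pcs_input=n_pcs, seed=seed)
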