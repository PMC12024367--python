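"""Linear discriminant classification of latent vectors and screening metrics.

After contrastive pre-training the encoder is frozen; a two-class LDA is
fitted on the training partition's latents and evaluated on the held-out
test partition.  The within-class scatter is shrunk toward a scaled identity
(Ledoit-Wolf by default) so the fit stays well-posed even when the latent
dimension approaches the sample count.  Screening quality is summarised by
accuracy, sensitivity TP/(TP+FN) and specificity TN/(TN+FP); with equal
positive and negative test counts, accuracy equals the mean of sensitivity
and specificity exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .encoder import LatentMatrix

__all__ = [
    "ConfusionCounts",
    "MetricReport",
    "LdaModel",
    "fit_lda",
    "predict",
    "confusion_from_labels",
    "compute_metrics",
    "aggregate_metrics",
    "pca_embed",
]


def _as_matrix(X) -> np.ndarray:
    if isinstance(X, LatentMatrix):
        X = X.values
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("expected a 2-D feature matrix")
    return X


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion counts; positive class is label 1."""

    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass(frozen=True)
class MetricReport:
    """Accuracy / sensitivity / specificity, possibly aggregated over trials.

    A metric whose denominator is empty (e.g. sensitivity with no positive
    samples) is reported as None rather than silently 0.
    """

    accuracy: float | None
    sensitivity: float | None
    specificity: float | None
    n_trials: int = 1
    accuracy_sd: float | None = None
    sensitivity_sd: float | None = None
    specificity_sd: float | None = None

    def __post_init__(self) -> None:
        for name in ("accuracy", "sensitivity", "specificity"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "n_trials": self.n_trials,
            "accuracy_sd": self.accuracy_sd,
            "sensitivity_sd": self.sensitivity_sd,
            "specificity_sd": self.specificity_sd,
        }


@dataclass
class LdaModel:
    """Fitted two-class linear discriminant.

    Prediction uses the sign of the linear discriminant score; a score of
    exactly zero (a tie) goes to the negative class.
    """

    class_means: np.ndarray  # (2, p), rows ordered [negative, positive]
    coef: np.ndarray  # (p,)
    intercept: float
    priors: np.ndarray
    shrinkage: float | str
    n_features: int

    def decision_scores(self, X) -> np.ndarray:
        X = _as_matrix(X)
        if X.shape[1] != self.n_features:
            raise ValueError(
                f"expected {self.n_features} features, got {X.shape[1]}"
            )
        return X @ self.coef + self.intercept


def fit_lda(X, y, shrinkage: float | str = "auto",
            priors: tuple[float, float] = (0.5, 0.5)) -> LdaModel:
    """Fit a shrinkage-regularized two-class LDA on latent features.

    ``shrinkage`` is the convex weight toward a scaled identity for the
    within-class scatter; ``"auto"`` uses the analytic Ledoit-Wolf rule,
    which is deterministic.  Priors default to equal, so the decision
    threshold sits midway between the class means regardless of the class
    balance of the training latents.
    """
    X = _as_matrix(X)
    y = np.asarray(y, dtype=int)
    classes = np.unique(y)
    if classes.tolist() != [0, 1]:
        raise ValueError("need both classes 0 and 1 present to fit LDA")
    if min((y == 0).sum(), (y == 1).sum()) < 2:
        raise ValueError("need at least 2 samples per class")
    if isinstance(shrinkage, (int, float)) and not (0.0 <= shrinkage <= 1.0):
        raise ValueError("shrinkage must be in [0, 1]")
    skl = LinearDiscriminantAnalysis(
        solver="lsqr",
        shrinkage=None if shrinkage == 0 else shrinkage,
        priors=np.asarray(priors, dtype=float),
    )
    skl.fit(X, y)
    return LdaModel(
        class_means=skl.means_.copy(),
        coef=skl.coef_.ravel().copy(),
        intercept=float(skl.intercept_[0]),
        priors=np.asarray(priors, dtype=float),
        shrinkage=shrinkage,
        n_features=X.shape[1],
    )


def predict(model: LdaModel, X) -> np.ndarray:
    """Hard labels from discriminant scores; ties go to the negative class."""
    return (model.decision_scores(X) > 0).astype(int)


def confusion_from_labels(y_true, y_pred) -> ConfusionCounts:
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors differ in length")
    return ConfusionCounts(
        TP=int(((y_true == 1) & (y_pred == 1)).sum()),
        TN=int(((y_true == 0) & (y_pred == 0)).sum()),
        FP=int(((y_true == 0) & (y_pred == 1)).sum()),
        FN=int(((y_true == 1) & (y_pred == 0)).sum()),
    )


def compute_metrics(counts: ConfusionCounts) -> MetricReport:
    """Accuracy, sensitivity and specificity from confusion counts."""
    if counts.total == 0:
        raise ValueError("empty confusion matrix")
    acc = (counts.TP + counts.TN) / counts.total
    pos = counts.TP + counts.FN
    neg = counts.TN + counts.FP
    return MetricReport(
        accuracy=acc,
        sensitivity=counts.TP / pos if pos > 0 else None,
        specificity=counts.TN / neg if neg > 0 else None,
    )


def aggregate_metrics(reports: list[MetricReport]) -> MetricReport:
    """Mean and (population) sd per metric over per-trial reports."""
    if not reports:
        raise ValueError("no reports to aggregate")

    def stats(name):
        vals = [getattr(r, name) for r in reports if getattr(r, name) is not None]
        if not vals:
            return None, None
        return float(np.mean(vals)), float(np.std(vals))

    acc, acc_sd = stats("accuracy")
    sen, sen_sd = stats("sensitivity")
    spe, spe_sd = stats("specificity")
    return MetricReport(
        accuracy=acc, sensitivity=sen, specificity=spe,
        n_trials=len(reports),
        accuracy_sd=acc_sd, sensitivity_sd=sen_sd, specificity_sd=spe_sd,
    )


def pca_embed(X, n_components: int = 2) -> np.ndarray:
    """Deterministic PCA projection for visualising raw vs. encoded data.

    Components are sign-fixed by making each axis's largest-magnitude loading
    positive, so repeated runs and equivalent inputs give identical plots.
    """
    X = _as_matrix(X)
    if X.shape[0] < n_components:
        raise ValueError(
            f"need at least {n_components} rows for {n_components} components"
        )
    if np.allclose(X.var(axis=0), 0.0):
        raise ValueError("zero-variance input: PCA is degenerate")
    pca = PCA(n_components=n_components, svd_solver="full")
    Z = pca.fit_transform(X)
    for j in range(n_components):
        load = pca.components_[j]
        k = int(np.argmax(np.abs(load)))
        if load[k] < 0:
            Z[:, j] = -Z[:, j]
    return Z
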