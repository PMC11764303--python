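"""Feature extraction, K-means pseudo-labeling and SVM stress classification.

The workflow mirrors a common weak-supervision pattern: K-means with
k=2 splits the cohort's feature vectors into "stressed" and "relaxed"
clusters (the cluster with the larger mean peak amplitude is the
stressed one); the cluster labels then serve as training labels for a
support-vector classifier (linear or RBF kernel, or the ν-parameterized
NuSVM variant), tuned by grid search under 5-fold cross-validation.
Evaluation metrics (precision, recall, F1, accuracy) are computed from
first-principles confusion counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.model_selection import GridSearchCV, KFold
from sklearn.svm import SVC, NuSVC

from .device_model import ConductanceTrace
from .preprocess import PhasicTrace, normalize_01
from .scr_events import SCREvent, peak_width

__all__ = [
    "FeatureVector",
    "MLConfig",
    "ClassificationMetrics",
    "extract_features",
    "features_frame",
    "kmeans_stress_clusters",
    "train_classifier",
    "evaluate",
]

FEATURE_NAMES = ("peak_amplitude", "peak_width", "mean_gsr", "amp_minus_mean", "phasic_max")

DEFAULT_C_GRID = (0.01, 0.1, 1.0, 10.0, 100.0)
DEFAULT_GAMMA_GRID = (0.1, 0.5, 1.0, 2.0, 5.0)


@dataclass
class FeatureVector:
    """Per-trace scalar features feeding the classifiers.

    ``peak_amplitude``/``peak_width`` come from the largest detected
    SCR (0 when the trace has none); ``amp_minus_mean`` is the peak
    conductance minus the trace mean; ``phasic_max`` the maximum of
    the baseline-subtracted signal.
    """

    peak_amplitude: float
    peak_width: float
    mean_gsr: float
    amp_minus_mean: float
    phasic_max: float

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.peak_amplitude, self.peak_width, self.mean_gsr, self.amp_minus_mean, self.phasic_max]
        )


@dataclass(frozen=True)
class MLConfig:
    """SVM/NuSVM settings: kernel, grids, ν, CV folds and seed."""

    kernel: str = "rbf"
    C_grid: Tuple[float, ...] = DEFAULT_C_GRID
    gamma_grid: Tuple[float, ...] = DEFAULT_GAMMA_GRID
    gamma: float = 2.0
    nu: Optional[float] = None
    n_folds: int = 5
    seed: int = 0
    grid_search: bool = True

    def __post_init__(self) -> None:
        if self.kernel not in ("linear", "rbf"):
            raise ValueError("kernel must be 'linear' or 'rbf'")
        if self.nu is not None and not 0 < self.nu < 1:
            raise ValueError("nu must lie in (0, 1)")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")


@dataclass
class ClassificationMetrics:
    tp: int
    fp: int
    fn: int
    tn: int
    precision: float
    recall: float
    f1: float
    accuracy: float
    pct_stressed: float
    pct_unstressed: float


def extract_features(
    trace: ConductanceTrace,
    phasic: PhasicTrace,
    events: Sequence[SCREvent],
) -> FeatureVector:
    """Summarize one trace as a feature vector (see :class:`FeatureVector`)."""
    y = trace.conductance[np.isfinite(trace.conductance)]
    mean_gsr = float(np.mean(y)) if y.size else float("nan")
    ph = phasic.phasic[np.isfinite(phasic.phasic)]
    phasic_max = float(np.max(ph)) if ph.size else 0.0
    if events:
        best = max(events, key=lambda e: e.amplitude)
        amp = float(best.amplitude)
        width = float(peak_width(trace, best))
        peak_val = float(best.peak_value)
    else:
        amp = 0.0
        width = 0.0
        peak_val = float(np.max(y)) if y.size else mean_gsr
    return FeatureVector(
        peak_amplitude=amp,
        peak_width=width,
        mean_gsr=mean_gsr,
        amp_minus_mean=peak_val - mean_gsr,
        phasic_max=phasic_max,
    )


def features_frame(features: Sequence[FeatureVector], normalized: bool = True) -> pd.DataFrame:
    """One row per trace; with ``normalized`` each feature also gets a
    cohort-wise [0, 1] rescaled ``*_norm`` column."""
    df = pd.DataFrame([f.as_array() for f in features], columns=list(FEATURE_NAMES))
    if normalized:
        for name in FEATURE_NAMES:
            df[f"{name}_norm"] = normalize_01(df[name].to_numpy())
    return df


def kmeans_stress_clusters(
    features, seed: int = 0, amplitude_column: int = 0
) -> Tuple[np.ndarray, np.ndarray]:
    """k=2 K-means partition with a semantic assignment rule.

    Returns ``(labels, centroids)`` where label 1 marks the cluster
    whose centroid has the larger peak amplitude ("stressed") and the
    centroid rows are ordered (relaxed, stressed).
    """
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] < 2 or np.all(X == X[0]):
        raise ValueError("k-means needs at least two distinct points")
    km = KMeans(n_clusters=2, n_init=10, random_state=seed)
    raw = km.fit_predict(X)
    centers = km.cluster_centers_
    stressed_cluster = int(np.argmax(centers[:, amplitude_column]))
    labels = (raw == stressed_cluster).astype(int)
    ordered = centers[[1 - stressed_cluster, stressed_cluster]]
    return labels, ordered


def train_classifier(features, labels, cfg: MLConfig = MLConfig()):
    """Fit an SVM (or NuSVM when ``cfg.nu`` is set), grid-searching C
    (and gamma for RBF) by mean k-fold CV accuracy.

    Ties resolve to the smaller C, then the smaller gamma.  Raises on
    single-class labels.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if np.unique(y).size < 2:
        raise ValueError("training labels contain a single class")
    if cfg.nu is not None:
        est = NuSVC(nu=cfg.nu, kernel=cfg.kernel, gamma=cfg.gamma)
        return est.fit(X, y)
    if not cfg.grid_search:
        est = SVC(kernel=cfg.kernel, C=1.0, gamma=cfg.gamma)
        return est.fit(X, y)
    grid = {"C": list(cfg.C_grid)}
    if cfg.kernel == "rbf":
        grid["gamma"] = list(cfg.gamma_grid)
    n_folds = min(cfg.n_folds, np.bincount(pd.factorize(y)[0]).min(), X.shape[0])
    n_folds = max(n_folds, 2)
    cv = KFold(n_splits=n_folds, shuffle=True, random_state=cfg.seed)
    search = GridSearchCV(
        SVC(kernel=cfg.kernel),
        grid,
        scoring="accuracy",
        cv=cv,
        refit=True,
    )
    search.fit(X, y)
    return search


def evaluate(predicted, truth, positive=1) -> ClassificationMetrics:
    """Confusion counts and the derived metrics.

    precision = TP/(TP+FP), recall = TP/(TP+FN), F1 their harmonic
    mean, accuracy the fraction of matching labels.  Undefined ratios
    (zero denominators) are reported as 0 by convention.
    """
    p = np.asarray(predicted)
    t = np.asarray(truth)
    if p.shape != t.shape:
        raise ValueError(f"length mismatch: predicted {p.shape} vs truth {t.shape}")
    if p.size == 0:
        raise ValueError("cannot evaluate empty predictions")
    pp, tt = p == positive, t == positive
    tp = int(np.sum(pp & tt))
    fp = int(np.sum(pp & ~tt))
    fn = int(np.sum(~pp & tt))
    tn = int(np.sum(~pp & ~tt))
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    accuracy = (tp + tn) / p.size
    return ClassificationMetrics(
        tp=tp,
        fp=fp,
        fn=fn,
        tn=tn,
        precision=precision,
        recall=recall,
        f1=f1,
        accuracy=accuracy,
        pct_stressed=100.0 * pp.mean(),
        pct_unstressed=100.0 * (~pp).mean(),
    )
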