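"""Adaptive dimensionality reduction: pick the projection prefix length that
maximizes a cross-validated SVM fitness.

The canonical loadings order directions by decreasing shared-structure
strength, so candidate feature sets are the column prefixes ``U_l = X A_l``
for ``l = 1..r``.  The fitness of each prefix is the stratified k-fold
cross-validated accuracy of an RBF-kernel support-vector machine, and the
selected dimension is the argmax (smallest ``l`` on ties).  The enumeration
is exhaustive — every prefix is scored, no early stopping.

Because the prefixes are nested, the search computes the RBF kernel
incrementally: columns are standardized once, per-dimension squared
distances are accumulated, and each prefix's kernel is handed to the SVM
precomputed.  ``fitness`` uses the identical code path, so an external loop
over ``fitness(U_l)`` reproduces ``select_dimension`` exactly.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .canonical import ProjectionPair
from .errors import ConfigurationError

__all__ = ["SVMConfig", "ADRResult", "make_classifier", "fitness", "select_dimension"]


@dataclass(frozen=True)
class SVMConfig:
    """RBF-kernel SVM with fixed hyperparameters (one-vs-one multiclass).

    ``gamma='auto'`` is 1/dim, so the kernel width tracks the prefix length;
    features are standardized before the kernel so fitness is invariant to
    the scatter-normalized scale of canonical variates.
    """

    kernel: str = "rbf"
    C: float = 1.0
    gamma: str | float = "auto"


@dataclass
class ADRResult:
    """Fitness curve over prefix dimensions and the selected dimension."""

    fitness_curve: np.ndarray  # f(U_l) for l = 1..r, each in [0, 1]
    selected_l: int
    classifier_config: SVMConfig = field(default_factory=SVMConfig)
    cv_folds: int = 5
    seed: int = 0

    @property
    def selected_fitness(self) -> float:
        return float(self.fitness_curve[self.selected_l - 1])

    def to_json(self, path=None) -> str:
        payload = {
            "fitness_curve": np.asarray(self.fitness_curve).tolist(),
            "selected_l": int(self.selected_l),
            "classifier_config": asdict(self.classifier_config),
            "cv_folds": int(self.cv_folds),
            "seed": int(self.seed),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def make_classifier(config: SVMConfig | None = None) -> Pipeline:
    """Standardizer + SVC pipeline (the final-model and baseline classifier)."""
    config = config or SVMConfig()
    return Pipeline(
        [
            ("scale", StandardScaler()),
            ("svm", SVC(kernel=config.kernel, C=config.C, gamma=config.gamma)),
        ]
    )


def _resolve_folds(labels: np.ndarray, cv_folds: int) -> int:
    _, counts = np.unique(labels, return_counts=True)
    if counts.size < 2:
        raise ConfigurationError("fitness needs at least 2 classes")
    min_count = int(counts.min())
    if min_count < cv_folds:
        folds = max(2, min_count)
        warnings.warn(
            f"rarest class has {min_count} samples; reducing CV folds "
            f"{cv_folds} -> {folds}",
            stacklevel=3,
        )
        return folds
    return cv_folds


def _standardize(U: np.ndarray) -> np.ndarray:
    mean = U.mean(axis=0)
    std = U.std(axis=0)  # population SD, matching StandardScaler
    std = np.where(std > 0, std, 1.0)
    return (U - mean) / std


def _cumulative_sqdist(Us: np.ndarray, keep_all: bool = True) -> np.ndarray:
    """Accumulate pairwise squared distances column by column.

    With ``keep_all`` returns a (d, n, n) stack where slice l-1 holds the
    distances in the first l standardized columns; otherwise only the final
    (n, n) matrix.  The column-wise accumulation order is what makes
    ``fitness`` and ``select_dimension`` bit-identical."""
    n, d = Us.shape
    out = np.empty((d, n, n)) if keep_all else None
    acc = np.zeros((n, n))
    for j in range(d):
        diff = Us[:, j : j + 1] - Us[:, j]
        acc = acc + diff * diff
        if keep_all:
            out[j] = acc
    return out if keep_all else acc


def _cv_accuracy_kernel(
    K: np.ndarray, labels: np.ndarray, splits, C: float
) -> float:
    scores = []
    for tr, te in splits:
        svc = SVC(kernel="precomputed", C=C)
        svc.fit(K[np.ix_(tr, tr)], labels[tr])
        scores.append(float(np.mean(svc.predict(K[np.ix_(te, tr)]) == labels[te])))
    return float(np.mean(scores))


def _cv_accuracy_features(
    U: np.ndarray, labels: np.ndarray, splits, config: SVMConfig
) -> float:
    scores = []
    for tr, te in splits:
        svc = SVC(kernel=config.kernel, C=config.C, gamma=config.gamma)
        svc.fit(U[tr], labels[tr])
        scores.append(float(np.mean(svc.predict(U[te]) == labels[te])))
    return float(np.mean(scores))


def _make_splits(labels: np.ndarray, folds: int, seed: int):
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    return list(cv.split(np.zeros((labels.size, 1)), labels))


def _gamma_value(config: SVMConfig, dim: int) -> float:
    if config.gamma == "auto":
        return 1.0 / dim
    if config.gamma == "scale":  # standardized columns have unit variance
        return 1.0 / dim
    return float(config.gamma)


def fitness(
    U_l: np.ndarray,
    labels: np.ndarray,
    config: SVMConfig | None = None,
    cv_folds: int = 5,
    seed: int = 0,
) -> float:
    """Stratified cross-validated accuracy of the SVM on a projected view.

    Columns are standardized once over the whole view (the same deterministic
    normalization the final classifier uses); folds are stratified and
    shuffled by ``seed``.  If the rarest class has fewer samples than
    ``cv_folds``, the fold count is reduced to that size (with a warning)
    rather than failing.
    """
    config = config or SVMConfig()
    U_l = np.atleast_2d(np.asarray(U_l, dtype=float))
    if U_l.shape[1] == 0:
        raise ConfigurationError("projected view has no columns")
    if U_l.shape[0] == 1:  # a 1-D vector of samples, not one row
        U_l = U_l.T
    labels = np.asarray(labels)
    folds = _resolve_folds(labels, cv_folds)
    splits = _make_splits(labels, folds, seed)
    Us = _standardize(U_l)
    if config.kernel == "rbf":
        D = _cumulative_sqdist(Us, keep_all=False)
        K = np.exp(-_gamma_value(config, Us.shape[1]) * D)
        return _cv_accuracy_kernel(K, labels, splits, config.C)
    return _cv_accuracy_features(Us, labels, splits, config)


def select_dimension(
    X: "np.ndarray | object",
    P: ProjectionPair,
    labels: np.ndarray,
    config: SVMConfig | None = None,
    cv_folds: int = 5,
    seed: int = 0,
) -> ADRResult:
    """Exhaustively score every prefix ``U_l = X A_l`` and return the argmax.

    ``X`` may be a raw array or a FeatureMatrix-like object with ``.values``.
    Ties are broken toward the smallest ``l`` (the cheaper model).  The curve
    is numerically identical to ``[fitness(X @ P.A[:, :l], ...) for l]``.
    """
    config = config or SVMConfig()
    values = np.asarray(getattr(X, "values", X), dtype=float)
    if P.r < 1:
        raise ConfigurationError("projection pair retains no directions")
    labels = np.asarray(labels)
    folds = _resolve_folds(labels, cv_folds)
    splits = _make_splits(labels, folds, seed)
    U_full = values @ P.A  # prefixes are column slices of the full projection
    Us = _standardize(U_full)
    if config.kernel == "rbf":
        dists = _cumulative_sqdist(Us)
        curve = np.array(
            [
                _cv_accuracy_kernel(
                    np.exp(-_gamma_value(config, l) * dists[l - 1]),
                    labels,
                    splits,
                    config.C,
                )
                for l in range(1, P.r + 1)
            ]
        )
    else:
        curve = np.array(
            [
                _cv_accuracy_features(Us[:, :l], labels, splits, config)
                for l in range(1, P.r + 1)
            ]
        )
    selected = int(np.argmax(curve)) + 1  # argmax returns the first maximum
    return ADRResult(
        fitness_curve=curve,
        selected_l=selected,
        classifier_config=config,
        cv_folds=cv_folds,
        seed=seed,
    )
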