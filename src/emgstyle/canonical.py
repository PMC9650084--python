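"""Column standardization, classical CCA, and discriminative CCA (DCCA).

Both analyses are solved through the symmetric whitened formulation rather
than the raw generalized-eigenproblem products: with scatter matrices
``S11 = X'X`` and ``S22 = Y'Y`` (optionally ridge-regularized), the loading
pairs are recovered from the SVD of ``S11^{-1/2} K S22^{-1/2}`` where ``K`` is
the cross-scatter ``X'Y`` for CCA or the intra-class correlation matrix ``Cw``
for DCCA.  This guarantees real, non-negative eigenvalues ``lambda^2``
(squared singular values) and loadings that satisfy the unit-scatter
constraints ``A_i' S11 A_i = 1`` and ``B_i' S22 B_i = 1`` by construction.

DCCA replaces the sample-paired cross-scatter with the class-indicator form

    Cw = sum_k (sum of class-k rows of X)' (sum of class-k rows of Y),

which only requires the two views to share a class set — not matched rows —
so a pooled training view and a small calibration view of different sizes can
be aligned.  For column-standardized views the inter-class matrix is exactly
``Cb = -Cw``, so maximizing intra-class correlation simultaneously minimizes
inter-class correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import linalg

from .errors import (
    ConditioningError,
    ConfigurationError,
    DegenerateColumnError,
    DegenerateDesignError,
    LabelMismatchError,
)

__all__ = [
    "FeatureMatrix",
    "ColumnStats",
    "CorrelationMatrices",
    "ProjectionPair",
    "CanonicalVariates",
    "standardize_columns",
    "build_class_matrices",
    "fit_cca",
    "fit_dcca",
    "project",
    "canonical_variates",
]


@dataclass
class FeatureMatrix:
    """A labeled feature table: one row per window (or sample).

    Rows are kept grouped contiguously by class; :meth:`sorted_by_class`
    enforces that layout, which the class-indicator construction of DCCA
    assumes.
    """

    values: np.ndarray
    labels: np.ndarray
    column_names: list[str] = field(default_factory=list)
    user_id: str = ""
    n_channels: int | None = None
    groups: np.ndarray | None = None  # repetition id per row, for majority voting

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.shape[0] != self.values.shape[0]:
            raise ConfigurationError(
                f"{self.labels.shape[0]} labels for {self.values.shape[0]} rows"
            )
        if not self.column_names:
            self.column_names = [f"f{j}" for j in range(self.values.shape[1])]
        if self.groups is not None:
            self.groups = np.asarray(self.groups)

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.labels)

    @property
    def n_classes(self) -> int:
        return self.classes.size

    def class_counts(self) -> dict[int, int]:
        cls, cnt = np.unique(self.labels, return_counts=True)
        return dict(zip(cls.tolist(), cnt.tolist()))

    def sorted_by_class(self) -> "FeatureMatrix":
        """Return a copy with rows grouped contiguously by class (stable)."""
        order = np.argsort(self.labels, kind="stable")
        return replace(
            self,
            values=self.values[order],
            labels=self.labels[order],
            groups=None if self.groups is None else self.groups[order],
        )

    def subset(self, mask: np.ndarray) -> "FeatureMatrix":
        return replace(
            self,
            values=self.values[mask],
            labels=self.labels[mask],
            groups=None if self.groups is None else self.groups[mask],
        )

    # -- CSV round trip -----------------------------------------------------
    def to_csv(self, path) -> None:
        df = pd.DataFrame(self.values, columns=self.column_names)
        df["label"] = self.labels
        df["user_id"] = self.user_id or "user"
        if self.groups is not None:
            df["rep"] = self.groups
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, n_channels: int | None = None) -> "FeatureMatrix":
        df = pd.read_csv(path)
        meta = [c for c in ("label", "user_id", "rep") if c in df.columns]
        feats = [c for c in df.columns if c not in meta]
        user = str(df["user_id"].iloc[0]) if "user_id" in meta else ""
        return cls(
            values=df[feats].to_numpy(dtype=float),
            labels=df["label"].to_numpy(dtype=int),
            column_names=feats,
            user_id=user,
            n_channels=n_channels,
            groups=df["rep"].to_numpy() if "rep" in meta else None,
        )


@dataclass
class ColumnStats:
    """Per-column mean and standard deviation frozen from one view.

    Used to standardize a held-out view (e.g. a new user's test set) with the
    statistics of the view the projection was fitted on (the calibration set).
    """

    mean: np.ndarray
    std: np.ndarray

    def apply(self, fm: FeatureMatrix) -> FeatureMatrix:
        return replace(fm, values=(fm.values - self.mean) / self.std)


def standardize_columns(fm: FeatureMatrix, ddof: int = 1) -> tuple[FeatureMatrix, ColumnStats]:
    """Standardize every column to mean 0 and unit standard deviation.

    Raises :class:`DegenerateColumnError` naming the first constant column.
    """
    mean = fm.values.mean(axis=0)
    std = fm.values.std(axis=0, ddof=ddof)
    bad = np.flatnonzero(~(std > 0))
    if bad.size:
        names = [fm.column_names[j] for j in bad[:5]]
        raise DegenerateColumnError(
            f"constant column(s) cannot be standardized: {names}"
        )
    stats = ColumnStats(mean=mean, std=std)
    return stats.apply(fm), stats


@dataclass
class CorrelationMatrices:
    """Scatter and class-correlation matrices of a standardized view pair."""

    C11: np.ndarray  # p x p scatter of X
    C12: np.ndarray | None  # p x q cross-scatter (None when rows are unpaired)
    C21: np.ndarray | None  # q x p
    C22: np.ndarray  # q x q scatter of Y
    Cw: np.ndarray  # p x q intra-class correlation matrix
    Cb: np.ndarray  # p x q inter-class correlation matrix
    class_sizes_x: dict[int, int] = field(default_factory=dict)
    class_sizes_y: dict[int, int] = field(default_factory=dict)


def _class_sums(values: np.ndarray, labels: np.ndarray, classes: np.ndarray) -> np.ndarray:
    """Stack per-class column sums (the e_nk indicator products) as rows."""
    return np.stack([values[labels == k].sum(axis=0) for k in classes])


def build_class_matrices(X: FeatureMatrix, Y: FeatureMatrix) -> CorrelationMatrices:
    """Build the scatter, intra-class (Cw) and inter-class (Cb) matrices.

    Cw sums, per class, the outer product of the two views' class-wise column
    sums; Cb is the complement over all cross-class pairs, which reduces to
    ``(1'X)'(1'Y) - Cw`` and hence to ``-Cw`` when both views are
    column-standardized.  The construction is valid for unequal per-class
    counts across the two views.
    """
    cx, cy = set(X.classes.tolist()), set(Y.classes.tolist())
    if cx != cy:
        raise LabelMismatchError(
            f"class sets differ between views: only in X {sorted(cx - cy)}, "
            f"only in Y {sorted(cy - cx)}"
        )
    classes = X.classes
    sx = _class_sums(X.values, X.labels, classes)  # c x p
    sy = _class_sums(Y.values, Y.labels, classes)  # c x q
    Cw = sx.T @ sy
    total = np.outer(X.values.sum(axis=0), Y.values.sum(axis=0))
    Cb = total - Cw
    return CorrelationMatrices(
        C11=X.values.T @ X.values,
        C12=(X.values.T @ Y.values) if X.n_rows == Y.n_rows else None,
        C21=(Y.values.T @ X.values) if X.n_rows == Y.n_rows else None,
        C22=Y.values.T @ Y.values,
        Cw=Cw,
        Cb=Cb,
        class_sizes_x=X.class_counts(),
        class_sizes_y=Y.class_counts(),
    )


@dataclass
class ProjectionPair:
    """Paired loading matrices from a CCA/DCCA fit.

    ``A`` (p x r) and ``B`` (q x r) are ordered by descending eigenvalue
    ``lambda^2``; ``prefix(l)`` returns the first ``l`` loading columns of
    either side, the prefix views the dimension search enumerates.  ``S11``
    and ``S22`` are the (regularized) scatter matrices the unit-scatter
    constraints are taken against.
    """

    A: np.ndarray
    B: np.ndarray
    eigenvalues: np.ndarray  # lambda^2, descending
    r: int
    S11: np.ndarray
    S22: np.ndarray
    method: str = "cca"

    def prefix(self, l: int, side: str = "first") -> np.ndarray:
        if not 1 <= l <= self.r:
            raise ConfigurationError(f"prefix length {l} outside 1..{self.r}")
        M = self.A if side == "first" else self.B
        return M[:, :l]

    def constraint_residuals(self) -> tuple[np.ndarray, np.ndarray]:
        """|A_i' S11 A_i - 1| and |B_i' S22 B_i - 1| per retained pair."""
        ra = np.abs(np.einsum("ir,ij,jr->r", self.A, self.S11, self.A) - 1.0)
        rb = np.abs(np.einsum("ir,ij,jr->r", self.B, self.S22, self.B) - 1.0)
        return ra, rb

    def save(self, path) -> None:
        np.savez(
            path,
            A=self.A,
            B=self.B,
            eigenvalues=self.eigenvalues,
            r=self.r,
            S11=self.S11,
            S22=self.S22,
            method=np.array(self.method),
        )

    @classmethod
    def load(cls, path) -> "ProjectionPair":
        with np.load(path, allow_pickle=False) as z:
            return cls(
                A=z["A"],
                B=z["B"],
                eigenvalues=z["eigenvalues"],
                r=int(z["r"]),
                S11=z["S11"],
                S22=z["S22"],
                method=str(z["method"]),
            )


@dataclass
class CanonicalVariates:
    """Projected views U = X A_l, V = Y B_l and their per-pair correlations."""

    U: np.ndarray
    V: np.ndarray
    correlations: np.ndarray


def _regularized_scatter(values: np.ndarray, ridge: float) -> np.ndarray:
    S = values.T @ values
    if ridge > 0:
        p = S.shape[0]
        S = S + (ridge * np.trace(S) / p) * np.eye(p)
    return S


def _inv_sqrt(S: np.ndarray, what: str) -> np.ndarray:
    w, V = linalg.eigh(S)
    tiny = np.max(w) * 1e-12 if np.max(w) > 0 else 0.0
    if np.min(w) <= tiny:
        raise ConditioningError(
            f"{what} is numerically singular (min eigenvalue {np.min(w):.3e}); "
            "refit with ridge > 0"
        )
    return (V / np.sqrt(w)) @ V.T


def _paired_svd(
    K: np.ndarray,
    S11: np.ndarray,
    S22: np.ndarray,
    method: str,
    rank_tol: float = 1e-9,
) -> ProjectionPair:
    """Solve the whitened problem for cross-operator K and apply conventions.

    Retains ``r = min(min(p, q) - 1, numerical rank of the whitened K)`` pairs
    (at least one), sorted by descending eigenvalue; each pair is sign-fixed so
    the largest-magnitude entry of the A-column is positive (the B-column is
    flipped with it, preserving the objective).
    """
    W1 = _inv_sqrt(S11, "C11")
    W2 = _inv_sqrt(S22, "C22")
    M = W1 @ K @ W2
    U, s, Vt = linalg.svd(M, full_matrices=False)
    p, q = K.shape
    bound = min(p, q) - 1 if min(p, q) > 1 else 1
    rank = int(np.sum(s > s[0] * rank_tol)) if s.size and s[0] > 0 else 1
    r = max(1, min(bound, rank))
    A = W1 @ U[:, :r]
    B = W2 @ Vt[:r].T
    flip = np.where(A[np.abs(A).argmax(axis=0), np.arange(r)] < 0, -1.0, 1.0)
    return ProjectionPair(
        A=A * flip,
        B=B * flip,
        eigenvalues=s[:r] ** 2,
        r=r,
        S11=S11,
        S22=S22,
        method=method,
    )


def fit_cca(X: FeatureMatrix, Y: FeatureMatrix, ridge: float = 0.03) -> ProjectionPair:
    """Classical CCA between two row-paired standardized views.

    The singular values of the whitened cross-scatter are the canonical
    correlations; ``eigenvalues`` holds their squares.
    """
    if X.n_rows != Y.n_rows:
        raise ConfigurationError(
            f"CCA needs row-paired views, got {X.n_rows} vs {Y.n_rows} rows"
        )
    if ridge < 0:
        raise ConfigurationError("ridge must be non-negative")
    S11 = _regularized_scatter(X.values, ridge)
    S22 = _regularized_scatter(Y.values, ridge)
    return _paired_svd(X.values.T @ Y.values, S11, S22, method="cca")


def fit_dcca(
    X: FeatureMatrix,
    Y: FeatureMatrix,
    ridge: float = 0.03,
) -> ProjectionPair:
    """Discriminative CCA between two class-matched standardized views.

    Maximizes ``A' Cw B`` subject to the unit-scatter constraints; because
    ``Cb = -Cw`` for standardized views, this jointly minimizes the
    inter-class correlation.  Row counts of the two views may differ.
    """
    if ridge < 0:
        raise ConfigurationError("ridge must be non-negative")
    mats = build_class_matrices(X, Y)
    if np.linalg.norm(mats.Cw) < 1e-12:
        raise DegenerateDesignError(
            "intra-class correlation matrix is numerically zero; "
            "need >= 2 classes with non-cancelling class means"
        )
    S11 = _regularized_scatter(X.values, ridge)
    S22 = _regularized_scatter(Y.values, ridge)
    return _paired_svd(mats.Cw, S11, S22, method="dcca")


def project(M: FeatureMatrix, P: ProjectionPair, side: str = "first", l: int | None = None) -> np.ndarray:
    """Project a view onto the first ``l`` canonical directions.

    ``side='first'`` uses the A loadings (training-user view), ``'second'``
    uses B (new-user view).  Columns of the result are prefix-consistent: the
    first ``l`` columns for a larger ``l`` are identical.
    """
    if side not in ("first", "second"):
        raise ConfigurationError(f"side must be 'first' or 'second', got {side!r}")
    if l is None:
        l = P.r
    return M.values @ P.prefix(l, side)


def canonical_variates(
    X: FeatureMatrix, Y: FeatureMatrix, P: ProjectionPair, l: int | None = None
) -> CanonicalVariates:
    """Projected variate pair with empirical per-column correlations.

    Correlations require row-paired views (same row count in X and Y).
    """
    if l is None:
        l = P.r
    U = project(X, P, "first", l)
    V = project(Y, P, "second", l)
    corr = np.array(
        [abs(float(np.corrcoef(U[:, i], V[:, i])[0, 1])) for i in range(l)]
    )
    return CanonicalVariates(U=U, V=V, correlations=corr)
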