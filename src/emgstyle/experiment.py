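"""End-to-end framework runs and the study's evaluation designs.

The core routine (:func:`run_framework`) realizes the style-space transfer
chain for one (training user, new user) pair: standardize both views, align
them with discriminative CCA fitted on the pooled training features and the
new user's small calibration set, pick the projection dimension with the
adaptive search, train the final SVM on the projected training features, and
score the new user's held-out test set projected through the second-view
loadings.  On top of it sit the three evaluation designs: leave-one-user-out
(pairwise accuracy matrix), channel dropout on the test users, and the
calibration-size sweep.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, replace, asdict

import numpy as np
import pandas as pd
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .adr import ADRResult, SVMConfig, make_classifier, select_dimension
from .canonical import (
    FeatureMatrix,
    fit_cca,
    fit_dcca,
    standardize_columns,
)
from .errors import ClassCoverageError, ConfigurationError
from .synthgen import drop_channels

logger = logging.getLogger(__name__)

__all__ = [
    "ExperimentConfig",
    "UserDataset",
    "ExperimentReport",
    "run_framework",
    "run_baseline",
    "run_leave_one_user_out",
    "run_channel_dropout",
    "run_calibration_sweep",
]


@dataclass(frozen=True)
class ExperimentConfig:
    """Knobs of the transfer framework and its evaluation harness."""

    method: str = "dcca"  # "dcca" or "cca"
    ridge: float = 0.03
    svm: SVMConfig = field(default_factory=SVMConfig)
    cv_folds: int = 5
    calibration_per_class: int = 8
    pooled_training: bool = False
    majority_vote: bool = False
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class UserDataset:
    """A new user's data split into calibration (Y1) and held-out test (Y2)."""

    calibration: FeatureMatrix
    test: FeatureMatrix
    user_id: str

    def __post_init__(self) -> None:
        missing = set(self.test.classes.tolist()) - set(self.calibration.classes.tolist())
        if missing:
            raise ClassCoverageError(
                f"calibration of {self.user_id} misses classes {sorted(missing)}"
            )

    @classmethod
    def from_feature_matrix(
        cls, fm: FeatureMatrix, calibration_per_class: int = 8, seed: int = 0
    ) -> "UserDataset":
        """Stratified random split: ``calibration_per_class`` rows per class
        go to calibration, the remainder to test."""
        rng = np.random.default_rng(seed)
        cal_mask = np.zeros(fm.n_rows, dtype=bool)
        for k in fm.classes:
            idx = np.flatnonzero(fm.labels == k)
            if idx.size <= calibration_per_class:
                raise ConfigurationError(
                    f"class {k} of {fm.user_id} has {idx.size} rows; "
                    f"cannot reserve {calibration_per_class} for calibration"
                )
            chosen = rng.choice(idx, size=calibration_per_class, replace=False)
            cal_mask[chosen] = True
        return cls(
            calibration=fm.subset(cal_mask),
            test=fm.subset(~cal_mask),
            user_id=fm.user_id,
        )

    def full(self) -> FeatureMatrix:
        """Calibration and test rows concatenated (role as a training user)."""
        groups = None
        if self.calibration.groups is not None and self.test.groups is not None:
            groups = np.concatenate([self.calibration.groups, self.test.groups])
        return replace(
            self.calibration,
            values=np.vstack([self.calibration.values, self.test.values]),
            labels=np.concatenate([self.calibration.labels, self.test.labels]),
            groups=groups,
        )

    def truncate_calibration(self, per_class: int, seed: int = 0) -> "UserDataset":
        """Keep only ``per_class`` calibration rows per class (others unused)."""
        counts = self.calibration.class_counts()
        if per_class > min(counts.values()):
            raise ConfigurationError(
                f"requested {per_class} calibration rows per class, "
                f"only {min(counts.values())} available"
            )
        if per_class == min(counts.values()) and len(set(counts.values())) == 1:
            return self
        rng = np.random.default_rng(seed)
        mask = np.zeros(self.calibration.n_rows, dtype=bool)
        for k in self.calibration.classes:
            idx = np.flatnonzero(self.calibration.labels == k)
            mask[rng.choice(idx, size=per_class, replace=False)] = True
        return replace(self, calibration=self.calibration.subset(mask))


@dataclass
class ExperimentReport:
    """Pairwise accuracy matrix (percent) with per-test-user summaries."""

    accuracy_matrix: pd.DataFrame  # rows: training user, cols: test user, NaN diagonal
    selected_dims: pd.DataFrame
    config: dict
    seed: int

    def per_test_user_mean(self) -> pd.Series:
        return self.accuracy_matrix.mean(axis=0, skipna=True)

    def per_test_user_std(self) -> pd.Series:
        return self.accuracy_matrix.std(axis=0, skipna=True, ddof=1)

    @property
    def mean_accuracy(self) -> float:
        """Grand mean over the per-test-user (per-trial) averages, percent."""
        return float(self.per_test_user_mean().mean())

    def to_csv(self, path) -> None:
        self.accuracy_matrix.to_csv(path)

    def to_json(self, path=None) -> str:
        payload = {
            "accuracy_matrix": self.accuracy_matrix.to_dict(),
            "selected_dims": self.selected_dims.to_dict(),
            "per_test_user_mean": self.per_test_user_mean().to_dict(),
            "per_test_user_std": self.per_test_user_std().to_dict(),
            "mean_accuracy": self.mean_accuracy,
            "config": self.config,
            "seed": self.seed,
        }
        text = json.dumps(payload, indent=2, default=float)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _pair_rows_by_class(X: FeatureMatrix, Y: FeatureMatrix) -> tuple[FeatureMatrix, FeatureMatrix]:
    """Row-pair two class-matched views by truncating each class to the
    smaller per-class count (classical CCA needs matched rows)."""
    keep_x, keep_y = [], []
    for k in X.classes:
        ix = np.flatnonzero(X.labels == k)
        iy = np.flatnonzero(Y.labels == k)
        m = min(ix.size, iy.size)
        keep_x.append(ix[:m])
        keep_y.append(iy[:m])
    mask_x = np.concatenate(keep_x)
    mask_y = np.concatenate(keep_y)
    return X.subset(mask_x), Y.subset(mask_y)


def _fit_projection(X, Y1, config: ExperimentConfig):
    if config.method == "dcca":
        return fit_dcca(X, Y1, ridge=config.ridge)
    if config.method == "cca":
        Xp, Yp = _pair_rows_by_class(X, Y1)
        return fit_cca(Xp, Yp, ridge=config.ridge)
    raise ConfigurationError(f"unknown method {config.method!r}")


def _score(pred: np.ndarray, fm: FeatureMatrix, majority_vote: bool) -> float:
    if majority_vote and fm.groups is not None:
        correct = []
        key = np.stack([fm.labels, fm.groups], axis=1)
        for lab, grp in {tuple(k) for k in key.tolist()}:
            m = (fm.labels == lab) & (fm.groups == grp)
            votes, counts = np.unique(pred[m], return_counts=True)
            correct.append(votes[np.argmax(counts)] == lab)
        return float(np.mean(correct))
    return float(np.mean(pred == fm.labels))


def run_framework(
    train: FeatureMatrix,
    new_user: UserDataset,
    config: ExperimentConfig | None = None,
) -> tuple[ADRResult, float]:
    """One full transfer run; returns the dimension-search result and the
    new user's test accuracy as a fraction.

    The test view is standardized with the calibration set's column
    statistics (the only new-user statistics available at calibration time)
    and projected through the second-view loadings ``B``; the classifier's
    canonical-space scaling for the test side is likewise frozen on the
    projected calibration view.
    """
    config = config or ExperimentConfig()
    missing = set(train.classes.tolist()) - set(new_user.calibration.classes.tolist())
    if missing:
        raise ClassCoverageError(
            f"calibration of {new_user.user_id} misses classes {sorted(missing)}"
        )
    t0 = time.perf_counter()
    Xs, _ = standardize_columns(train)
    Y1s, stats_y = standardize_columns(new_user.calibration)
    P = _fit_projection(Xs, Y1s, config)
    t1 = time.perf_counter()
    adr = select_dimension(
        Xs, P, train.labels, config.svm, config.cv_folds, config.seed
    )
    t2 = time.perf_counter()
    l = adr.selected_l
    U = Xs.values @ P.A[:, :l]
    V1 = Y1s.values @ P.B[:, :l]
    V2 = stats_y.apply(new_user.test).values @ P.B[:, :l]
    scaler_u = StandardScaler().fit(U)
    svc = SVC(kernel=config.svm.kernel, C=config.svm.C, gamma=config.svm.gamma)
    svc.fit(scaler_u.transform(U), train.labels)
    scaler_v = StandardScaler().fit(V1)
    pred = svc.predict(scaler_v.transform(V2))
    acc = _score(pred, new_user.test, config.majority_vote)
    logger.info(
        "run_framework %s->%s: fit %.2fs adr %.2fs l*=%d acc=%.3f",
        train.user_id or "train",
        new_user.user_id,
        t1 - t0,
        t2 - t1,
        l,
        acc,
    )
    return adr, acc


def run_baseline(
    train: FeatureMatrix,
    new_user: UserDataset,
    config: ExperimentConfig | None = None,
) -> float:
    """No-adaptation baseline: SVM on raw standardized training features,
    scored on the new user's test set (standardized with calibration stats)."""
    config = config or ExperimentConfig()
    Xs, _ = standardize_columns(train)
    _, stats_y = standardize_columns(new_user.calibration)
    clf = make_classifier(config.svm)
    clf.fit(Xs.values, train.labels)
    pred = clf.predict(stats_y.apply(new_user.test).values)
    return _score(pred, new_user.test, config.majority_vote)


def _pooled_train(users: dict[str, UserDataset], exclude: str) -> FeatureMatrix:
    parts = [u.full() for uid, u in users.items() if uid != exclude]
    fm = FeatureMatrix(
        values=np.vstack([p.values for p in parts]),
        labels=np.concatenate([p.labels for p in parts]),
        column_names=parts[0].column_names,
        user_id="pooled",
        n_channels=parts[0].n_channels,
    )
    return fm.sorted_by_class()


def run_leave_one_user_out(
    users: dict[str, UserDataset],
    config: ExperimentConfig | None = None,
    baseline: bool = False,
) -> ExperimentReport:
    """Each user in turn is the new user; every other user (or the pooled
    remainder, with ``config.pooled_training``) supplies training data.

    With pairwise training and ``m`` users the accuracy matrix has
    ``m * (m - 1)`` defined off-diagonal entries, as percentages.  With
    ``baseline=True`` the no-adaptation SVM is run instead of the framework.
    """
    config = config or ExperimentConfig()
    if len(users) < 3:
        raise ConfigurationError("leave-one-user-out needs at least 3 users")
    ids = list(users)
    rows = ["pooled"] if config.pooled_training else ids
    acc = pd.DataFrame(np.nan, index=rows, columns=ids)
    dims = pd.DataFrame(np.nan, index=rows, columns=ids)
    for test_id in ids:
        new_user = users[test_id]
        if config.pooled_training:
            train_sets = {"pooled": _pooled_train(users, exclude=test_id)}
        else:
            train_sets = {
                uid: users[uid].full().sorted_by_class() for uid in ids if uid != test_id
            }
        for train_id, train_fm in train_sets.items():
            if baseline:
                a = run_baseline(train_fm, new_user, config)
            else:
                adr, a = run_framework(train_fm, new_user, config)
                dims.loc[train_id, test_id] = adr.selected_l
            acc.loc[train_id, test_id] = 100.0 * a
    return ExperimentReport(
        accuracy_matrix=acc,
        selected_dims=dims,
        config=config.to_dict() | {"baseline": baseline},
        seed=config.seed,
    )


def run_channel_dropout(
    users: dict[str, UserDataset],
    n_drop: int = 2,
    config: ExperimentConfig | None = None,
    seed: int = 0,
) -> ExperimentReport:
    """Leave-one-user-out with ``n_drop`` channels removed from every test
    user's calibration and test views (training views keep all channels).

    Channel choice is random per test user but identical between that user's
    calibration and test views; the projections are refitted on the reduced
    view, which DCCA supports because the two views may have different
    dimensionalities."""
    config = config or ExperimentConfig()
    reduced: dict[str, UserDataset] = {}
    for i, (uid, u) in enumerate(users.items()):
        ch_seed = (seed * 1009 + i) % (2**31)
        reduced[uid] = UserDataset(
            calibration=drop_channels(u.calibration, n_drop, seed=ch_seed),
            test=drop_channels(u.test, n_drop, seed=ch_seed),
            user_id=uid,
        )
    # training users keep the full-channel views of the original datasets
    ids = list(users)
    rows = ["pooled"] if config.pooled_training else ids
    acc = pd.DataFrame(np.nan, index=rows, columns=ids)
    dims = pd.DataFrame(np.nan, index=rows, columns=ids)
    for test_id in ids:
        new_user = reduced[test_id]
        if config.pooled_training:
            train_sets = {"pooled": _pooled_train(users, exclude=test_id)}
        else:
            train_sets = {
                uid: users[uid].full().sorted_by_class() for uid in ids if uid != test_id
            }
        for train_id, train_fm in train_sets.items():
            adr, a = run_framework(train_fm, new_user, config)
            acc.loc[train_id, test_id] = 100.0 * a
            dims.loc[train_id, test_id] = adr.selected_l
    return ExperimentReport(
        accuracy_matrix=acc,
        selected_dims=dims,
        config=config.to_dict() | {"n_drop": n_drop, "dropout_seed": seed},
        seed=config.seed,
    )


def run_calibration_sweep(
    users: dict[str, UserDataset],
    sizes=range(3, 11),
    config: ExperimentConfig | None = None,
) -> pd.DataFrame:
    """Accuracy and selected dimension as the calibration size grows.

    For every calibration size the full leave-one-user-out design is re-run
    with each test user's calibration truncated to that many repetitions per
    class.  A calibration-only baseline (classifier trained directly on the
    truncated calibration data, no transfer) is reported alongside.
    """
    config = config or ExperimentConfig()
    records = []
    for size in sizes:
        trunc = {
            uid: u.truncate_calibration(size, seed=config.seed)
            for uid, u in users.items()
        }
        report = run_leave_one_user_out(trunc, config)
        tccd = []
        for uid, u in trunc.items():
            clf = make_classifier(config.svm)
            cal_s, stats = standardize_columns(u.calibration)
            clf.fit(cal_s.values, u.calibration.labels)
            pred = clf.predict(stats.apply(u.test).values)
            tccd.append(100.0 * _score(pred, u.test, config.majority_vote))
        records.append(
            {
                "calibration_per_class": int(size),
                "accuracy": report.mean_accuracy,
                "selected_l": float(np.nanmean(report.selected_dims.to_numpy())),
                "tccd_accuracy": float(np.mean(tccd)),
            }
        )
    return pd.DataFrame.from_records(records)
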