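"""Training: dataset split, activity classifier, and the two HR regressors.

The classifier is a multiclass AdaBoost (SAMME) ensemble of depth-limited
trees (defaults: 492 learners, learning rate 0.34449, 204-split cap).  The
regressors are a Gaussian process with constant basis and isotropic
exponential kernel (B1) and a bagged-trees ensemble (B2: 14 learners,
minimum leaf size 3).  GP kernel hyperparameters start from the tuned
defaults and are refit by marginal-likelihood maximization.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
from sklearn.base import clone
from sklearn.ensemble import AdaBoostClassifier, BaggingRegressor
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern, WhiteKernel
from sklearn.model_selection import StratifiedKFold, KFold
from sklearn.tree import DecisionTreeClassifier, DecisionTreeRegressor

from .features import NormStats, WindowTable
from .select import SelectionResult

log = logging.getLogger(__name__)

__all__ = ["TrainedBundle", "split_dataset", "train_classifier", "train_regressors",
           "save_bundle", "load_bundle"]


@dataclass
class TrainedBundle:
    """Fitted classifier + regressors with everything needed for inference."""

    classifier: object
    regressor_b1: object
    regressor_b2: object
    norm_stats: NormStats
    selection_clf: SelectionResult
    selection_reg: SelectionResult
    metadata: dict = field(default_factory=dict)

    def classifier_features(self, X: np.ndarray) -> np.ndarray:
        return X[:, self.selection_clf.selected_indices]

    def regressor_features(self, X: np.ndarray) -> np.ndarray:
        return X[:, self.selection_reg.selected_indices]


def split_dataset(table: WindowTable, cfg=None, seed: int | None = None):
    """Seeded shuffle and stratified 70/30 partition by task class."""
    from .session_io import PipelineConfig

    if cfg is None:
        cfg = PipelineConfig()
    if len(table) == 0:
        raise ValueError("cannot split an empty table")
    if seed is None:
        seed = cfg.seed
    rng = np.random.default_rng(seed)
    y = table.label_task
    train_idx: list[int] = []
    test_idx: list[int] = []
    for cls in np.unique(y):
        pool = np.flatnonzero(y == cls)
        rng.shuffle(pool)
        n_train = int(round(cfg.split_fraction * len(pool)))
        if n_train == 0 or n_train == len(pool):
            log.warning("class %s has only %d windows; split is degenerate", cls, len(pool))
            n_train = min(max(n_train, 1), len(pool) - 1) if len(pool) > 1 else len(pool)
        train_idx.extend(pool[:n_train])
        test_idx.extend(pool[n_train:])
    train_idx, test_idx = np.sort(train_idx), np.sort(test_idx)
    train = WindowTable(table.df.iloc[train_idx].reset_index(drop=True), table.catalogue)
    test = WindowTable(table.df.iloc[test_idx].reset_index(drop=True), table.catalogue)
    return train, test


def train_classifier(
    train: WindowTable,
    selection: SelectionResult,
    cfg=None,
    *,
    cv: bool = True,
):
    """Fit the AdaBoost activity classifier on the selected feature columns.

    Returns ``(classifier, cv_accuracy)``; ``cv_accuracy`` is the 5-fold
    cross-validated accuracy on the training split (None when ``cv`` is off).
    """
    from .session_io import PipelineConfig

    if cfg is None:
        cfg = PipelineConfig()
    X = train.features[:, selection.selected_indices]
    y = train.label_task
    clf = AdaBoostClassifier(
        estimator=DecisionTreeClassifier(
            max_leaf_nodes=cfg.clf_max_splits + 1, random_state=cfg.seed
        ),
        n_estimators=cfg.clf_n_learners,
        learning_rate=cfg.clf_learning_rate,
        random_state=cfg.seed,
    )
    cv_acc = None
    if cv:
        if len(train) < cfg.cv_folds:
            raise ValueError(f"fewer windows ({len(train)}) than CV folds ({cfg.cv_folds})")
        skf = StratifiedKFold(n_splits=cfg.cv_folds, shuffle=True, random_state=cfg.seed)
        scores = []
        for tr, va in skf.split(X, y):
            m = clone(clf).fit(X[tr], y[tr])
            scores.append(float(np.mean(m.predict(X[va]) == y[va])))
        cv_acc = float(np.mean(scores))
        log.info("classifier %d-fold CV accuracy: %.4f", cfg.cv_folds, cv_acc)
    clf.fit(X, y)
    return clf, cv_acc


def _rmse(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean((np.asarray(a) - np.asarray(b)) ** 2)))


def train_regressors(
    train: WindowTable,
    selection: SelectionResult,
    cfg=None,
    *,
    cv: bool = True,
    max_gp_samples: int = 800,
):
    """Fit the two HR regressors on the selected feature columns.

    B1 is a Gaussian process (constant mean via target normalization,
    isotropic exponential kernel initialized at the tuned scale/variance/
    noise values, refit by marginal likelihood); its training set is capped
    at ``max_gp_samples`` seeded random rows to bound the cubic cost.  B2 is
    a bagged regression-tree ensemble.  Returns
    ``(regressor_b1, regressor_b2, cv_rmse)`` with per-model CV RMSE.
    """
    from .session_io import PipelineConfig

    if cfg is None:
        cfg = PipelineConfig()
    X = train.features[:, selection.selected_indices]
    y = train.label_hr
    if np.any(~np.isfinite(y)) or np.any(y <= 0):
        raise ValueError("regression labels must be finite positive bpm values")

    kernel = (
        ConstantKernel(cfg.gp_signal_sd**2, (1e-3, 1e6))
        * Matern(length_scale=cfg.gp_kernel_scale, length_scale_bounds=(1e-3, 1e4), nu=0.5)
        + WhiteKernel(cfg.gp_noise_sigma**2, (1e-6, 1e6))
    )

    def make_gp():
        return GaussianProcessRegressor(
            kernel=kernel, normalize_y=True, random_state=cfg.seed
        )

    def make_bag():
        return BaggingRegressor(
            estimator=DecisionTreeRegressor(
                min_samples_leaf=cfg.bag_min_leaf, random_state=cfg.seed
            ),
            n_estimators=cfg.bag_n_learners,
            random_state=cfg.seed,
        )

    rng = np.random.default_rng(cfg.seed)

    def gp_subset(idx: np.ndarray) -> np.ndarray:
        if len(idx) > max_gp_samples:
            return np.sort(rng.choice(idx, size=max_gp_samples, replace=False))
        return idx

    cv_rmse = {}
    if cv:
        if len(train) < cfg.cv_folds:
            raise ValueError(f"fewer windows ({len(train)}) than CV folds ({cfg.cv_folds})")
        kf = KFold(n_splits=cfg.cv_folds, shuffle=True, random_state=cfg.seed)
        gp_scores, bag_scores = [], []
        for tr, va in kf.split(X):
            sub = gp_subset(tr)
            gp = make_gp().fit(X[sub], y[sub])
            gp_scores.append(_rmse(gp.predict(X[va]), y[va]))
            bag = make_bag().fit(X[tr], y[tr])
            bag_scores.append(_rmse(bag.predict(X[va]), y[va]))
        cv_rmse = {"b1": float(np.mean(gp_scores)), "b2": float(np.mean(bag_scores))}
        log.info("regressor CV RMSE: B1=%.3f bpm, B2=%.3f bpm", *cv_rmse.values())

    all_idx = np.arange(len(y))
    b1 = make_gp().fit(X[gp_subset(all_idx)], y[gp_subset(all_idx)])
    b2 = make_bag().fit(X, y)
    return b1, b2, cv_rmse


def save_bundle(bundle: TrainedBundle, path: str | Path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    joblib.dump(
        {
            "classifier": bundle.classifier,
            "regressor_b1": bundle.regressor_b1,
            "regressor_b2": bundle.regressor_b2,
            "norm_stats": bundle.norm_stats,
            "selection_clf": bundle.selection_clf,
            "selection_reg": bundle.selection_reg,
        },
        path / "bundle.joblib",
    )
    (path / "metadata.json").write_text(json.dumps(bundle.metadata, indent=2, default=str))


def load_bundle(path: str | Path) -> TrainedBundle:
    path = Path(path)
    blob = joblib.load(path / "bundle.joblib")
    meta = json.loads((path / "metadata.json").read_text())
    return TrainedBundle(metadata=meta, **blob)
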