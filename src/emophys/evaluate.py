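"""Cross-validated evaluation of the reduction + classification pipeline.

Runs stratified 10-fold cross-validation of the variance filter ->
standardisation -> kernel PCA -> GBDT chain over a FeatureTable, reporting
pooled accuracy (fraction of all held-out samples classified correctly),
per-fold accuracy, per-emotion recall and the confusion matrix.

Two leakage modes: "strict" (default) fits every step — variance mask,
standardisation, KPCA, classifier — on the training rows of each fold only;
"prefit" fits the variance filter and KPCA once on the full table
before splitting, the historically common but optimistic ordering.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold, StratifiedKFold

from . import gbdt, kpca
from .features import variance_filter, apply_mask

SIGNAL_PREFIXES = {"ECG": "ECG_", "GSR": "GSR_", "EMG": "EMG_", "PPG": "PPG_",
                   "Total": ""}


@dataclass
class PipelineConfig:
    """Configuration of one cross-validated pipeline run."""

    signals: str = "Total"            # ECG | GSR | EMG | PPG | Total
    reducer: str = "kpca"             # "kpca" | "none"
    n_components: int | None = None   # None -> number of training samples
    sigma: float | None = None        # None -> gamma = 1/(d var) rule
    variance_threshold: float = 0.8 * (1 - 0.8)
    learning_rate: float = 0.1
    n_estimators: int = 200
    max_depth: int = 4
    max_features: int | None = 30
    k_folds: int = 10
    stratified: bool = True
    leakage_mode: str = "strict"      # "strict" | "prefit"
    seed: int = 0

    def to_dict(self) -> dict[str, Any]:
        return dict(self.__dict__)


@dataclass
class CVResult:
    fold_accuracies: list[float]
    overall_accuracy: float           # pooled over folds
    mean_fold_accuracy: float
    per_class_accuracy: dict[str, float]
    confusion: pd.DataFrame           # rows true, columns predicted
    config: dict[str, Any]
    seed: int
    n_samples: int = 0
    predictions: pd.Series | None = field(default=None, repr=False)


def kfold_split(labels, k: int = 10, seed: int = 0,
                stratified: bool = True) -> np.ndarray:
    """Fold assignment per sample; stratified folds balance every class."""
    labels = np.asarray(labels)
    n = labels.size
    if k < 2 or k > n:
        raise ValueError("k must lie in [2, n_samples]")
    if stratified:
        _, counts = np.unique(labels, return_counts=True)
        if counts.min() < k:
            raise ValueError(
                f"smallest class has {counts.min()} samples < k={k}; reduce k")
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    else:
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    folds = np.empty(n, dtype=int)
    for f, (_, test_idx) in enumerate(splitter.split(np.zeros((n, 1)), labels)):
        folds[test_idx] = f
    return folds


def _select_signal(table: pd.DataFrame, signals: str) -> pd.DataFrame:
    if signals not in SIGNAL_PREFIXES:
        raise ValueError(f"signals must be one of {sorted(SIGNAL_PREFIXES)}")
    prefix = SIGNAL_PREFIXES[signals]
    cols = [c for c in table.columns if c != "emotion" and c.startswith(prefix)]
    return table[cols + ["emotion"]]


def _fit_predict_fold(X_train, y_train, X_test, cfg: PipelineConfig,
                      fold_seed: int):
    if cfg.reducer == "kpca":
        model = kpca.fit(X_train, sigma=cfg.sigma,
                         n_components=min(cfg.n_components or len(X_train),
                                          len(X_train)))
        Z_train = kpca.transform(model, X_train)
        Z_test = kpca.transform(model, X_test)
    elif cfg.reducer == "none":
        mu, sd = X_train.mean(axis=0), X_train.std(axis=0)
        sd = np.where(sd > 1e-12, sd, 1.0)
        Z_train, Z_test = (X_train - mu) / sd, (X_test - mu) / sd
    else:
        raise ValueError(f"unknown reducer {cfg.reducer!r}")
    clf = gbdt.fit(Z_train, y_train, learning_rate=cfg.learning_rate,
                   n_estimators=cfg.n_estimators, max_depth=cfg.max_depth,
                   max_features=cfg.max_features, seed=fold_seed)
    return gbdt.predict(clf, Z_test)


def cross_validate(feature_table: pd.DataFrame,
                   config: PipelineConfig | None = None) -> CVResult:
    """K-fold cross-validation of the configured pipeline over a FeatureTable."""
    cfg = config or PipelineConfig()
    table = _select_signal(feature_table, cfg.signals)
    y = table["emotion"].to_numpy()
    classes = np.unique(y)
    folds = kfold_split(y, k=cfg.k_folds, seed=cfg.seed, stratified=cfg.stratified)

    if cfg.leakage_mode == "prefit":
        filtered, _ = variance_filter(table, cfg.variance_threshold)
        X_all = filtered.drop(columns=["emotion"]).to_numpy(dtype=float)
        if cfg.reducer == "kpca":
            model, _ = kpca.fit_transform(X_all, sigma=cfg.sigma,
                                          n_components=cfg.n_components)
            X_all = kpca.transform(model, X_all)
    elif cfg.leakage_mode != "strict":
        raise ValueError("leakage_mode must be 'strict' or 'prefit'")

    pred = np.empty(len(table), dtype=object)
    fold_acc: list[float] = []
    for f in range(cfg.k_folds):
        train, test = folds != f, folds == f
        if np.unique(y[train]).size < classes.size:
            raise ValueError("a class is absent from a training fold; reduce k")
        fold_seed = cfg.seed * 1009 + f
        if cfg.leakage_mode == "prefit":
            clf = gbdt.fit(X_all[train], y[train], learning_rate=cfg.learning_rate,
                           n_estimators=cfg.n_estimators, max_depth=cfg.max_depth,
                           max_features=cfg.max_features, seed=fold_seed)
            yhat = gbdt.predict(clf, X_all[test])
        else:
            train_tab = table.iloc[np.nonzero(train)[0]]
            filtered, mask = variance_filter(train_tab, cfg.variance_threshold)
            X_train = filtered.drop(columns=["emotion"]).to_numpy(dtype=float)
            test_tab = apply_mask(table.iloc[np.nonzero(test)[0]], mask)
            X_test = test_tab.drop(columns=["emotion"]).to_numpy(dtype=float)
            yhat = _fit_predict_fold(X_train, y[train], X_test, cfg, fold_seed)
        pred[test] = yhat
        fold_acc.append(float(np.mean(yhat == y[test])))

    correct = pred == y
    confusion = pd.crosstab(pd.Series(y, name="true"),
                            pd.Series(pred, name="predicted"),
                            dropna=False).reindex(index=classes, columns=classes,
                                                  fill_value=0)
    per_class = {c: float(np.mean(pred[y == c] == c)) for c in classes}
    return CVResult(
        fold_accuracies=fold_acc,
        overall_accuracy=float(np.mean(correct)),
        mean_fold_accuracy=float(np.mean(fold_acc)),
        per_class_accuracy=per_class,
        confusion=confusion,
        config=cfg.to_dict(),
        seed=cfg.seed,
        n_samples=len(table),
        predictions=pd.Series(pred, index=feature_table.index, name="predicted"),
    )


def grid_search(feature_table: pd.DataFrame, grid: dict[str, list],
                base_config: PipelineConfig | None = None) -> pd.DataFrame:
    """One cross-validated run per grid point; returns a tidy results table.

    ``grid`` maps PipelineConfig field names (e.g. ``learning_rate``,
    ``n_estimators``, ``max_depth``, ``max_features``, ``n_components``) to
    candidate value lists.
    """
    base = (base_config or PipelineConfig()).to_dict()
    keys = sorted(grid)
    rows = []
    for combo in itertools.product(*(grid[k] for k in keys)):
        params = dict(base)
        params.update(dict(zip(keys, combo)))
        result = cross_validate(feature_table, PipelineConfig(**params))
        row = {k: params[k] for k in keys}
        row["accuracy"] = result.overall_accuracy
        row["mean_fold_accuracy"] = result.mean_fold_accuracy
        rows.append(row)
    return pd.DataFrame(rows)


def correlation_matrix(feature_table: pd.DataFrame,
                       method: str = "pearson") -> pd.DataFrame:
    """Pairwise feature correlations (Pearson, or Spearman = Pearson of ranks)."""
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    feats = feature_table.drop(columns=["emotion"], errors="ignore")
    return feats.corr(method=method)
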