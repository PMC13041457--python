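"""Cluster-vs-control discrimination: SMOTE, random-forest grid search, SHAP.

Each identified cluster yields one independent binary problem: its cycles
(label 1) against the control cycles (label 0).  Because clusters are small
relative to the control pool, the minority class is rebalanced with SMOTE —
synthetic minority rows interpolated between nearest minority neighbours —
rather than duplicated.  A random-forest classifier is then grid-searched
with 10-fold stratified cross-validation, and the best model is explained
with path-dependent TreeSHAP attributions ranked by mean |SHAP|.

The replication-faithful default applies SMOTE once, before cross-validation,
which lets synthetic neighbours of a training point appear in validation
folds; ``safe_resampling=True`` instead applies SMOTE inside each training
fold, which is the leakage-free variant.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import NearestNeighbors

from .treeshap import ShapSummary, forest_shap_values

#: Hyperparameter grid searched for every cluster model, in deterministic
#: order: trees x max_features x depth x split criterion (54 configurations).
RF_GRID = {
    "n_estimators": (200, 500, 1000),
    "max_features": ("sqrt", "log2"),
    "max_depth": (10, 15, 20),
    "criterion": ("gini", "entropy", "log_loss"),
}


class SmoteConfigError(ValueError):
    """SMOTE configuration incompatible with the data."""


@dataclass(frozen=True)
class SmoteConfig:
    """SMOTE settings: ``k_neighbors`` candidate neighbours per sample."""

    k_neighbors: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise SmoteConfigError("k_neighbors must be >= 1")


def smote_balance(table: pd.DataFrame, cfg: SmoteConfig | None = None) -> pd.DataFrame:
    """Balance a labeled feature table by synthesizing minority rows.

    Each synthetic row is ``x + u * (x_nn - x)`` with ``u ~ Uniform(0, 1)``
    and ``x_nn`` one of the ``k`` nearest minority neighbours of a randomly
    chosen minority row ``x`` (Euclidean distance in feature space).
    Original rows are preserved verbatim; synthetic rows get index labels
    ``smote_<i>``.
    """
    if cfg is None:
        cfg = SmoteConfig()
    if "label" not in table.columns:
        raise ValueError("feature table must have a 'label' column")
    y = table["label"].to_numpy()
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("need exactly two classes to rebalance")
    minority = classes[np.argmin(counts)]
    n_min, n_maj = counts.min(), counts.max()
    if n_min == n_maj:
        return table.copy()
    if n_min <= cfg.k_neighbors:
        raise SmoteConfigError(
            f"minority class has {n_min} rows <= k_neighbors="
            f"{cfg.k_neighbors}; lower k_neighbors"
        )
    feats = table.drop(columns="label")
    Xmin = feats[y == minority].to_numpy(dtype=float)
    nn = NearestNeighbors(n_neighbors=cfg.k_neighbors + 1).fit(Xmin)
    _, idx = nn.kneighbors(Xmin)  # column 0 is the point itself
    rng = np.random.default_rng(cfg.seed)
    n_new = n_maj - n_min
    base = rng.integers(0, n_min, size=n_new)
    pick = rng.integers(1, cfg.k_neighbors + 1, size=n_new)
    u = rng.random(n_new)
    neighbors = Xmin[idx[base, pick]]
    synthetic = Xmin[base] + u[:, None] * (neighbors - Xmin[base])
    extra = pd.DataFrame(synthetic, columns=feats.columns,
                         index=[f"smote_{i}" for i in range(n_new)])
    extra["label"] = minority
    return pd.concat([table, extra])


def _grid_configs(grid: dict | None = None) -> list[dict]:
    grid = dict(RF_GRID if grid is None else grid)
    keys = list(grid)
    return [dict(zip(keys, combo))
            for combo in itertools.product(*(grid[k] for k in keys))]


@dataclass(frozen=True)
class GridSearchReport:
    """Per-configuration CV accuracies and the selected configuration."""

    table: pd.DataFrame           # one row per configuration + mean_cv_accuracy
    best_params: dict
    best_accuracy: float
    seed: int
    safe_resampling: bool = False

    @property
    def n_configs(self) -> int:
        return len(self.table)


def _make_rf(params: dict, seed: int) -> RandomForestClassifier:
    return RandomForestClassifier(random_state=seed, n_jobs=1, **params)


def train_rf_grid(
    table: pd.DataFrame,
    seed: int = 0,
    grid: dict | None = None,
    n_folds: int = 10,
    safe_resampling: bool = False,
    smote_cfg: SmoteConfig | None = None,
) -> tuple[GridSearchReport, RandomForestClassifier]:
    """Grid-search a random forest with stratified cross-validation.

    With the default ``safe_resampling=False`` the caller is expected to pass
    an already-balanced table (the replication pipeline applies
    :func:`smote_balance` first).  With ``safe_resampling=True`` the table
    should be the raw imbalanced one and SMOTE is fit inside each training
    fold.  Ties in mean CV accuracy resolve to the first configuration in
    deterministic grid order.  The best configuration is refit on the full
    (balanced) table and returned.
    """
    if "label" not in table.columns:
        raise ValueError("feature table must have a 'label' column")
    y = table["label"].to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("need both classes present to train")
    X = table.drop(columns="label")
    configs = _grid_configs(grid)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(X, y))
    if smote_cfg is None:
        smote_cfg = SmoteConfig(seed=seed)

    rows = []
    best_i, best_acc = 0, -np.inf
    for i, params in enumerate(configs):
        accs = []
        for tr, te in folds:
            if safe_resampling:
                balanced = smote_balance(table.iloc[tr], smote_cfg)
                Xtr = balanced.drop(columns="label").to_numpy()
                ytr = balanced["label"].to_numpy()
            else:
                Xtr, ytr = X.to_numpy()[tr], y[tr]
            clf = _make_rf(params, seed)
            clf.fit(Xtr, ytr)
            accs.append(clf.score(X.to_numpy()[te], y[te]))
        mean_acc = float(np.mean(accs))
        rows.append({**params, "mean_cv_accuracy": mean_acc})
        if mean_acc > best_acc:
            best_acc, best_i = mean_acc, i

    best_params = configs[best_i]
    if safe_resampling:
        balanced = smote_balance(table, smote_cfg)
        Xfit = balanced.drop(columns="label").to_numpy()
        yfit = balanced["label"].to_numpy()
    else:
        Xfit, yfit = X.to_numpy(), y
    model = _make_rf(best_params, seed).fit(Xfit, yfit)
    report = GridSearchReport(
        table=pd.DataFrame(rows),
        best_params=best_params,
        best_accuracy=best_acc,
        seed=seed,
        safe_resampling=safe_resampling,
    )
    return report, model


def explain_shap(model: RandomForestClassifier,
                 table: pd.DataFrame) -> ShapSummary:
    """Path-dependent TreeSHAP attributions in positive-class probability space.

    Local accuracy holds row-wise: base value plus the attribution sum equals
    the model's predicted probability of class 1 (to numerical precision).
    """
    X = table.drop(columns="label") if "label" in table.columns else table
    if X.shape[1] != model.n_features_in_:
        raise ValueError(
            f"model expects {model.n_features_in_} features, table has "
            f"{X.shape[1]}"
        )
    phi, base = forest_shap_values(model, X.to_numpy(dtype=float))
    return ShapSummary(
        feature_names=tuple(X.columns), local=phi, base_value=base
    )
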