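"""Leakage-safe repeated stratified k-fold benchmark of feature selectors.

Compares the component-frequency selector ("ours") against standard
selectors — top-|coefficient| LASSO selection, recursive feature
elimination, variance thresholding — plus two no-selection baselines (all
features with and without a PCA embedding), across six classifier families
(L1 logistic, linear SVM, MLP, XGBoost, random forest, ridge logistic) at
library-default hyperparameters.

Protocol: for each trial a fresh stratified k-fold partition is drawn; for
each fold, feature selection, PCA and model fitting all run on the training
rows only, and the held-out fold is scored by ROC AUC.  The default
protocol is 100 trials of 10-fold cross-validation; test suites scale this
down.  All selector/model cells of one comparison share identical fold
partitions, so differences are paired.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score, roc_curve

from .feature_space import ComponentRegistry, FeatureTable, registry_from_keys
from .selection import SelectorParams, fit_pca_embed, run_selector

logger = logging.getLogger(__name__)

__all__ = [
    "SELECTOR_NAMES",
    "MODEL_NAMES",
    "CVResult",
    "BenchmarkResult",
    "make_partitions",
    "select_features",
    "run_cv",
    "compare_table",
    "roc_points",
]

SELECTOR_NAMES = ("ours", "lasso_topk", "rfe", "variance", "all_pca", "all")
MODEL_NAMES = ("lasso", "svm", "mlp", "xgboost", "rf", "lr")

# which selectors are followed by a PCA embedding
_SELECTOR_USES_PCA = {
    "ours": True, "lasso_topk": True, "rfe": True, "variance": True,
    "all_pca": True, "all": False,
}


@dataclass
class CVResult:
    """One (selector, model) cell of the benchmark."""

    selector: str
    model: str
    fold_scores: np.ndarray  # (trials, folds)
    roc: tuple[np.ndarray, np.ndarray] | None = None

    @property
    def mean_auc(self) -> float:
        return float(self.fold_scores.mean())

    @property
    def sd_over_folds(self) -> float:
        return float(self.fold_scores.std())

    @property
    def sd_over_trials(self) -> float:
        """Spread of per-trial mean AUCs (the conventional +- number)."""
        return float(self.fold_scores.mean(axis=1).std())


@dataclass
class BenchmarkResult:
    """Grid of CV cells on shared partitions, plus the run configuration."""

    cells: dict[tuple[str, str], CVResult]
    selectors: tuple[str, ...]
    models: tuple[str, ...]
    config: dict = field(default_factory=dict)

    def mean_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [[self.cells[(s, m)].mean_auc for m in self.models] for s in self.selectors],
            index=list(self.selectors),
            columns=list(self.models),
        )

    def sd_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [[self.cells[(s, m)].sd_over_trials for m in self.models] for s in self.selectors],
            index=list(self.selectors),
            columns=list(self.models),
        )

    def to_text(self) -> str:
        mean, sd = self.mean_table(), self.sd_table()
        body = mean.round(3).astype(str) + " ±" + sd.round(3).astype(str)
        return body.to_string()

    def to_json_dict(self) -> dict:
        return {
            "selectors": list(self.selectors),
            "models": list(self.models),
            "mean_auc": {s: {m: self.cells[(s, m)].mean_auc for m in self.models} for s in self.selectors},
            "sd_over_trials": {
                s: {m: self.cells[(s, m)].sd_over_trials for m in self.models} for s in self.selectors
            },
            "sd_over_folds": {
                s: {m: self.cells[(s, m)].sd_over_folds for m in self.models} for s in self.selectors
            },
            "config": self.config,
        }

    def write_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json_dict(), fh, indent=2)


# ---------------------------------------------------------------------------
# Partitions
# ---------------------------------------------------------------------------

def make_partitions(
    labels: np.ndarray, trials: int, folds: int, seed: int
) -> list[list[tuple[np.ndarray, np.ndarray]]]:
    """Stratified k-fold partitions for each trial; shared by all cells.

    The fold count is reduced (with a warning) when the smaller class has
    fewer members than folds.
    """
    from sklearn.model_selection import StratifiedKFold

    labels = np.asarray(labels)
    smallest = int(np.bincount(labels).min())
    if smallest < 2:
        raise ValueError("need at least 2 subjects in each class")
    if smallest < folds:
        logger.warning("reducing folds from %d to %d (smallest class)", folds, smallest)
        folds = smallest
    out = []
    for t in range(trials):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=(seed + t) % (2**31))
        out.append([(tr.copy(), te.copy()) for tr, te in skf.split(np.zeros(len(labels)), labels)])
    return out


# ---------------------------------------------------------------------------
# Baseline selectors
# ---------------------------------------------------------------------------

def _standardize_train(X: np.ndarray) -> np.ndarray:
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


def _lasso_topk(X: np.ndarray, y: np.ndarray, k: int, seed: int) -> np.ndarray:
    model = LogisticRegression(l1_ratio=1.0, C=1.0, solver="liblinear", random_state=seed % (2**31))
    model.fit(_standardize_train(X), y)
    coefs = np.abs(model.coef_[0])
    # largest-coefficient features first; if fewer than k are nonzero the
    # remainder is padded by the next-largest magnitudes (i.e. plain top-k)
    order = np.argsort(-coefs, kind="stable")
    return np.sort(order[:k])


def _rfe(X: np.ndarray, y: np.ndarray, k: int, seed: int) -> np.ndarray:
    from sklearn.feature_selection import RFE

    est = LogisticRegression(max_iter=1000)
    rfe = RFE(est, n_features_to_select=k, step=0.1)
    rfe.fit(_standardize_train(X), y)
    return np.flatnonzero(rfe.support_)


def _variance_topk(X: np.ndarray, y: np.ndarray, k: int, seed: int) -> np.ndarray:
    var = X.var(axis=0)
    order = np.argsort(-var, kind="stable")
    return np.sort(order[:k])


def select_features(
    name: str,
    X_train: np.ndarray,
    y_train: np.ndarray,
    table: FeatureTable,
    registry: ComponentRegistry,
    seed: int,
    k: int = 288,
    selector_params: SelectorParams | None = None,
    train_rows: np.ndarray | None = None,
) -> tuple[np.ndarray, object | None]:
    """Run one named selector on training data only.

    Returns (column indices, fitted selector artifact or None).  ``k`` is
    the forced selection size for the baselines; "ours" determines its size
    from the component counts (288 at the default (3, 3, 4, 8)).
    """
    p = X_train.shape[1]
    if name in ("lasso_topk", "rfe", "variance") and k > p:
        raise ValueError(f"cannot select k={k} from {p} features")
    if name == "ours":
        params = selector_params or SelectorParams()
        result = run_selector(table, train_rows, params=params, registry=registry, seed=seed)
        return np.asarray(result.columns), result
    if name == "lasso_topk":
        return _lasso_topk(X_train, y_train, k, seed), None
    if name == "rfe":
        return _rfe(X_train, y_train, k, seed), None
    if name == "variance":
        return _variance_topk(X_train, y_train, k, seed), None
    if name in ("all_pca", "all"):
        return np.arange(p), None
    raise ValueError(f"unknown selector {name!r}; known: {SELECTOR_NAMES}")


# ---------------------------------------------------------------------------
# Models
# ---------------------------------------------------------------------------

def _make_model(name: str, seed: int):
    if name == "lasso":
        return LogisticRegression(l1_ratio=1.0, C=1.0, solver="liblinear", random_state=seed % (2**31))
    if name == "svm":
        from sklearn.svm import SVC

        return SVC(kernel="linear", random_state=seed % (2**31))
    if name == "mlp":
        from sklearn.neural_network import MLPClassifier

        return MLPClassifier(random_state=seed % (2**31))
    if name == "xgboost":
        from xgboost import XGBClassifier

        return XGBClassifier(random_state=seed % (2**31), n_jobs=1, verbosity=0)
    if name == "rf":
        from sklearn.ensemble import RandomForestClassifier

        return RandomForestClassifier(random_state=seed % (2**31))
    if name == "lr":
        # scikit-learn's default LogisticRegression is L2 (ridge) penalized
        return LogisticRegression(random_state=seed % (2**31))
    raise ValueError(f"unknown model {name!r}; known: {MODEL_NAMES}")


def _score_rows(model, X: np.ndarray) -> np.ndarray:
    if hasattr(model, "predict_proba"):
        return model.predict_proba(X)[:, 1]
    return model.decision_function(X)


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

def run_cv(
    table: FeatureTable,
    selector: str = "ours",
    model: str = "lr",
    trials: int = 100,
    folds: int = 10,
    seed: int = 0,
    k: int = 288,
    pca_dim: int = 15,
    selector_params: SelectorParams | None = None,
    partitions: Sequence | None = None,
    collect_roc: bool = False,
) -> CVResult:
    """Mean held-out AUC of one (selector, model) cell.

    Selection, PCA and model fitting happen inside every fold on training
    rows only.  Deterministic given ``seed`` (or the supplied shared
    ``partitions``).
    """
    registry = registry_from_keys(table.keys)
    parts = partitions if partitions is not None else make_partitions(table.labels, trials, folds, seed)
    use_pca = _SELECTOR_USES_PCA[selector]
    scores = np.empty((len(parts), len(parts[0])))
    roc_scores: list[np.ndarray] = []
    roc_labels: list[np.ndarray] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # MLP convergence etc. at default settings
        for t, trial_folds in enumerate(parts):
            for f, (train_rows, test_rows) in enumerate(trial_folds):
                fold_seed = (seed + 104729 * t + 7919 * f) % (2**31)
                X_train = table.values[train_rows]
                y_train = table.labels[train_rows]
                cols, artifact = select_features(
                    selector, X_train, y_train, table, registry, fold_seed,
                    k=k, selector_params=selector_params, train_rows=train_rows,
                )
                X_te = table.values[np.asarray(test_rows)][:, cols]
                if selector == "ours" and artifact is not None and artifact.embedding is not None:
                    Z_tr = artifact.embedding.transform(X_train[:, cols])
                    Z_te = artifact.embedding.transform(X_te)
                elif use_pca:
                    dim = min(pca_dim, len(train_rows) - 1, len(cols))
                    emb = fit_pca_embed(X_train[:, cols], dim=dim)
                    Z_tr = emb.transform(X_train[:, cols])
                    Z_te = emb.transform(X_te)
                else:
                    Z_tr, Z_te = X_train[:, cols], X_te
                clf = _make_model(model, fold_seed)
                clf.fit(Z_tr, y_train)
                s = _score_rows(clf, Z_te)
                scores[t, f] = roc_auc_score(table.labels[test_rows], s)
                if collect_roc and t == 0:
                    roc_scores.append(s)
                    roc_labels.append(table.labels[test_rows])
    roc = None
    if collect_roc:
        fpr, tpr, _, _ = roc_points(np.concatenate(roc_scores), np.concatenate(roc_labels))
        roc = (fpr, tpr)
    return CVResult(selector=selector, model=model, fold_scores=scores, roc=roc)


def compare_table(
    table: FeatureTable,
    selectors: Sequence[str] = SELECTOR_NAMES,
    models: Sequence[str] = MODEL_NAMES,
    trials: int = 100,
    folds: int = 10,
    seed: int = 0,
    k: int = 288,
    pca_dim: int = 15,
    selector_params: SelectorParams | None = None,
) -> BenchmarkResult:
    """The full selector x model comparison grid on shared partitions."""
    partitions = make_partitions(table.labels, trials, folds, seed)
    cells: dict[tuple[str, str], CVResult] = {}
    for s in selectors:
        for m in models:
            logger.info("benchmark cell selector=%s model=%s", s, m)
            cells[(s, m)] = run_cv(
                table, s, m, seed=seed, k=k, pca_dim=pca_dim,
                selector_params=selector_params, partitions=partitions,
                collect_roc=True,
            )
    config = {
        "trials": len(partitions), "folds": len(partitions[0]), "seed": seed,
        "k": k, "pca_dim": pca_dim,
    }
    return BenchmarkResult(cells=cells, selectors=tuple(selectors), models=tuple(models), config=config)


def roc_points(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """ROC curve and trapezoidal AUC.

    The AUC equals the Mann-Whitney U statistic divided by n1*n2 (the
    probability that a random positive outranks a random negative, ties
    counted half).
    """
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("ROC needs both classes present")
    fpr, tpr, thresholds = roc_curve(labels, scores)
    auc = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, thresholds, auc
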