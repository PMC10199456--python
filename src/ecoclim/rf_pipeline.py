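"""Random-forest presence/pseudo-absence classifier: tuning, evaluation,
variable importance and map projection.

The forest itself is scikit-learn's :class:`RandomForestClassifier`; this
module owns everything around it: the exhaustive (ntree, mtry) out-of-bag
tuning loop, confusion-matrix metrics (sensitivity, specificity, TSS),
rank-based AUC, permutation importance (mean decrease in accuracy, MDA),
Gini importance aggregated over trees (mean decrease in Gini, MDG), and the
projection of per-cell presence probabilities onto a raster grid.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier

from .errors import DataError
from .features import PredictorStack

DEFAULT_NTREE_GRID = tuple(range(50, 401, 50))
DEFAULT_MTRY_GRID = (1, 2, 3, 4)

__all__ = [
    "RFConfig",
    "EvalReport",
    "tune_rf",
    "fit_rf",
    "fit_and_predict",
    "confusion_metrics",
    "roc_auc",
    "variable_importance",
    "evaluate",
    "project_probability_map",
    "DEFAULT_NTREE_GRID",
    "DEFAULT_MTRY_GRID",
]


@dataclass
class RFConfig:
    """Chosen forest structure plus the grids it was selected from."""

    ntree: int
    mtry: int
    ntree_grid: tuple = DEFAULT_NTREE_GRID
    mtry_grid: tuple = DEFAULT_MTRY_GRID
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.ntree not in self.ntree_grid or self.mtry not in self.mtry_grid:
            raise DataError("chosen (ntree, mtry) must be members of their grids")


@dataclass
class EvalReport:
    """Confusion-matrix metrics, AUC, OOB error and variable importance."""

    tp: int
    fp: int
    fn: int
    tn: int
    sensitivity: float
    specificity: float
    tss: float
    accuracy: float
    class_errors: dict[str, float]
    auc: float | None = None
    oob_error: float | None = None
    importance: pd.DataFrame | None = field(default=None, repr=False)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {k: v for k, v in asdict(self).items() if k != "importance"}
        if self.importance is not None:
            payload["importance"] = self.importance.to_dict(orient="index")
        text = json.dumps(payload, indent=2, default=float)
        if path is not None:
            Path(path).write_text(text)
        return text


def _split_xy(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, list[str]]:
    if "label" not in table.columns:
        raise DataError("feature table must have a 'label' column")
    names = [c for c in table.columns if c != "label"]
    X = table[names].to_numpy(dtype=float)
    y = table["label"].to_numpy(dtype=int)
    return X, y, names


def _make_forest(ntree: int, mtry: int, seed: int) -> RandomForestClassifier:
    return RandomForestClassifier(
        n_estimators=ntree, max_features=mtry, oob_score=True,
        bootstrap=True, random_state=seed, n_jobs=1)


def tune_rf(train: pd.DataFrame, ntree_grid=DEFAULT_NTREE_GRID,
            mtry_grid=DEFAULT_MTRY_GRID, rng_seed: int = 0
            ) -> tuple[RFConfig, pd.DataFrame]:
    """Exhaustive out-of-bag grid search over (ntree, mtry).

    Every grid combination is fitted and scored by OOB error; the minimiser
    wins, with ties broken toward smaller ntree then smaller mtry.  Returns
    the chosen config and the full grid report (one row per combination).
    """
    X, y, names = _split_xy(train)
    if len(np.unique(y)) < 2:
        raise DataError("training data must contain both classes")
    ntree_grid = tuple(ntree_grid)
    mtry_grid = tuple(m for m in mtry_grid)
    bad = [m for m in mtry_grid if m > len(names)]
    if bad:
        raise DataError(f"mtry values {bad} exceed the {len(names)} available features")
    rows = []
    for ntree in sorted(ntree_grid):
        for mtry in sorted(mtry_grid):
            forest = _make_forest(ntree, mtry, rng_seed)
            forest.fit(X, y)
            rows.append({"ntree": ntree, "mtry": mtry,
                         "oob_error": 1.0 - forest.oob_score_})
    report = pd.DataFrame(rows)
    # rows are sorted by (ntree, mtry); idxmin takes the first minimum,
    # which is exactly the smaller-ntree-then-smaller-mtry tie-break
    best = report.loc[report["oob_error"].idxmin()]
    config = RFConfig(ntree=int(best["ntree"]), mtry=int(best["mtry"]),
                      ntree_grid=ntree_grid, mtry_grid=mtry_grid, rng_seed=rng_seed)
    return config, report


def fit_rf(train: pd.DataFrame, config: RFConfig) -> RandomForestClassifier:
    """Fit the forest with the chosen structure on a feature table."""
    X, y, names = _split_xy(train)
    forest = _make_forest(config.ntree, config.mtry, config.rng_seed)
    forest.fit(X, y)
    forest.feature_names_ecoclim_ = names
    return forest


def fit_and_predict(train: pd.DataFrame, test: pd.DataFrame, config: RFConfig
                    ) -> tuple[RandomForestClassifier, np.ndarray, np.ndarray]:
    """Fit on train, return (model, presence probability, class) on test.

    The class is the majority vote, i.e. probability >= 0.5.
    """
    _, _, train_names = _split_xy(train)
    X_test, _, test_names = _split_xy(test)
    if train_names != test_names:
        raise DataError(f"feature mismatch between train {train_names} and test {test_names}")
    model = fit_rf(train, config)
    proba = model.predict_proba(X_test)[:, list(model.classes_).index(1)]
    return model, proba, (proba >= 0.5).astype(int)


def confusion_metrics(tp: int, fp: int, fn: int, tn: int) -> dict:
    """Metrics from the 2x2 confusion matrix.

    sensitivity = TP/(TP+FN), specificity = TN/(TN+FP),
    TSS = sensitivity + specificity - 1, accuracy = (TP+TN)/n.  Row class
    errors follow the report layout in which the predicted-negative row
    holds (TP, FP) and the predicted-positive row holds (FN, TN): each row
    error is the off-diagonal count over the row sum.  An empty margin
    leaves the affected metric as None (reported missing).
    """
    for name, v in (("tp", tp), ("fp", fp), ("fn", fn), ("tn", tn)):
        if v < 0:
            raise DataError(f"negative count {name}={v}")
    n = tp + fp + fn + tn
    if n == 0:
        raise DataError("empty confusion matrix")

    def ratio(num, den):
        return num / den if den > 0 else None

    sens = ratio(tp, tp + fn)
    spec = ratio(tn, tn + fp)
    return {
        "tp": tp, "fp": fp, "fn": fn, "tn": tn,
        "sensitivity": sens,
        "specificity": spec,
        "tss": sens + spec - 1.0 if sens is not None and spec is not None else None,
        "accuracy": (tp + tn) / n,
        "class_errors": {
            "predicted_negative": ratio(fp, tp + fp),
            "predicted_positive": ratio(fn, fn + tn),
        },
    }


def roc_auc(labels, scores) -> float | None:
    """Rank-based (Mann-Whitney) area under the ROC curve, ties averaged.

    Equals the probability that a random positive outranks a random
    negative, with ties counting 1/2.  Returns None on single-class input.
    """
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        return None
    ranks = rankdata(scores)
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def variable_importance(model: RandomForestClassifier, validation: pd.DataFrame,
                        n_permutations: int = 10, rng_seed: int = 0) -> pd.DataFrame:
    """Per-variable MDA and MDG with ranks (1 = most important).

    MDA: mean drop in validation accuracy over ``n_permutations`` shuffles
    of each feature column (permutation importance); NaN when
    ``n_permutations == 0``.  MDG: mean over trees of the total Gini
    impurity decrease attributed to the variable.
    """
    names = getattr(model, "feature_names_ecoclim_", None)
    X, y, val_names = _split_xy(validation)
    if names is not None and names != val_names:
        raise DataError(f"feature mismatch between model {names} and validation {val_names}")
    names = val_names
    rng = np.random.default_rng(rng_seed)
    base_acc = float((model.predict(X) == y).mean())

    mda = np.full(len(names), np.nan)
    if n_permutations > 0:
        for j in range(len(names)):
            drops = np.empty(n_permutations)
            for k in range(n_permutations):
                Xp = X.copy()
                Xp[:, j] = Xp[rng.permutation(len(X)), j]
                drops[k] = base_acc - (model.predict(Xp) == y).mean()
            mda[j] = drops.mean()

    mdg = np.zeros(len(names))
    for tree in model.estimators_:
        mdg += tree.tree_.compute_feature_importances(normalize=False)
    mdg /= len(model.estimators_)

    table = pd.DataFrame({"mda": mda, "mdg": mdg}, index=pd.Index(names, name="variable"))
    if n_permutations > 0:
        table["mda_rank"] = rankdata(-table["mda"], method="min").astype(int)
    table["mdg_rank"] = rankdata(-table["mdg"], method="min").astype(int)
    return table


def evaluate(model: RandomForestClassifier, test: pd.DataFrame,
             oob_error: float | None = None, n_permutations: int = 10,
             rng_seed: int = 0) -> EvalReport:
    """Full held-out evaluation: confusion metrics, AUC, importance."""
    X, y, _ = _split_xy(test)
    proba = model.predict_proba(X)[:, list(model.classes_).index(1)]
    pred = (proba >= 0.5).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    m = confusion_metrics(tp, fp, fn, tn)
    importance = variable_importance(model, test, n_permutations=n_permutations,
                                     rng_seed=rng_seed)
    return EvalReport(
        tp=tp, fp=fp, fn=fn, tn=tn,
        sensitivity=m["sensitivity"], specificity=m["specificity"],
        tss=m["tss"], accuracy=m["accuracy"], class_errors=m["class_errors"],
        auc=roc_auc(y, proba), oob_error=oob_error, importance=importance)


def project_probability_map(model: RandomForestClassifier, stack: PredictorStack
                            ) -> np.ndarray:
    """Per-cell presence probability over a predictor stack.

    Layers are taken in the model's training feature order; a missing layer
    is a hard failure naming it.  No-data cells (NaN in any layer)
    propagate to NaN in the output.
    """
    names = getattr(model, "feature_names_ecoclim_", None)
    if names is None:
        raise DataError("model was not fitted through fit_rf; feature names unknown")
    missing = [n for n in names if n not in stack.layers]
    if missing:
        raise DataError(f"predictor stack is missing layers: {missing}")
    grids = [np.asarray(stack.layers[n], dtype=float) for n in names]
    valid = np.ones(stack.geom.shape, dtype=bool)
    for g in grids:
        valid &= np.isfinite(g)
    out = np.full(stack.geom.shape, np.nan)
    if valid.any():
        X = np.column_stack([g[valid] for g in grids])
        out[valid] = model.predict_proba(X)[:, list(model.classes_).index(1)]
    return out
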