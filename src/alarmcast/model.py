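"""Classification: exhaustive per-family feature selection under CV,
decision-tree and gradient-boosted classifiers with a fixed-specificity
operating point, and Gain feature importance.

The estimators follow scikit-learn conventions (``fit`` / ``predict`` /
``predict_proba``, ``get_params``, trailing-underscore fitted attributes) and
compose with sklearn pipelines.  Missing feature values (NaN) are routed by
the tree learners' learned default directions; no imputation is performed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.feature_selection import SelectorMixin
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeClassifier
from xgboost import XGBClassifier

from .features import ALWAYS_FAMILIES, FEATURE_FAMILIES, SELECTABLE_FAMILIES
from .metrics import OperatingPoint, auroc, confusion_at, roc_points, sensitivity_at_specificity

DEFAULT_SELECTION_TOL = 1e-3
DEFAULT_MAX_SUBSET = 8


@dataclass(frozen=True)
class TreeParams:
    """Single-tree settings: gini splitting, depth capped at 6 levels."""

    max_depth: int = 6
    min_samples_leaf: int = 1
    seed: int = 0

    def make(self) -> DecisionTreeClassifier:
        return DecisionTreeClassifier(criterion="gini", max_depth=self.max_depth,
                                      min_samples_leaf=self.min_samples_leaf,
                                      random_state=self.seed)


# ---------------------------------------------------------------------------
# exhaustive per-family selection
# ---------------------------------------------------------------------------

@dataclass
class SelectionResult:
    family: str
    chosen: tuple[str, ...]
    chosen_auroc: float
    best_by_k: dict[int, tuple[tuple[str, ...], float]] = field(default_factory=dict)
    evaluated: list[tuple[tuple[str, ...], float]] = field(default_factory=list)
    stopped_at_k: int = 0
    capped: bool = False

    @property
    def stopping_trace(self) -> list[float]:
        return [self.best_by_k[k][1] for k in sorted(self.best_by_k)]


def _mean_cv_auroc(Xv: np.ndarray, y: np.ndarray, cols: tuple[int, ...],
                   folds: Sequence[tuple[np.ndarray, np.ndarray]],
                   params: TreeParams) -> float:
    sub = Xv[:, cols]
    scores = []
    for tr, va in folds:
        tree = params.make().fit(sub[tr], y[tr])
        s = tree.predict_proba(sub[va])[:, 1]
        scores.append(auroc(s, y[va]))
    return float(np.mean(scores))


def select_family(X_family: pd.DataFrame, y: Sequence[int],
                  folds: Sequence[tuple[np.ndarray, np.ndarray]],
                  params: TreeParams = TreeParams(),
                  tol: float = DEFAULT_SELECTION_TOL,
                  max_subset_size: int = DEFAULT_MAX_SUBSET) -> SelectionResult:
    """Exhaustive subset search within one feature family.

    All subsets of cardinality 1, 2, ... are scored by mean cross-validated
    AUROC of a depth-capped gini decision tree; the search stops at the first
    cardinality k where the best (k+1)-subset improves on the best k-subset
    by less than ``tol`` (or at the family size).  Ties are broken by frozen
    column order, then by the smaller subset.  ``folds`` hold positional
    indices into ``X_family``.
    """
    cols = list(X_family.columns)
    name = _family_name(cols)
    Xv = X_family.to_numpy(dtype=float)
    y = np.asarray(y)
    n = len(cols)
    cap = min(n, max_subset_size)
    result = SelectionResult(name, (), np.nan)
    best_prev: tuple[tuple[int, ...], float] | None = None
    for k in range(1, cap + 1):
        best_k: tuple[tuple[int, ...], float] | None = None
        for combo in combinations(range(n), k):   # lexicographic = frozen order
            score = _mean_cv_auroc(Xv, y, combo, folds, params)
            result.evaluated.append((tuple(cols[i] for i in combo), score))
            if best_k is None or score > best_k[1]:
                best_k = (combo, score)
        result.best_by_k[k] = (tuple(cols[i] for i in best_k[0]), best_k[1])
        if best_prev is not None and best_k[1] - best_prev[1] < tol:
            result.chosen = tuple(cols[i] for i in best_prev[0])
            result.chosen_auroc = best_prev[1]
            result.stopped_at_k = k - 1
            return result
        best_prev = best_k
    result.chosen = tuple(cols[i] for i in best_prev[0])
    result.chosen_auroc = best_prev[1]
    result.stopped_at_k = cap
    result.capped = cap < n
    if result.capped:
        warnings.warn(f"family {name}: subset search capped at {cap} features",
                      stacklevel=2)
    return result


def _family_name(cols: Sequence[str]) -> str:
    for fam, fam_cols in FEATURE_FAMILIES.items():
        if set(cols) <= set(fam_cols):
            return fam
    return "custom"


def build_pool(selections: Mapping[str, SelectionResult], X: pd.DataFrame) -> pd.DataFrame:
    """Final feature pool: the chosen subset of each selectable family plus
    *all* features of the first three families (metadata, category, alarm
    counts), in frozen column order."""
    keep = []
    for fam in ALWAYS_FAMILIES:
        keep.extend(c for c in FEATURE_FAMILIES[fam] if c in X.columns)
    for fam in SELECTABLE_FAMILIES:
        if fam in selections:
            keep.extend(c for c in FEATURE_FAMILIES[fam] if c in selections[fam].chosen)
    return X[keep]


class FamilyAurocSelector(SelectorMixin, BaseEstimator):
    """Transformer running the per-family exhaustive CV-AUROC subset search
    and keeping the resulting feature pool.

    The first three families (metadata, anchor category, pre-window alarm
    counts) are always kept in full; the HR, BR, SpO2, correlation and HRV
    families are reduced to their chosen subsets.
    """

    def __init__(self, max_depth: int = 6, min_samples_leaf: int = 1,
                 tol: float = DEFAULT_SELECTION_TOL,
                 max_subset_size: int = DEFAULT_MAX_SUBSET,
                 cv: int = 5, random_state: int = 0):
        self.max_depth = max_depth
        self.min_samples_leaf = min_samples_leaf
        self.tol = tol
        self.max_subset_size = max_subset_size
        self.cv = cv
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y, folds=None):
        if not isinstance(X, pd.DataFrame):
            raise TypeError("FamilyAurocSelector requires a named-column DataFrame")
        y = np.asarray(y)
        if folds is None:
            skf = StratifiedKFold(n_splits=self.cv, shuffle=True,
                                  random_state=self.random_state)
            folds = list(skf.split(np.zeros(len(y)), y))
        params = TreeParams(self.max_depth, self.min_samples_leaf, self.random_state)
        self.results_ = {}
        for fam in SELECTABLE_FAMILIES:
            fam_cols = [c for c in FEATURE_FAMILIES[fam] if c in X.columns]
            if not fam_cols:
                continue
            self.results_[fam] = select_family(X[fam_cols], y, folds, params,
                                               self.tol, self.max_subset_size)
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.n_features_in_ = X.shape[1]
        self.selected_columns_ = list(build_pool(self.results_, X).columns)
        self.fit_n_rows_ = len(y)
        return self

    def _get_support_mask(self) -> np.ndarray:
        return np.isin(self.feature_names_in_, self.selected_columns_)

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return X[self.selected_columns_]


# ---------------------------------------------------------------------------
# fixed-specificity classifiers
# ---------------------------------------------------------------------------

class _FixedSpecificityBase(ClassifierMixin, BaseEstimator):
    """Shared machinery: fit a scorer, then fix the operating threshold at
    the target specificity on cross-validated (out-of-fold) training scores."""

    spec_target: float
    threshold_cv: int
    random_state: int

    def _make_model(self):  # pragma: no cover - abstract
        raise NotImplementedError

    @staticmethod
    def _as_matrix(X):
        return X if isinstance(X, pd.DataFrame) else np.asarray(X, dtype=float)

    def fit(self, X, y):
        X = self._as_matrix(X)
        y = np.asarray(y)
        classes = np.unique(y)
        if classes.size == 1:
            raise ValueError("degenerate labels: only one class present")
        if not np.array_equal(classes, [0, 1]):
            raise ValueError("labels must be binary 0/1")
        self.classes_ = np.array([0, 1])
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.n_features_in_ = X.shape[1]
        self.estimator_ = self._make_model().fit(X, y)
        oof = self._oof_scores(X, y)
        op = sensitivity_at_specificity(oof, y, self.spec_target)
        self.threshold_ = op.threshold
        self.operating_point_ = op
        self.oof_scores_ = oof
        return self

    def _oof_scores(self, X, y) -> np.ndarray:
        skf = StratifiedKFold(n_splits=self.threshold_cv, shuffle=True,
                              random_state=self.random_state)
        oof = np.empty(len(y), dtype=float)
        for tr, va in skf.split(np.zeros(len(y)), y):
            m = self._make_model().fit(_take(X, tr), y[tr])
            oof[va] = m.predict_proba(_take(X, va))[:, 1]
        return oof

    def predict_scores(self, X) -> np.ndarray:
        return self.estimator_.predict_proba(self._as_matrix(X))[:, 1]

    def predict_proba(self, X) -> np.ndarray:
        s = self.predict_scores(X)
        return np.column_stack((1.0 - s, s))

    def predict(self, X) -> np.ndarray:
        return (self.predict_scores(X) >= self.threshold_).astype(int)

    def evaluate(self, X, y, tag: str = "test") -> "EvalReport":
        s = self.predict_scores(X)
        y = np.asarray(y)
        conf = confusion_at(s, y, self.threshold_)
        sens = conf["tp"] / max(1, conf["tp"] + conf["fn"])
        spec = conf["tn"] / max(1, conf["tn"] + conf["fp"])
        return EvalReport(tag, auroc(s, y), sens, spec, self.spec_target,
                          self.threshold_, conf, roc_points(s, y))


def _take(X, idx):
    return X.iloc[idx] if isinstance(X, pd.DataFrame) else X[idx]


class AlarmDecisionTree(_FixedSpecificityBase):
    """Gini decision tree (depth <= 6) scoring episodes by leaf case
    proportion, with a fixed-specificity operating threshold chosen on
    out-of-fold training scores."""

    def __init__(self, max_depth: int = 6, min_samples_leaf: int = 1,
                 spec_target: float = 0.98, threshold_cv: int = 5,
                 random_state: int = 0):
        self.max_depth = max_depth
        self.min_samples_leaf = min_samples_leaf
        self.spec_target = spec_target
        self.threshold_cv = threshold_cv
        self.random_state = random_state

    def _make_model(self):
        return DecisionTreeClassifier(criterion="gini", max_depth=self.max_depth,
                                      min_samples_leaf=self.min_samples_leaf,
                                      random_state=self.random_state)


class BoostedAlarmClassifier(_FixedSpecificityBase):
    """Gradient-boosted ensemble of depth-capped trees (XGBoost); the first
    tree plays the role of the unboosted decision tree and subsequent trees
    fit the residual error."""

    def __init__(self, max_depth: int = 6, n_rounds: int = 200,
                 learning_rate: float = 0.1, min_child_weight: float = 1.0,
                 reg_lambda: float = 1.0, spec_target: float = 0.98,
                 threshold_cv: int = 5, random_state: int = 0):
        self.max_depth = max_depth
        self.n_rounds = n_rounds
        self.learning_rate = learning_rate
        self.min_child_weight = min_child_weight
        self.reg_lambda = reg_lambda
        self.spec_target = spec_target
        self.threshold_cv = threshold_cv
        self.random_state = random_state

    def _make_model(self):
        return XGBClassifier(max_depth=self.max_depth, n_estimators=self.n_rounds,
                             learning_rate=self.learning_rate,
                             min_child_weight=self.min_child_weight,
                             reg_lambda=self.reg_lambda,
                             objective="binary:logistic", tree_method="hist",
                             n_jobs=1, random_state=self.random_state,
                             eval_metric="logloss", verbosity=0)


# ---------------------------------------------------------------------------
# Gain importance
# ---------------------------------------------------------------------------

@dataclass
class GainReport:
    """Per-feature Gain (total loss/impurity reduction across all trees) and
    the descending top-10 ranking."""

    gains: dict[str, float]

    def top(self, n: int = 10) -> list[tuple[str, float]]:
        ranked = sorted(self.gains.items(), key=lambda kv: (-kv[1], kv[0]))
        return ranked[:n]

    def normalized(self) -> "GainReport":
        total = sum(self.gains.values())
        if total <= 0:
            return GainReport(dict(self.gains))
        return GainReport({k: v / total for k, v in self.gains.items()})


def tree_gain(tree: DecisionTreeClassifier, feature_names: Sequence[str]) -> dict[str, float]:
    """Per-feature total impurity reduction of a fitted sklearn tree,
    normalised by the root sample weight."""
    t = tree.tree_
    gains = {name: 0.0 for name in feature_names}
    w = t.weighted_n_node_samples
    for node in range(t.node_count):
        left, right = t.children_left[node], t.children_right[node]
        if left == -1:
            continue
        drop = (w[node] * t.impurity[node] - w[left] * t.impurity[left]
                - w[right] * t.impurity[right]) / w[0]
        gains[feature_names[t.feature[node]]] += float(drop)
    return gains


def gain_importance(model, feature_names: Sequence[str] | None = None) -> GainReport:
    """Gain report for a fitted classifier (boosted ensemble or single tree)."""
    if isinstance(model, _FixedSpecificityBase):
        feature_names = feature_names if feature_names is not None else \
            list(getattr(model, "feature_names_in_", []))
        model = model.estimator_
    if isinstance(model, XGBClassifier):
        booster = model.get_booster()
        raw = booster.get_score(importance_type="total_gain")
        names = feature_names or booster.feature_names or []
        gains = {str(n): 0.0 for n in names}
        for key, val in raw.items():
            if key.startswith("f") and key[1:].isdigit() and names:
                key = str(names[int(key[1:])])
            gains[str(key)] = float(val)
        return GainReport(gains)
    if isinstance(model, DecisionTreeClassifier):
        if feature_names is None:
            feature_names = [f"f{i}" for i in range(model.n_features_in_)]
        return GainReport(tree_gain(model, list(feature_names)))
    raise TypeError(f"unsupported model type {type(model).__name__}")


# ---------------------------------------------------------------------------
# tree structure export
# ---------------------------------------------------------------------------

def tree_node_stats(tree: DecisionTreeClassifier, feature_names: Sequence[str],
                    max_depth: int = 3) -> list[dict]:
    """Node annotations (gini, share of samples, class proportions) for the
    top layers of a fitted tree."""
    t = tree.tree_
    out = []

    def visit(node: int, depth: int):
        if depth > max_depth or node == -1:
            return
        props = t.value[node][0] / t.value[node][0].sum()
        rec = {"node": int(node), "depth": depth,
               "gini": float(t.impurity[node]),
               "samples_pct": float(100.0 * t.weighted_n_node_samples[node]
                                    / t.weighted_n_node_samples[0]),
               "value": [float(p) for p in props],
               "n": float(t.weighted_n_node_samples[node])}
        if t.children_left[node] != -1:
            rec["feature"] = str(feature_names[t.feature[node]])
            rec["threshold"] = float(t.threshold[node])
        out.append(rec)
        visit(t.children_left[node], depth + 1)
        visit(t.children_right[node], depth + 1)

    visit(0, 0)
    return out


def export_tree_text(tree: DecisionTreeClassifier, feature_names: Sequence[str],
                     max_depth: int = 3) -> str:
    """Indented text rendering of the top tree layers with gini / samples /
    class-proportion annotations."""
    t = tree.tree_
    lines: list[str] = []

    def visit(node: int, depth: int, prefix: str):
        if node == -1 or depth > max_depth:
            return
        props = t.value[node][0] / t.value[node][0].sum()
        pct = 100.0 * t.weighted_n_node_samples[node] / t.weighted_n_node_samples[0]
        head = (f"{feature_names[t.feature[node]]} <= {t.threshold[node]:.4g}"
                if t.children_left[node] != -1 else "leaf")
        lines.append(f"{prefix}{head} | gini={t.impurity[node]:.3f} "
                     f"samples={pct:.1f}% value=[{props[1]:.3f}, {props[0]:.3f}]")
        visit(t.children_left[node], depth + 1, prefix + "  ")
        visit(t.children_right[node], depth + 1, prefix + "  ")

    visit(0, 0, "")
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# experiment grid
# ---------------------------------------------------------------------------

@dataclass
class EvalReport:
    tag: str
    auroc: float
    sensitivity: float
    specificity: float
    spec_target: float
    threshold: float
    confusion: dict[str, int]
    roc: np.ndarray | None = None


def evaluate_feature_set(X: pd.DataFrame, y: np.ndarray, plan, columns: Sequence[str],
                         estimator: _FixedSpecificityBase) -> dict:
    """Train-CV mean and held-out test performance for one feature set.

    Train-CV: per-fold fit and out-of-fold AUROC / sensitivity at the target
    specificity, averaged over folds.  Test: fit on the full training set,
    threshold fixed on out-of-fold training scores, then applied unchanged.
    """
    Xs = X[list(columns)]
    y = np.asarray(y)
    cv_auroc, cv_sens = [], []
    for tr, va in plan.cv_folds:
        m = clone(estimator)._make_model().fit(Xs.iloc[tr], y[tr])
        s = m.predict_proba(Xs.iloc[va])[:, 1]
        cv_auroc.append(auroc(s, y[va]))
        cv_sens.append(sensitivity_at_specificity(s, y[va], estimator.spec_target).sensitivity)
    est = clone(estimator).fit(Xs.iloc[plan.train_idx], y[plan.train_idx])
    test = est.evaluate(Xs.iloc[plan.test_idx], y[plan.test_idx])
    return {"train_cv_auroc": float(np.mean(cv_auroc)),
            "train_cv_sensitivity": float(np.mean(cv_sens)),
            "test": test, "estimator": est, "n_features": len(columns)}


def run_experiment_grid(matrices: Mapping, plans: Mapping, *,
                        seed: int = 0, spec_target: float = 0.98,
                        tol: float = DEFAULT_SELECTION_TOL,
                        max_subset_size: int = DEFAULT_MAX_SUBSET,
                        n_rounds: int = 200, learning_rate: float = 0.1,
                        min_per_class: int = 50,
                        ) -> tuple[pd.DataFrame, dict]:
    """Per-family, pooled-tree and boosted reports for every window spec.

    ``matrices`` maps window spec -> (X, y); ``plans`` maps window spec ->
    SplitPlan with CV folds.  Specs with fewer than ``min_per_class``
    episodes in either class are skipped with a warning.  Feature selection
    and threshold fixing see only training folds.
    """
    rows = []
    details: dict = {}
    for spec, (X, y) in matrices.items():
        y = np.asarray(y)
        plan = plans[spec]
        counts = np.bincount(y, minlength=2)
        if counts.min() < min_per_class:
            warnings.warn(f"{spec}: only {counts.min()} episodes in the minority "
                          f"class; skipped", stacklevel=2)
            continue
        pos_map = {int(g): p for p, g in enumerate(plan.train_idx)}
        folds_local = [(np.array([pos_map[i] for i in tr]),
                        np.array([pos_map[i] for i in va]))
                       for tr, va in plan.cv_folds]
        X_train = X.iloc[plan.train_idx].reset_index(drop=True)
        y_train = y[plan.train_idx]
        selector = FamilyAurocSelector(tol=tol, max_subset_size=max_subset_size,
                                       random_state=seed)
        selector.fit(X_train, y_train, folds=folds_local)
        tree = AlarmDecisionTree(spec_target=spec_target, random_state=seed)
        boosted = BoostedAlarmClassifier(n_rounds=n_rounds, learning_rate=learning_rate,
                                         spec_target=spec_target, random_state=seed)
        spec_details = {"selector": selector, "plan": plan, "models": {}}
        model_sets: list[tuple[str, list[str], _FixedSpecificityBase]] = []
        for fam in ALWAYS_FAMILIES:
            model_sets.append((f"family:{fam}", FEATURE_FAMILIES[fam], tree))
        for fam in SELECTABLE_FAMILIES:
            model_sets.append((f"family:{fam}", list(selector.results_[fam].chosen), tree))
        pool_cols = selector.selected_columns_
        model_sets.append(("pool_tree", pool_cols, tree))
        model_sets.append(("pool_boosted", pool_cols, boosted))
        for name, columns, est in model_sets:
            res = evaluate_feature_set(X, y, plan, columns, est)
            spec_details["models"][name] = res
            rows.append({"window": str(spec), "model": name,
                         "n_features": res["n_features"],
                         "train_cv_auroc": res["train_cv_auroc"],
                         "train_cv_sensitivity": res["train_cv_sensitivity"],
                         "test_auroc": res["test"].auroc,
                         "test_sensitivity": res["test"].sensitivity,
                         "test_specificity": res["test"].specificity,
                         "threshold": res["test"].threshold})
        details[spec] = spec_details
    return pd.DataFrame(rows), details
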