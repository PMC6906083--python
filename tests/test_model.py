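"""Feature selection, tree/boosted classifiers, Gain importance and the
experiment grid."""

import warnings
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeClassifier

from alarmcast.model import (AlarmDecisionTree, BoostedAlarmClassifier,
                             FamilyAurocSelector, TreeParams, build_pool,
                             gain_importance, select_family, tree_node_stats)


def oracle_select(X, y, folds, tol=1e-3, max_depth=6, seed=0):
    """Independent exhaustive search replicating the stop rule with sklearn
    scoring only."""
    cols = list(X.columns)
    Xv = X.to_numpy()

    def cv_score(combo):
        aucs = []
        for tr, va in folds:
            m = DecisionTreeClassifier(criterion="gini", max_depth=max_depth,
                                       random_state=seed).fit(Xv[tr][:, combo], y[tr])
            aucs.append(roc_auc_score(y[va], m.predict_proba(Xv[va][:, combo])[:, 1]))
        return float(np.mean(aucs))

    best_prev = None
    for k in range(1, len(cols) + 1):
        best_k = None
        for combo in combinations(range(len(cols)), k):
            s = cv_score(combo)
            if best_k is None or s > best_k[1]:
                best_k = (combo, s)
        if best_prev is not None and best_k[1] - best_prev[1] < tol:
            return tuple(cols[i] for i in best_prev[0])
        best_prev = best_k
    return tuple(cols[i] for i in best_prev[0])


def _folds(y, k=5, seed=0):
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros(len(y)), y))


def _informative_family(rng, n=300, n_noise=4):
    y = (rng.random(n) < 0.4).astype(int)
    X = pd.DataFrame({"corr_HR_BR": y * 2.0 + rng.normal(0, 0.6, n)})
    for i in range(n_noise):
        X[f"noise_{i}"] = rng.normal(size=n)
    return X, y


class TestSelectFamily:
    def test_single_informative_feature_chosen(self, rng):
        X, y = _informative_family(rng)
        res = select_family(X, y, _folds(y), TreeParams(seed=0))
        assert res.chosen == ("corr_HR_BR",)
        assert res.stopped_at_k == 1

    def test_matches_independent_exhaustive_oracle(self, rng):
        for trial in range(3):
            n = 240
            y = (rng.random(n) < 0.5).astype(int)
            X = pd.DataFrame({f"f{j}": rng.normal(size=n) + (0.8 * y if j < 2 else 0)
                              for j in range(4)})
            folds = _folds(y, 5, trial)
            res = select_family(X, y, folds, TreeParams(seed=0))
            assert res.chosen == oracle_select(X, y, folds)

    def test_stop_rule_on_flat_trace(self):
        # a second identical column cannot improve: stop at k=1, keep first
        rng = np.random.default_rng(0)
        y = (rng.random(200) < 0.5).astype(int)
        base = y + rng.normal(0, 0.5, 200)
        X = pd.DataFrame({"a": base, "b": base})
        res = select_family(X, y, _folds(y), TreeParams(seed=0))
        assert res.chosen == ("a",)
        trace = res.stopping_trace
        assert len(trace) == 2 and trace[1] - trace[0] < 1e-3

    def test_single_feature_family_trivial(self, rng):
        X, y = _informative_family(rng, n_noise=0)
        res = select_family(X, y, _folds(y), TreeParams(seed=0))
        assert res.chosen == ("corr_HR_BR",) and res.stopped_at_k == 1

    def test_chosen_auroc_never_below_smaller_cardinality(self, rng):
        X, y = _informative_family(rng, n=200, n_noise=3)
        res = select_family(X, y, _folds(y), TreeParams(seed=0))
        trace = res.stopping_trace
        assert res.chosen_auroc >= trace[0] - 1e-12


class TestBuildPool:
    def _selection(self, fam, cols):
        from alarmcast.model import SelectionResult
        return SelectionResult(fam, tuple(cols), 0.8)

    def test_pool_union_and_order(self):
        from alarmcast.features import FEATURE_COLUMNS, FEATURE_FAMILIES
        X = pd.DataFrame(np.zeros((3, 63)), columns=FEATURE_COLUMNS)
        sels = {"HR": self._selection("HR", FEATURE_FAMILIES["HR"][:5]),
                "BR": self._selection("BR", FEATURE_FAMILIES["BR"][:4]),
                "SpO2": self._selection("SpO2", FEATURE_FAMILIES["SpO2"][:3]),
                "corr": self._selection("corr", FEATURE_FAMILIES["corr"][:2]),
                "HRV": self._selection("HRV", FEATURE_FAMILIES["HRV"][:1])}
        pool = build_pool(sels, X)
        assert pool.shape[1] == 6 + 15    # always-kept families + chosen subsets
        assert list(pool.columns)[:6] == FEATURE_COLUMNS[:6]

    def test_pool_never_below_eleven(self):
        from alarmcast.features import FEATURE_COLUMNS, SELECTABLE_FAMILIES, FEATURE_FAMILIES
        X = pd.DataFrame(np.zeros((2, 63)), columns=FEATURE_COLUMNS)
        sels = {fam: self._selection(fam, FEATURE_FAMILIES[fam][:1])
                for fam in SELECTABLE_FAMILIES}
        assert build_pool(sels, X).shape[1] == 11


class TestClassifiers:
    def test_separable_feature_gives_perfect_training_auroc(self, rng):
        y = np.array([0, 1] * 40)
        X = pd.DataFrame({"f": y * 10.0 + rng.normal(0, 0.1, 80)})
        clf = AlarmDecisionTree(random_state=0).fit(X, y)
        s = clf.predict_scores(X)
        assert clf.estimator_.get_depth() == 1
        from alarmcast.metrics import auroc
        assert auroc(s, y) == 1.0

    def test_pure_noise_cv_auroc_near_half(self, rng):
        from alarmcast.metrics import auroc
        n = 600
        y = (rng.random(n) < 0.5).astype(int)
        X = pd.DataFrame(rng.normal(size=(n, 5)), columns=list("abcde"))
        clf = AlarmDecisionTree(random_state=0).fit(X, y)
        assert auroc(clf.oof_scores_, y) == pytest.approx(0.5, abs=0.05)

    def test_operating_specificity_met_on_oof_scores(self, rng):
        n = 400
        y = (rng.random(n) < 0.4).astype(int)
        X = pd.DataFrame({"f": y + rng.normal(0, 0.8, n),
                          "g": rng.normal(size=n)})
        for cls in (AlarmDecisionTree, BoostedAlarmClassifier):
            kw = {"n_rounds": 30} if cls is BoostedAlarmClassifier else {}
            clf = cls(random_state=0, **kw).fit(X, y)
            if clf.operating_point_.attainable:
                assert clf.operating_point_.specificity >= 0.98

    def test_degenerate_labels_rejected(self):
        X = pd.DataFrame({"f": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="one class"):
            AlarmDecisionTree().fit(X, np.array([1, 1, 1]))

    def test_missing_values_handled_natively(self, rng):
        n = 300
        y = (rng.random(n) < 0.5).astype(int)
        f = y * 2.0 + rng.normal(0, 0.5, n)
        f[rng.random(n) < 0.2] = np.nan
        X = pd.DataFrame({"f": f})
        for cls, kw in ((AlarmDecisionTree, {}), (BoostedAlarmClassifier, {"n_rounds": 20})):
            clf = cls(random_state=0, **kw).fit(X, y)
            assert np.isfinite(clf.predict_scores(X)).all()

    def test_single_boosting_round_ranks_like_single_tree(self, rng):
        # two pure leaves of equal size: the first boosted tree orders
        # episodes exactly as the unboosted tree's leaf proportions
        y = np.array([1] * 20 + [0] * 20)
        X = pd.DataFrame({"f": np.concatenate([np.ones(20), np.zeros(20)])})
        tree = AlarmDecisionTree(random_state=0).fit(X, y)
        boost = BoostedAlarmClassifier(n_rounds=1, learning_rate=1.0,
                                       min_child_weight=0.0, random_state=0).fit(X, y)
        st = tree.predict_scores(X)
        sb = boost.predict_scores(X)
        assert (np.argsort(np.argsort(st)) == np.argsort(np.argsort(sb))).all() or \
               np.array_equal(np.sign(np.subtract.outer(st, st)),
                              np.sign(np.subtract.outer(sb, sb)))

    def test_boosting_not_worse_than_tree(self, rng):
        from alarmcast.metrics import auroc
        n = 700
        y = (rng.random(n) < 0.4).astype(int)
        X = pd.DataFrame({"a": y + rng.normal(0, 1.2, n),
                          "b": y * rng.normal(1, 1, n),
                          "c": rng.normal(size=n)})
        tr, te = np.arange(0, 500), np.arange(500, n)
        tree = AlarmDecisionTree(random_state=0).fit(X.iloc[tr], y[tr])
        boost = BoostedAlarmClassifier(n_rounds=100, random_state=0).fit(X.iloc[tr], y[tr])
        a_tree = auroc(tree.predict_scores(X.iloc[te]), y[te])
        a_boost = auroc(boost.predict_scores(X.iloc[te]), y[te])
        assert a_boost >= a_tree - 0.01

    def test_sklearn_get_set_params_roundtrip(self):
        clf = BoostedAlarmClassifier(n_rounds=42)
        params = clf.get_params()
        assert params["n_rounds"] == 42
        clf.set_params(learning_rate=0.3)
        assert clf.learning_rate == 0.3


class TestGain:
    def test_unused_feature_has_zero_gain(self, rng):
        y = np.array([0, 1] * 30)
        X = pd.DataFrame({"used": y * 5.0 + rng.normal(0, 0.1, 60),
                          "unused": np.zeros(60)})
        clf = AlarmDecisionTree(random_state=0).fit(X, y)
        rep = gain_importance(clf)
        assert rep.gains["unused"] == 0.0 and rep.gains["used"] > 0

    def test_single_tree_gain_matches_independent_recount(self, rng):
        n = 400
        y = (rng.random(n) < 0.5).astype(int)
        X = pd.DataFrame({"a": y + rng.normal(0, 0.7, n),
                          "b": rng.normal(size=n),
                          "c": y * rng.normal(0.5, 1, n)})
        tree = DecisionTreeClassifier(criterion="gini", max_depth=4,
                                      random_state=0).fit(X, y)
        rep = gain_importance(tree, list(X.columns))
        # oracle: route samples manually through the exported split structure
        t = tree.tree_
        Xv = X.to_numpy()

        def gini(idx):
            if idx.size == 0:
                return 0.0
            p = y[idx].mean()
            return 2.0 * p * (1.0 - p)

        expect = {c: 0.0 for c in X.columns}

        def walk(node, idx):
            if t.children_left[node] == -1:
                return
            f, thr = t.feature[node], t.threshold[node]
            left = idx[Xv[idx, f] <= thr]
            right = idx[Xv[idx, f] > thr]
            drop = (idx.size * gini(idx) - left.size * gini(left)
                    - right.size * gini(right)) / n
            expect[X.columns[f]] += drop
            walk(t.children_left[node], left)
            walk(t.children_right[node], right)

        walk(0, np.arange(n))
        for c in X.columns:
            assert rep.gains[c] == pytest.approx(expect[c], abs=1e-9)

    def test_normalized_gains_sum_to_one(self, rng):
        y = (rng.random(200) < 0.5).astype(int)
        X = pd.DataFrame({"a": y + rng.normal(0, 1, 200), "b": rng.normal(size=200)})
        clf = BoostedAlarmClassifier(n_rounds=20, random_state=0).fit(X, y)
        norm = gain_importance(clf).normalized()
        assert sum(norm.gains.values()) == pytest.approx(1.0)
        top = norm.top(10)
        assert top == sorted(top, key=lambda kv: -kv[1])


class TestNodeStats:
    def test_top_layers_match_manual_recount(self):
        y = np.array([1] * 30 + [0] * 70)
        X = pd.DataFrame({"f": np.concatenate([np.linspace(2, 3, 30),
                                               np.linspace(0, 1, 70)])})
        tree = DecisionTreeClassifier(criterion="gini", max_depth=3,
                                      random_state=0).fit(X, y)
        stats = tree_node_stats(tree, ["f"], max_depth=3)
        root = stats[0]
        assert root["samples_pct"] == 100.0
        assert root["gini"] == pytest.approx(2 * 0.3 * 0.7)
        assert root["value"] == pytest.approx([0.7, 0.3])


class TestSelectorAndLeakage:
    def test_selector_transform_keeps_pool_order(self, rng):
        from alarmcast.features import FEATURE_COLUMNS
        n = 260
        y = (rng.random(n) < 0.4).astype(int)
        X = pd.DataFrame(rng.normal(size=(n, 63)), columns=FEATURE_COLUMNS)
        X["SpO2_occ"] = -3.0 * y + rng.normal(0, 0.5, n)
        sel = FamilyAurocSelector(random_state=0, max_subset_size=2)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sel.fit(X, y)
        assert "SpO2_occ" in sel.selected_columns_
        out = sel.transform(X)
        assert list(out.columns) == sel.selected_columns_
        assert sel.get_support().sum() == len(sel.selected_columns_)
        assert sel.fit_n_rows_ == n

    def test_selection_and_threshold_see_only_training_rows(self, rng):
        """Structural no-leakage audit across the experiment grid."""
        from alarmcast.cohort import WindowSpec, make_cv_folds, split_train_test
        from alarmcast.features import FEATURE_COLUMNS
        from alarmcast.model import run_experiment_grid
        n = 300
        y = (rng.random(n) < 0.4).astype(int)
        X = pd.DataFrame(rng.normal(size=(n, 63)), columns=FEATURE_COLUMNS)
        X["SpO2_occ"] += 2.0 * y
        spec = WindowSpec(60, 60)
        plan = make_cv_folds(split_train_test(y, 0.8, 0), y, 5, 0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rep, det = run_experiment_grid({spec: (X, y)}, {spec: plan}, seed=0,
                                           n_rounds=20, max_subset_size=2)
        sel = det[spec]["selector"]
        assert sel.fit_n_rows_ == plan.train_idx.size
        assert np.intersect1d(plan.train_idx, plan.test_idx).size == 0
        for tr, va in plan.cv_folds:
            assert np.intersect1d(va, plan.test_idx).size == 0
        assert len(rep) == 10  # 8 families + pooled tree + boosted
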