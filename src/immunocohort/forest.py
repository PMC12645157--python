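"""Random-forest classification: OOB depth tuning, Gini importance, AUC curves.

Maximum tree depth is the one constrained hyperparameter: within each of k
stratified folds, forests are fitted at every depth in a grid on the
training part and scored by out-of-bag accuracy; the per-fold best depths
are combined by mode (smallest wins ties at both levels). A final forest
at the chosen depth, trained on the full data, supplies Gini
impurity-decrease importances, and incremental forests on the top-N
important variables trace an AUC-vs-N curve.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .model_selection import CvCurve, _fold_ci, auc_roc, stratified_kfold

logger = logging.getLogger(__name__)

DEFAULT_DEPTH_GRID = (2, 3, 4, 5, 7, 10, None)


def _depth_key(d):
    return np.inf if d is None else d


def choose_depth(per_fold_choices: list) -> object:
    """Mode of the per-fold depth choices; the smallest depth wins a tie."""
    if not per_fold_choices:
        raise ValueError("no per-fold choices")
    counts = Counter(per_fold_choices)
    best = max(counts.values())
    candidates = [d for d, c in counts.items() if c == best]
    return min(candidates, key=_depth_key)


def _forest(depth, n_trees, seed, oob=False):
    return RandomForestClassifier(
        n_estimators=n_trees,
        max_depth=depth,
        oob_score=oob,
        random_state=seed,
        n_jobs=1,
        bootstrap=True,
    )


def tune_depth_oob(
    table_df: pd.DataFrame,
    labels: np.ndarray,
    depth_grid=DEFAULT_DEPTH_GRID,
    k: int = 10,
    seed: int = 0,
    n_trees: int = 500,
) -> tuple[object, pd.DataFrame]:
    """Choose max depth by per-fold OOB score, then take the across-fold mode.

    Returns (chosen_depth, per-fold table with columns fold, depth, oob).
    Within each fold the best depth is the OOB-score argmax, smallest depth
    on ties.
    """
    if not len(depth_grid):
        raise ValueError("empty depth grid")
    y = np.asarray(labels)
    folds = stratified_kfold(y, k, seed)
    X = table_df.to_numpy(dtype=float)
    rows = []
    per_fold_best = []
    for f in range(k):
        tr = folds != f
        best_depth, best_score = None, -np.inf
        for depth in depth_grid:
            clf = _forest(depth, n_trees, seed, oob=True)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # few-OOB-samples warnings at tiny n
                clf.fit(X[tr], y[tr])
            score = getattr(clf, "oob_score_", np.nan)
            if not np.isfinite(score):
                continue
            rows.append({"fold": f, "depth": depth, "oob": float(score)})
            if score > best_score or (score == best_score and _depth_key(depth) < _depth_key(best_depth)):
                best_depth, best_score = depth, score
        if best_depth is None:
            raise ValueError(f"OOB score undefined at every depth in fold {f} (too few trees?)")
        per_fold_best.append(best_depth)
    chosen = choose_depth(per_fold_best)
    table = pd.DataFrame(rows)
    table.attrs["per_fold_best"] = per_fold_best
    table.attrs["chosen_depth"] = chosen
    return chosen, table


@dataclass
class ImportanceRanking:
    """Gini impurity-decrease importances, normalized to sum 1."""

    importances: dict[str, float]
    ordering: list[str]  # descending importance, name tie-break
    depth: object
    n_trees: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"variable": self.ordering,
             "gini_importance": [self.importances[v] for v in self.ordering]}
        )


def gini_ranking(
    table_df: pd.DataFrame,
    labels: np.ndarray,
    depth=None,
    n_trees: int = 500,
    seed: int = 0,
) -> ImportanceRanking:
    """Train one forest on the full data and rank variables by Gini importance."""
    X = table_df.to_numpy(dtype=float)
    zero_var = [v for v in table_df.columns if np.ptp(table_df[v].to_numpy()) == 0]
    if zero_var:
        logger.warning("zero-variance variables get zero importance: %s", zero_var)
    clf = _forest(depth, n_trees, seed)
    clf.fit(X, np.asarray(labels))
    imp = clf.feature_importances_
    total = imp.sum()
    if total > 0:
        imp = imp / total
    importances = {v: float(w) for v, w in zip(table_df.columns, imp)}
    ordering = sorted(importances, key=lambda v: (-importances[v], v))
    return ImportanceRanking(importances, ordering, depth, n_trees, seed)


def incremental_rf_curve(
    table_df: pd.DataFrame,
    labels: np.ndarray,
    ranking: ImportanceRanking,
    max_features: int = 200,
    k: int = 10,
    seed: int = 0,
    n_trees: int = 500,
    depth=None,
) -> CvCurve:
    """Stratified k-fold CV AUC of forests on the top-N important variables."""
    if table_df.isna().to_numpy().any():
        raise ValueError("table contains missing values; impute before model building")
    order = [v for v in ranking.ordering if v in table_df.columns]
    if max_features > len(order):
        logger.warning("max_features=%d exceeds %d ranked variables; truncating",
                       max_features, len(order))
        max_features = len(order)
    y = np.asarray(labels)
    folds = stratified_kfold(y, k, seed)
    use_depth = ranking.depth if depth is None else depth
    ns, means, lows, highs, fold_rows = [], [], [], [], []
    for n_feat in range(1, max_features + 1):
        X = table_df[order[:n_feat]].to_numpy(dtype=float)
        aucs = []
        for f in range(k):
            tr, te = folds != f, folds == f
            clf = _forest(use_depth, n_trees, seed)
            clf.fit(X[tr], y[tr])
            prob = clf.predict_proba(X[te])[:, list(clf.classes_).index(sorted(set(y))[-1])]
            aucs.append(auc_roc(prob, (y[te] == sorted(set(y))[-1]).astype(int)))
        m, lo, hi = _fold_ci(np.array(aucs))
        ns.append(n_feat)
        means.append(m)
        lows.append(lo)
        highs.append(hi)
        fold_rows.append(aucs)
    return CvCurve(
        n_features=ns, mean_auc=means, ci_low=lows, ci_high=highs,
        fold_aucs=np.array(fold_rows), seed=seed, ranking=order[:max_features],
    )
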