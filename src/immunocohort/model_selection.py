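"""Incremental L2-penalized logistic model building with cross-validated AUC.

Candidate variables are added one at a time in univariate-ranking order
(N = 1..max_features); at each N a ridge-penalized logistic regression —
with age and sex as unpenalized adjustment covariates — is fitted inside
each training fold of a stratified k-fold split and scored on the held-out
fold by AUC. The resulting AUC-vs-N curve identifies the number of
informative variables beyond which generalization declines.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold

logger = logging.getLogger(__name__)


def auc_roc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve as the Mann-Whitney concordance probability.

    (concordant pairs + 0.5 * tied pairs) / (n_pos * n_neg), computed via
    midranks.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if s.shape != y.shape:
        raise ValueError("scores and labels must have the same length")
    pos = y == 1
    n1 = int(pos.sum())
    n0 = int((~pos).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present to compute AUC")
    ranks = stats.rankdata(s)  # midranks handle ties as half-concordant
    u = ranks[pos].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def stratified_kfold(labels: np.ndarray, k: int, seed: int) -> np.ndarray:
    """Deterministic stratified fold assignment (0..k-1 per subject)."""
    y = np.asarray(labels)
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < k:
        raise ValueError(f"smallest class has {counts.min()} members, fewer than k={k}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignment = np.empty(len(y), dtype=int)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(len(y)), y)):
        assignment[test_idx] = fold
    return assignment


# ---------------------------------------------------------------------------
# ridge logistic with unpenalized covariates


def _ridge_logistic_fit(X: np.ndarray, y: np.ndarray, penalty_mask: np.ndarray,
                        lam: float) -> np.ndarray:
    """Minimize logistic negative log-likelihood + (lam/2)*||beta[mask]||^2.

    X includes an intercept column; the mask marks penalized columns.
    """
    n, p = X.shape
    mask = penalty_mask.astype(float)

    def objective(beta):
        eta = X @ beta
        # log(1 + exp(-z*eta)) written stably
        z = 2.0 * y - 1.0
        m = -z * eta
        nll = np.sum(np.logaddexp(0.0, m))
        pen = 0.5 * lam * np.sum(mask * beta**2)
        prob = 1.0 / (1.0 + np.exp(-np.clip(eta, -500, 500)))
        grad = X.T @ (prob - y) + lam * mask * beta
        return nll + pen, grad

    beta0 = np.zeros(p)
    res = optimize.minimize(objective, beta0, jac=True, method="L-BFGS-B",
                            options={"maxiter": 500, "gtol": 1e-7})
    if not res.success:
        logger.debug("ridge logistic optimizer: %s", res.message)
    return res.x


def ridge_logistic_scores(
    X_train: np.ndarray, y_train: np.ndarray, X_test: np.ndarray,
    n_penalized: int, lam: float,
) -> np.ndarray:
    """Fit on the training matrix (first ``n_penalized`` columns penalized,
    the rest unpenalized covariates; intercept added internally) and return
    linear scores for the test matrix."""
    Xtr = np.column_stack([np.ones(len(X_train)), X_train])
    Xte = np.column_stack([np.ones(len(X_test)), X_test])
    mask = np.zeros(Xtr.shape[1], dtype=bool)
    mask[1 : 1 + n_penalized] = True
    beta = _ridge_logistic_fit(Xtr, y_train, mask, lam)
    return Xte @ beta


# ---------------------------------------------------------------------------
# the incremental curve


@dataclass
class CvCurve:
    """AUC-vs-number-of-features curve from stratified k-fold CV."""

    n_features: list[int]
    mean_auc: list[float]
    ci_low: list[float]
    ci_high: list[float]
    fold_aucs: np.ndarray  # shape (len(n_features), k)
    seed: int
    ranking: list[str] = field(default_factory=list)
    #: per-fold held-out scores/labels at the largest N evaluated
    fold_scores: list = field(default_factory=list, repr=False)
    fold_labels: list = field(default_factory=list, repr=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "n_features": self.n_features,
                "mean_auc": self.mean_auc,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
            }
        )


def _fold_ci(fold_aucs: np.ndarray) -> tuple[float, float, float]:
    """Mean AUC with a t-interval across folds."""
    k = len(fold_aucs)
    m = float(np.mean(fold_aucs))
    if k < 2:
        return m, m, m
    sd = float(np.std(fold_aucs, ddof=1))
    half = stats.t.ppf(0.975, k - 1) * sd / np.sqrt(k)
    return m, m - half, m + half


def incremental_l2_curve(
    table_df: pd.DataFrame,
    labels: np.ndarray,
    age: np.ndarray,
    sex: np.ndarray,
    ranking: list[str],
    max_features: int = 200,
    k: int = 10,
    seed: int = 0,
    penalty: float = 1.0,
    nested_ranking: bool = False,
) -> CvCurve:
    """AUC-vs-N curve for ridge logistic models on the top-N ranked variables.

    The table must be complete (post-imputation). Age and sex enter every
    model as unpenalized covariates. The fold split is fixed once (per
    seed) and reused across N so curve points are comparable.

    With ``nested_ranking=False`` (the literal protocol) the supplied
    full-data ranking is used in every fold; chance associations selected
    on the full data then leak optimism into the held-out AUC, flattening
    the decline beyond the informative variables. ``nested_ranking=True``
    re-ranks candidates inside each training fold (honest nested CV), at
    the cost of one univariate scan per fold.
    """
    missing = [v for v in ranking if v not in table_df.columns]
    if missing:
        raise KeyError(f"ranked variables absent from table: {missing}")
    if table_df.isna().to_numpy().any():
        raise ValueError("table contains missing values; impute before model building")
    y = np.asarray(labels, dtype=float)
    if max_features > len(ranking):
        logger.warning("max_features=%d exceeds %d ranked variables; truncating",
                       max_features, len(ranking))
        max_features = len(ranking)
    folds = stratified_kfold(y, k, seed)
    sex_arr = np.asarray(sex)
    sex_ind = np.asarray([1.0 if s == "M" else 0.0 for s in sex_arr])
    a = np.asarray(age, dtype=float)
    za = (a - a.mean()) / a.std(ddof=1)
    covars = np.column_stack([za, sex_ind])

    if nested_ranking:
        from .association import fit_logistic_association
        from .association import rank_by_pvalue as _rank

        fold_order = []
        for f in range(k):
            tr = folds != f
            recs = [
                fit_logistic_association(
                    table_df[v].to_numpy()[tr], y[tr], a[tr], sex_arr[tr], variable=v)
                for v in ranking
            ]
            fold_order.append(_rank(recs))
        fold_X = [table_df[order[:max_features]].to_numpy(dtype=float)
                  for order in fold_order]
    else:
        full_X = table_df[ranking[:max_features]].to_numpy(dtype=float)
        fold_X = [full_X] * k

    ns, means, lows, highs = [], [], [], []
    fold_auc_rows = []
    last_scores: list[np.ndarray] = []
    last_labels: list[np.ndarray] = []
    for n_feat in range(1, max_features + 1):
        aucs = []
        scores_per_fold, labels_per_fold = [], []
        for f in range(k):
            X = np.column_stack([fold_X[f][:, :n_feat], covars])
            tr, te = folds != f, folds == f
            sc = ridge_logistic_scores(X[tr], y[tr], X[te], n_feat, penalty)
            aucs.append(auc_roc(sc, y[te]))
            scores_per_fold.append(sc)
            labels_per_fold.append(y[te])
        m, lo, hi = _fold_ci(np.array(aucs))
        ns.append(n_feat)
        means.append(m)
        lows.append(lo)
        highs.append(hi)
        fold_auc_rows.append(aucs)
        last_scores, last_labels = scores_per_fold, labels_per_fold
    return CvCurve(
        n_features=ns,
        mean_auc=means,
        ci_low=lows,
        ci_high=highs,
        fold_aucs=np.array(fold_auc_rows),
        seed=seed,
        ranking=list(ranking[:max_features]),
        fold_scores=last_scores,
        fold_labels=last_labels,
    )


def cv_scores_at_n(
    table_df: pd.DataFrame, labels, age, sex, ranking, n_feat: int,
    k: int = 10, seed: int = 0, penalty: float = 1.0,
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Per-fold held-out scores and labels for a fixed feature count
    (input to :func:`averaged_roc`)."""
    y = np.asarray(labels, dtype=float)
    folds = stratified_kfold(y, k, seed)
    sex_ind = np.asarray([1.0 if s == "M" else 0.0 for s in sex])
    a = np.asarray(age, dtype=float)
    za = (a - a.mean()) / a.std(ddof=1)
    X = np.column_stack([table_df[ranking[:n_feat]].to_numpy(dtype=float), za, sex_ind])
    scores, labs = [], []
    for f in range(k):
        tr, te = folds != f, folds == f
        scores.append(ridge_logistic_scores(X[tr], y[tr], X[te], n_feat, penalty))
        labs.append(y[te])
    return scores, labs


def select_optimal_n(curve: CvCurve) -> int:
    """Smallest N attaining the maximum mean AUC."""
    if not curve.n_features:
        raise ValueError("empty curve")
    means = np.asarray(curve.mean_auc)
    return int(curve.n_features[int(np.argmax(means))])


def averaged_roc(
    fold_scores: list[np.ndarray],
    fold_labels: list[np.ndarray],
    grid_size: int = 101,
) -> pd.DataFrame:
    """Vertically average per-fold ROC curves on a fixed FPR grid.

    Returns a DataFrame with columns fpr, tpr_mean, tpr_ci_low, tpr_ci_high;
    the CI is mean +/- 1.96 * SD / sqrt(k) (normal approximation across
    folds). Folds containing a single class are skipped with a warning.
    """
    if len(fold_scores) < 2:
        raise ValueError("need >= 2 folds to average")
    grid = np.linspace(0.0, 1.0, grid_size)
    tprs = []
    for sc, y in zip(fold_scores, fold_labels):
        y = np.asarray(y)
        if len(np.unique(y)) < 2:
            logger.warning("skipping single-class fold in ROC averaging")
            continue
        fpr, tpr, _ = roc_curve(y, sc)
        tprs.append(np.interp(grid, fpr, tpr))
    if not tprs:
        raise ValueError("no usable folds")
    T = np.vstack(tprs)
    mean = T.mean(axis=0)
    sd = T.std(axis=0, ddof=1) if len(tprs) > 1 else np.zeros_like(mean)
    half = 1.959963984540054 * sd / np.sqrt(len(tprs))
    return pd.DataFrame(
        {
            "fpr": grid,
            "tpr_mean": mean,
            "tpr_ci_low": np.clip(mean - half, 0.0, 1.0),
            "tpr_ci_high": np.clip(mean + half, 0.0, 1.0),
        }
    )
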