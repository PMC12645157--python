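"""Serology-stratified group tests, severity trends and correlation structure.

These operations back the clinical-structure analyses: Mann-Whitney
comparisons within serology-defined strata with Benjamini-Hochberg FDR
control, Kruskal-Wallis followed by pairwise tests for serostatus x
disease groups, disease x serostatus interaction models, an ordered
(Jonckheere-Terpstra) trend test across MMSE cognition bands, Spearman
correlation against fluid biomarkers, and a Fisher-z test for deviation of
AD correlation structure from the healthy-control correlation structure.
BH adjustment is always applied within one analysis family, never pooled
across families.
"""

from __future__ import annotations

import itertools
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

#: largest combined sample size for which exact Mann-Whitney p is used (no ties)
EXACT_MWU_MAX_N = 12
#: largest total sample size for which the trend test enumerates exactly
EXACT_JT_MAX_N = 10


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Mann-Whitney U of x vs y with a two-sided p.

    Exact p for combined n <= 12 without ties, normal approximation with
    tie correction otherwise. Returns (U statistic of x, p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(pooled) <= EXACT_MWU_MAX_N and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def benjamini_hochberg(pvalues: Sequence[float]) -> np.ndarray:
    """BH step-up adjusted p-values, order-preserving."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def kruskal_wallis_pairwise(groups: Sequence[Sequence[float]],
                            labels: Sequence[str] | None = None
                            ) -> tuple[float, float, pd.DataFrame]:
    """Kruskal-Wallis global test plus pairwise Mann-Whitney with BH correction.

    Returns (H, global p, pairwise BH-adjusted p matrix). The matrix is
    symmetric with unit diagonal; BH is applied across the pairwise family
    within this call.
    """
    if len(groups) < 3:
        raise ValueError("need >= 3 groups (use mann_whitney_u for two)")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("all groups must be non-empty")
    labels = list(labels) if labels is not None else [f"group{i}" for i in range(len(arrays))]
    h, p_global = stats.kruskal(*arrays)
    m = len(arrays)
    raw = []
    idx_pairs = list(itertools.combinations(range(m), 2))
    for i, j in idx_pairs:
        raw.append(mann_whitney_u(arrays[i], arrays[j])[1])
    adj = benjamini_hochberg(raw)
    mat = pd.DataFrame(np.ones((m, m)), index=labels, columns=labels)
    for (i, j), q in zip(idx_pairs, adj):
        mat.iloc[i, j] = mat.iloc[j, i] = q
    return float(h), float(p_global), mat


def interaction_test(
    variable: np.ndarray,
    disease: np.ndarray,
    stratum: np.ndarray,
    age: np.ndarray,
    sex: Sequence[str],
) -> tuple[float, float]:
    """Disease x stratum interaction in a linear model adjusted for age and sex.

    Fits variable ~ disease + stratum + disease:stratum + age + sexM by OLS
    and returns (interaction coefficient, Wald p). Errors if any of the
    four disease x stratum cells is empty or the stratum is constant.
    """
    v = np.asarray(variable, dtype=float)
    d = np.asarray(disease, dtype=float)
    s = np.asarray(stratum, dtype=float)
    a = np.asarray(age, dtype=float)
    keep = np.isfinite(v) & np.isfinite(d) & np.isfinite(s) & np.isfinite(a)
    v, d, s, a = v[keep], d[keep], s[keep], a[keep]
    sx = np.asarray([1.0 if t == "M" else 0.0 for t in np.asarray(sex)[keep]])
    if len(np.unique(s)) < 2:
        raise ValueError("stratum is constant")
    for dv in (0, 1):
        for sv in (0, 1):
            if not np.any((d == dv) & (s == sv)):
                raise ValueError(f"empty cell: disease={dv}, stratum={sv}")
    X = sm.add_constant(np.column_stack([d, s, d * s, a, sx]), prepend=True)
    res = sm.OLS(v, X).fit()
    return float(res.params[3]), float(res.pvalues[3])


# ---------------------------------------------------------------------------
# Jonckheere-Terpstra ordered trend test


def _jt_statistic(groups: list[np.ndarray]) -> float:
    """Count of ascending cross-group pairs; ties weighted 1/2."""
    jt = 0.0
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            xi = groups[i][:, None]
            xj = groups[j][None, :]
            jt += np.sum(xj > xi) + 0.5 * np.sum(xj == xi)
    return float(jt)


def _jt_exact_tail(pooled: np.ndarray, sizes: list[int], observed: float) -> tuple[float, float]:
    """Exact one-sided tails by enumerating all assignments of the pooled
    values to the ordered groups (distinct permutations of a multiset)."""
    n = len(pooled)
    idx = list(range(n))
    seen = set()
    stats_all = []

    def assignments(remaining: tuple, sizes_left: list[int], chosen: list):
        if not sizes_left:
            stats_all.append(_jt_statistic([pooled[list(c)] for c in chosen]))
            return
        k = sizes_left[0]
        for combo in itertools.combinations(remaining, k):
            rest = tuple(i for i in remaining if i not in combo)
            assignments(rest, sizes_left[1:], chosen + [combo])

    assignments(tuple(idx), sizes, [])
    arr = np.array(stats_all)
    p_ge = float(np.mean(arr >= observed - 1e-12))
    p_le = float(np.mean(arr <= observed + 1e-12))
    return p_ge, p_le


def ordered_trend_test(groups: Sequence[Sequence[float]],
                       alternative: str = "increasing") -> tuple[float, float]:
    """Jonckheere-Terpstra trend test across ordered groups.

    The statistic counts ascending cross-group pairs (ties half-weighted).
    Exact p by enumeration when the total sample size is <= 10, otherwise a
    normal approximation. ``alternative`` is "increasing", "decreasing" or
    "two-sided".
    """
    arrays = [np.asarray(g, dtype=float) for g in groups if len(g) > 0]
    if len(arrays) < 2:
        raise ValueError("need >= 2 non-empty ordered groups")
    jt = _jt_statistic(arrays)
    sizes = [len(a) for a in arrays]
    n = sum(sizes)
    if n <= EXACT_JT_MAX_N:
        pooled = np.concatenate(arrays)
        p_ge, p_le = _jt_exact_tail(pooled, sizes, jt)
    else:
        mean = (n**2 - sum(s**2 for s in sizes)) / 4.0
        var = (n**2 * (2 * n + 3) - sum(s**2 * (2 * s + 3) for s in sizes)) / 72.0
        z = (jt - mean) / np.sqrt(var)
        p_ge = float(stats.norm.sf(z))
        p_le = float(stats.norm.cdf(z))
    if alternative == "increasing":
        p = p_ge
    elif alternative == "decreasing":
        p = p_le
    elif alternative == "two-sided":
        p = min(1.0, 2.0 * min(p_ge, p_le))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return jt, float(p)


def spearman_correlation(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with pairwise deletion of incomplete pairs."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 4:
        raise ValueError(f"need >= 4 complete pairs, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def correlation_deviation(
    table_hc: pd.DataFrame,
    table_ad: pd.DataFrame,
    variable_pairs: list[tuple[str, str]],
) -> pd.DataFrame:
    """Fisher-z test for each variable pair: does the AD correlation deviate
    from the healthy-control correlation?

    z = (atanh r_hc - atanh r_ad) / sqrt(1/(n_hc-3) + 1/(n_ad-3)); p values
    are BH-adjusted across the supplied pairs.
    """
    rows = []
    for va, vb in variable_pairs:
        sub_hc = table_hc[[va, vb]].dropna()
        sub_ad = table_ad[[va, vb]].dropna()
        n_hc, n_ad = len(sub_hc), len(sub_ad)
        if min(n_hc, n_ad) < 10:
            raise ValueError(f"pair ({va}, {vb}): need >= 10 complete subjects per group")
        r_hc = float(np.corrcoef(sub_hc[va], sub_hc[vb])[0, 1])
        r_ad = float(np.corrcoef(sub_ad[va], sub_ad[vb])[0, 1])
        if abs(r_hc) >= 1.0 or abs(r_ad) >= 1.0:
            raise ValueError(f"pair ({va}, {vb}): |r| = 1, Fisher z undefined")
        z = (np.arctanh(r_hc) - np.arctanh(r_ad)) / np.sqrt(1.0 / (n_hc - 3) + 1.0 / (n_ad - 3))
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append({"var_a": va, "var_b": vb, "r_hc": r_hc, "r_ad": r_ad,
                     "n_hc": n_hc, "n_ad": n_ad, "z": float(z), "p": float(p)})
    out = pd.DataFrame(rows)
    out["p_bh"] = benjamini_hochberg(out["p"].to_numpy())
    return out


def group_tests(
    table_df: pd.DataFrame,
    disease: np.ndarray,
    variables: list[str],
    subset_mask: np.ndarray | None = None,
    subset_expression: str = "all",
) -> pd.DataFrame:
    """Mann-Whitney AD-vs-HC comparison per variable within a declarative subset.

    ``subset_mask`` restricts subjects (e.g. EBV-seropositive only);
    ``subset_expression`` is recorded verbatim in the output so the family
    membership and the filter are explicit. BH is applied within this call.
    """
    mask = np.ones(len(table_df), dtype=bool) if subset_mask is None else np.asarray(subset_mask, bool)
    d = np.asarray(disease)[mask]
    rows = []
    for v in variables:
        vals = table_df[v].to_numpy()[mask]
        obs = np.isfinite(vals)
        x = vals[obs & (d == 1)]
        y = vals[obs & (d == 0)]
        u, p = mann_whitney_u(x, y)
        rows.append({"variable": v, "subset": subset_expression, "n_ad": len(x),
                     "n_hc": len(y), "U": u, "p": p})
    out = pd.DataFrame(rows)
    out["p_bh"] = benjamini_hochberg(out["p"].to_numpy())
    return out
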