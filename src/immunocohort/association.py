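"""Per-variable covariate-adjusted association with disease status and age.

For each immune variable a logistic regression of disease status (AD vs
HC) on the variable plus age and sex yields an odds ratio with Wald 95% CI
and p value; a linear regression of the variable on z-scored age plus sex
(optionally within one group) yields the age beta. The univariate p-value
ranking feeds the incremental model-building stage. Records that fail to
converge or show (quasi-)complete separation are flagged unusable rather
than reported with runaway estimates.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

logger = logging.getLogger(__name__)


@dataclass
class AssociationRecord:
    variable: str
    model: str  # "logistic_disease" or "linear_age"
    estimate: Optional[float]  # OR for logistic, beta for linear
    ci_low: Optional[float]
    ci_high: Optional[float]
    p: Optional[float]
    n_used: int
    p_adjusted: Optional[float] = None
    flag: Optional[str] = None  # e.g. "separation", "non_convergence"

    @property
    def usable(self) -> bool:
        return self.flag is None and self.p is not None


def _sex_indicator(sex: Sequence[str]) -> np.ndarray:
    # reference level F (alphabetical); single indicator for M
    return np.asarray([1.0 if s == "M" else 0.0 for s in sex])


def fit_logistic_association(
    values: np.ndarray,
    disease: np.ndarray,
    age: np.ndarray | None = None,
    sex: Sequence[str] | None = None,
    variable: str = "",
    min_per_class: int = 10,
) -> AssociationRecord:
    """Logistic fit of disease (1=AD) on the variable, adjusting for age and sex.

    Returns OR = exp(variable coefficient) with Wald 95% CI and p.
    Covariates are optional (omit both for an unadjusted fit). Separation or
    non-convergence flags the record unusable; the estimate is set missing
    rather than reported at an absurd magnitude.
    """
    y = np.asarray(disease, dtype=float)
    x = np.asarray(values, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    cols = [x]
    names = ["variable"]
    if age is not None:
        a = np.asarray(age, dtype=float)
        keep &= np.isfinite(a)
        cols.append(a)
        names.append("age")
    if sex is not None:
        cols.append(_sex_indicator(sex))
        names.append("sexM")
    X = np.column_stack(cols)[keep]
    y = y[keep]
    n_used = int(keep.sum())
    rec = AssociationRecord(variable, "logistic_disease", None, None, None, None, n_used)
    n1, n0 = int(y.sum()), int((1 - y).sum())
    if min(n1, n0) < min_per_class:
        rec.flag = "too_few_subjects"
        return rec
    X = sm.add_constant(X, prepend=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        if not res.mle_retvals.get("converged", False):
            rec.flag = "non_convergence"
            return rec
        coef = res.params[1]
        se = res.bse[1]
        if not np.isfinite(se) or abs(coef) > 15 or se > 50:
            rec.flag = "separation"
            return rec
        rec.estimate = float(np.exp(coef))
        rec.ci_low = float(np.exp(coef - 1.959963984540054 * se))
        rec.ci_high = float(np.exp(coef + 1.959963984540054 * se))
        rec.p = float(res.pvalues[1])
    except (PerfectSeparationError, PerfectSeparationWarning):
        rec.flag = "separation"
    except np.linalg.LinAlgError:
        rec.flag = "singular_design"
    return rec


def fit_age_association(
    values: np.ndarray,
    age: np.ndarray,
    sex: Sequence[str],
    group: Sequence[str] | None = None,
    subset: str = "all",
    variable: str = "",
) -> AssociationRecord:
    """OLS of the (standardized) variable on z-scored age plus sex.

    ``subset`` restricts to "AD", "HC" or "all" (requires ``group``
    when not "all"). Reports beta, Wald 95% CI and p for the age term.
    """
    x = np.asarray(values, dtype=float)
    a = np.asarray(age, dtype=float)
    keep = np.isfinite(x) & np.isfinite(a)
    if subset != "all":
        if group is None:
            raise ValueError("group labels required for subset fits")
        keep &= np.asarray(group) == subset
    x, a = x[keep], a[keep]
    s = _sex_indicator(np.asarray(sex)[keep])
    n_used = int(keep.sum())
    if n_used < 10:
        raise ValueError(f"need >= 10 subjects in subset {subset!r}, got {n_used}")
    if np.ptp(a) == 0:
        raise ValueError(f"age is constant in subset {subset!r}")
    za = (a - a.mean()) / a.std(ddof=1)
    X = sm.add_constant(np.column_stack([za, s]), prepend=True)
    res = sm.OLS(x, X).fit()
    coef, se = res.params[1], res.bse[1]
    return AssociationRecord(
        variable,
        f"linear_age_{subset}",
        float(coef),
        float(coef - 1.959963984540054 * se),
        float(coef + 1.959963984540054 * se),
        float(res.pvalues[1]),
        n_used,
    )


def associate_all(
    table_df: pd.DataFrame,
    disease: np.ndarray,
    age: np.ndarray,
    sex: Sequence[str],
) -> list[AssociationRecord]:
    """Disease-association scan over every variable, with BH adjustment across the scan."""
    records = [
        fit_logistic_association(table_df[v].to_numpy(), disease, age, sex, variable=v)
        for v in table_df.columns
    ]
    usable = [r for r in records if r.usable]
    if usable:
        adj = multipletests([r.p for r in usable], method="fdr_bh")[1]
        for r, q in zip(usable, adj):
            r.p_adjusted = float(q)
    n_flagged = len(records) - len(usable)
    if n_flagged:
        logger.warning("%d of %d variables flagged unusable in association scan", n_flagged, len(records))
    return records


def rank_by_pvalue(records: list[AssociationRecord]) -> list[str]:
    """Variables ordered by ascending p; ties by |log OR| descending, then name.

    Flagged-unusable records sort last (by name among themselves).
    """
    if not records:
        raise ValueError("no records to rank")
    models = {r.model for r in records}
    if len(models) > 1:
        raise ValueError(f"records mix model families: {sorted(models)}")

    def key(r: AssociationRecord):
        if not r.usable:
            return (1, 0.0, 0.0, r.variable)
        effect = abs(np.log(r.estimate)) if r.estimate and r.estimate > 0 else abs(r.estimate or 0.0)
        return (0, r.p, -effect, r.variable)

    return [r.variable for r in sorted(records, key=key)]


def records_frame(records: list[AssociationRecord]) -> pd.DataFrame:
    """Forest-plot-ready table: one row per record, none silently dropped."""
    return pd.DataFrame(
        {
            "variable": [r.variable for r in records],
            "model": [r.model for r in records],
            "n": [r.n_used for r in records],
            "estimate": [r.estimate for r in records],
            "ci_low": [r.ci_low for r in records],
            "ci_high": [r.ci_high for r in records],
            "p": [r.p for r in records],
            "p_bh": [r.p_adjusted for r in records],
            "flag": [r.flag for r in records],
        }
    )
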