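"""Missingness filtering, Box-Cox normalization, z-scoring and kNN imputation.

The preprocessing chain mirrors standard practice for cytometry
population-frequency panels: variables with more than a fixed fraction of
missing cells (default 20%) are dropped; each surviving variable is
Box-Cox transformed with a per-variable maximum-likelihood lambda (bounded,
default [-5, 5]); transformed variables are z-scored across all subjects
pooled; remaining missing cells are filled by k-nearest-neighbour
imputation (Euclidean distance over shared observed variables, default
k=3). Transform parameters are captured in a :class:`TransformSpec` so the
identical mapping can be reapplied to new subjects.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.metrics.pairwise import nan_euclidean_distances

from .cohort import CohortTable, CohortValidationError

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# missingness filter


def filter_missingness(table: CohortTable, threshold: float = 0.20) -> tuple[CohortTable, pd.DataFrame]:
    """Drop variables whose missing fraction strictly exceeds ``threshold``.

    A variable with missing fraction exactly equal to the threshold is kept.
    Subjects are untouched. Returns the filtered table and a report listing
    each dropped variable with its missing fraction.
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must lie in (0, 1)")
    if table.n_subjects == 0 or table.n_variables == 0:
        raise CohortValidationError("cannot filter an empty table")
    frac = table.missing_fraction()
    dropped = frac[frac > threshold]
    kept = [v for v in table.variable_names if v not in set(dropped.index)]
    report = pd.DataFrame({"variable": dropped.index, "missing_fraction": dropped.values})
    filtered = CohortTable(table.data[kept].copy(), provenance=table.provenance, scale=table.scale)
    return filtered, report


# ---------------------------------------------------------------------------
# Box-Cox


def compute_shift(values: np.ndarray) -> float:
    """Positivity shift: 1 - min(x) when min(x) <= 0, else 0."""
    finite = values[np.isfinite(values)]
    if finite.size == 0:
        raise ValueError("no observed values")
    m = float(finite.min())
    return 1.0 - m if m <= 0 else 0.0


def fit_boxcox_lambda(values: np.ndarray, bounds: tuple[float, float] = (-5.0, 5.0),
                      shift: float = 0.0) -> float:
    """Maximum-likelihood Box-Cox lambda, clamped to ``bounds``.

    Maximizes the Box-Cox profile log-likelihood over lambda for the shifted
    values using bounded scalar optimization. Requires at least 10 observed
    values, all strictly positive after the shift. A zero-variance input
    returns lambda = 1 (identity up to affine) with a warning.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)] + shift
    if x.size < 10:
        raise ValueError(f"need >= 10 observed values to fit lambda, got {x.size}")
    if np.min(x) <= 0:
        raise ValueError("values must be strictly positive after shift")
    if np.ptp(x) == 0:
        logger.warning("zero-variance input to fit_boxcox_lambda; returning lambda=1")
        return 1.0
    lo, hi = bounds
    if not lo < hi:
        raise ValueError("bounds must satisfy lower < upper")
    res = optimize.minimize_scalar(
        lambda lam: -stats.boxcox_llf(lam, x), bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-5},
    )
    lam = float(np.clip(res.x, lo, hi))
    # the bounded optimizer never sits exactly on a bound; snap when the
    # profile likelihood is still climbing at the boundary
    for b in (lo, hi):
        if abs(lam - b) < 1e-3 and stats.boxcox_llf(b, x) >= stats.boxcox_llf(lam, x):
            lam = float(b)
    return lam


def apply_boxcox(values: np.ndarray, lam: float, shift: float = 0.0) -> np.ndarray:
    """Box-Cox transform: ((x+shift)^lam - 1)/lam, or ln(x+shift) at lam = 0.

    Missing (NaN) entries stay missing.
    """
    x = np.asarray(values, dtype=float)
    out = np.full_like(x, np.nan)
    obs = np.isfinite(x)
    shifted = x[obs] + shift
    if np.any(shifted <= 0):
        bad = np.nonzero(obs)[0][shifted <= 0]
        raise ValueError(f"non-positive shifted value at positions {bad.tolist()}")
    if lam == 0:
        out[obs] = np.log(shifted)
    else:
        out[obs] = (shifted**lam - 1.0) / lam
    return out


def standardize(values: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Z-score the observed entries; returns (z, mean, sd) with sample SD (ddof=1)."""
    x = np.asarray(values, dtype=float)
    obs = np.isfinite(x)
    if obs.sum() < 2:
        raise ValueError("need >= 2 observed values to standardize")
    mean = float(x[obs].mean())
    sd = float(x[obs].std(ddof=1))
    if sd == 0:
        raise ValueError("zero variance: variable should be excluded")
    out = np.full_like(x, np.nan)
    out[obs] = (x[obs] - mean) / sd
    return out, mean, sd


@dataclass
class TransformSpec:
    """Per-variable Box-Cox + z-score parameters, fit once and reapplicable."""

    lambdas: dict[str, float] = field(default_factory=dict)
    shifts: dict[str, float] = field(default_factory=dict)
    means: dict[str, float] = field(default_factory=dict)
    sds: dict[str, float] = field(default_factory=dict)
    bounds: tuple[float, float] = (-5.0, 5.0)
    fitted_on: int = 0

    def save(self, path: str | Path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            json.dump(
                {
                    "lambdas": self.lambdas,
                    "shifts": self.shifts,
                    "means": self.means,
                    "sds": self.sds,
                    "bounds": list(self.bounds),
                    "fitted_on": self.fitted_on,
                },
                fh,
                indent=2,
            )

    @classmethod
    def load(cls, path: str | Path) -> "TransformSpec":
        with open(path) as fh:
            d = json.load(fh)
        d["bounds"] = tuple(d["bounds"])
        return cls(**d)


def fit_transform(table: CohortTable, bounds: tuple[float, float] = (-5.0, 5.0)
                  ) -> tuple[CohortTable, TransformSpec]:
    """Fit and apply the Box-Cox + z-score chain on all subjects pooled.

    Zero-variance variables are dropped with a warning (they carry no
    information and cannot be standardized).
    """
    spec = TransformSpec(bounds=bounds, fitted_on=table.n_subjects)
    cols = {}
    for v in table.variable_names:
        x = table.data[v].to_numpy()
        obs = x[np.isfinite(x)]
        if obs.size >= 2 and np.ptp(obs) == 0:
            logger.warning("dropping zero-variance variable %s", v)
            continue
        shift = compute_shift(x)
        lam = fit_boxcox_lambda(x, bounds=bounds, shift=shift)
        y = apply_boxcox(x, lam, shift)
        z, mean, sd = standardize(y)
        spec.lambdas[v] = lam
        spec.shifts[v] = shift
        spec.means[v] = mean
        spec.sds[v] = sd
        cols[v] = z
    out = pd.DataFrame(cols, index=table.data.index)
    return CohortTable(out, provenance=table.provenance + " | boxcox+zscore",
                       scale="transformed"), spec


def apply_transform(table: CohortTable, spec: TransformSpec) -> CohortTable:
    """Reapply a previously fitted TransformSpec to (possibly new) subjects."""
    cols = {}
    for v, lam in spec.lambdas.items():
        x = table.data[v].to_numpy()
        y = apply_boxcox(x, lam, spec.shifts[v])
        z = (y - spec.means[v]) / spec.sds[v]
        cols[v] = z
    out = pd.DataFrame(cols, index=table.data.index)
    return CohortTable(out, provenance=table.provenance + " | transform reapplied",
                       scale="transformed")


# ---------------------------------------------------------------------------
# kNN imputation


def _check_standardized(values: np.ndarray) -> bool:
    col_means = np.nanmean(values, axis=0)
    col_sds = np.nanstd(values, axis=0)
    return bool(np.all(np.abs(col_means) < 0.75) and np.all((col_sds > 0.2) & (col_sds < 5.0)))


def knn_impute(table: CohortTable, k: int = 3, aggregate: str = "median",
               allow_unstandardized: bool = False) -> CohortTable:
    """Fill missing cells from the ``k`` nearest subjects.

    Distance between two subjects is the Euclidean distance over variables
    observed in both, rescaled by sqrt(n_variables / n_shared) (the standard
    partial-distance convention, so subjects sharing few variables are not
    artificially close). Each missing cell is replaced by the median
    (configurable to mean) of that variable's values among the k nearest
    donors that observe it; if fewer than k donors observe the variable the
    available ones are used with a logged warning. Ties in donor distance
    are broken by subject order for determinism.

    The input is expected on the standardized scale so variables contribute
    comparably to the distance; a crude scale check refuses raw-percent
    input unless ``allow_unstandardized=True``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if aggregate not in ("median", "mean"):
        raise ValueError("aggregate must be 'median' or 'mean'")
    vals = table.data.to_numpy(dtype=float)
    n, p = vals.shape
    if not table.data.isna().to_numpy().any():
        return table
    if not allow_unstandardized and not _check_standardized(vals):
        raise ValueError(
            "table does not look standardized (means/SDs far from 0/1); "
            "transform first or pass allow_unstandardized=True"
        )
    obs = np.isfinite(vals)
    shared = obs.astype(float) @ obs.astype(float).T
    if np.any((shared - np.diag(np.diag(shared))).max(axis=1) == 0):
        lonely = [table.subject_ids[i] for i in range(n)
                  if (shared[i].sum() - shared[i, i]) == 0]
        raise ValueError(f"subjects share no observed variable with any donor: {lonely}")
    dist = nan_euclidean_distances(vals)  # partial-distance scaled by sqrt(p/shared)
    np.fill_diagonal(dist, np.inf)
    agg = np.nanmedian if aggregate == "median" else np.nanmean

    out = vals.copy()
    order = np.arange(n)
    for i in range(n):
        miss_j = np.nonzero(~obs[i])[0]
        if miss_j.size == 0:
            continue
        d = dist[i]
        # stable sort on (distance, subject order) for deterministic ties
        neighbour_order = np.lexsort((order, d))
        for j in miss_j:
            donors = [h for h in neighbour_order if obs[h, j] and np.isfinite(d[h])]
            if not donors:
                raise ValueError(
                    f"no donor observes variable {table.variable_names[j]!r} "
                    f"for subject {table.subject_ids[i]!r}"
                )
            chosen = donors[:k]
            if len(chosen) < k:
                logger.warning(
                    "only %d of %d donors available for subject %s, variable %s",
                    len(chosen), k, table.subject_ids[i], table.variable_names[j],
                )
            out[i, j] = agg(vals[chosen, j])
    df = pd.DataFrame(out, index=table.data.index, columns=table.data.columns)
    return CohortTable(df, provenance=table.provenance + f" | knn_impute(k={k})",
                       scale=table.scale)


def mean_impute(table: CohortTable) -> CohortTable:
    """Column-mean imputation (baseline comparator for kNN)."""
    df = table.data.fillna(table.data.mean(axis=0))
    return CohortTable(df, provenance=table.provenance + " | mean_impute", scale=table.scale)
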