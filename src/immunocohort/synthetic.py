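"""Synthetic case-control cohort generator with exported ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes in a memory-clinic cohort of Alzheimer's patients and their healthy
spouses:

* right-skewed percent-of-parent frequency distributions (log-normal);
* age and sex covariate effects on a subset of variables;
* a small set of disease-affected variables whose effect magnitude is
  graded by the patient's MMSE cognition band (worse cognition, larger
  shift);
* a shared-environment (cohabitation) component inducing within-pair
  correlation on a subset of variables;
* missingness concentrated in low-baseline-frequency populations, the
  pattern produced by gating sparse subsets.

Frequencies are generated as ``exp(mu_j + s_j * latent)`` where the latent
score is Gaussian with unit residual variance. Because the transform chain
(Box-Cox with lambda ~ 0, then z-scoring) inverts the exponential, effects
planted on the latent scale reappear as standardized mean differences on
the transformed scale, which makes parameter-recovery tests analytic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import CohortTable, SubjectRecord, MMSE_BANDS, validate_metadata

#: default MMSE-band severity multipliers: monotone ladder, worse cognition
#: -> larger planted effect, matching a step-wise severity gradient.
DEFAULT_SEVERITY_GRADIENT = {"25-30": 0.4, "20-24": 0.7, "10-19": 1.0, "<10": 1.3}

#: MMSE band mix for generated AD subjects (proportions of a 184-patient clinic cohort)
_MMSE_BAND_PROBS = np.array([33, 48, 80, 23], dtype=float) / 184.0


@dataclass
class SyntheticTruth:
    """Planted parameters of a generated cohort (the recovery-test oracle)."""

    affected_variables: list[str] = field(default_factory=list)
    effect_sizes: dict[str, float] = field(default_factory=dict)
    severity_gradient: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_SEVERITY_GRADIENT))
    shared_env_variables: list[str] = field(default_factory=list)
    shared_env_rho: float = 0.0
    age_slopes: dict[str, float] = field(default_factory=dict)
    missingness_base_rate: float = 0.05
    seed: int = 0

    def validate(self, variable_names: list[str] | None = None) -> None:
        if not (0.0 <= self.shared_env_rho < 1.0):
            raise ValueError(f"shared_env_rho must lie in [0, 1), got {self.shared_env_rho}")
        if set(self.effect_sizes) != set(self.affected_variables):
            raise ValueError("effect_sizes keys must match affected_variables")
        if not (0.0 <= self.missingness_base_rate < 1.0):
            raise ValueError("missingness_base_rate must lie in [0, 1)")
        for band in self.severity_gradient:
            if band not in MMSE_BANDS:
                raise ValueError(f"unknown MMSE band in severity_gradient: {band!r}")
        if variable_names is not None:
            known = set(variable_names)
            extra = (set(self.affected_variables) | set(self.shared_env_variables)) - known
            if extra:
                raise ValueError(f"truth references variables not generated: {sorted(extra)}")


#: biologically-styled names for the first planted variables, mirroring the
#: kind of B-cell maturation / T-cell memory gates a clinical panel reports
_NAMED_VARIABLES = [
    "B/naive/transitional_immature",
    "B/transitional",
    "T/CD8/TEM/Tbet_pos",
    "B/naive/IgMlow_IgDpos",
]


def variable_names(n_vars: int) -> list[str]:
    names = list(_NAMED_VARIABLES[:n_vars])
    names += [f"panel/pop{i:04d}" for i in range(len(names), n_vars)]
    return names


def default_truth(n_vars: int = 200, seed: int = 0, shared_env_rho: float = 0.3,
                  n_shared_env: int = 30, missingness_base_rate: float = 0.05) -> SyntheticTruth:
    """Study-condition defaults: four disease-affected variables (three of
    them depressed B-cell maturation gates plus one T-cell gate), a moderate
    cohabitation signal on 30 unaffected variables, and weak age slopes on
    ~10% of variables."""
    names = variable_names(n_vars)
    affected = names[:4]
    effects = dict(zip(affected, [-0.8, -0.7, -0.6, -0.5]))
    rng = np.random.default_rng(seed + 977)
    pool = [n for n in names[4:]]
    shared = list(rng.choice(pool, size=min(n_shared_env, len(pool)), replace=False))
    age_vars = rng.choice(pool, size=max(1, n_vars // 10), replace=False)
    age_slopes = {v: float(s) for v, s in zip(age_vars, rng.normal(0.0, 0.15, len(age_vars)))}
    return SyntheticTruth(
        affected_variables=affected,
        effect_sizes=effects,
        shared_env_variables=shared,
        shared_env_rho=shared_env_rho,
        age_slopes=age_slopes,
        missingness_base_rate=missingness_base_rate,
        seed=seed,
    )


def missingness_probabilities(log_baselines: np.ndarray, base_rate: float) -> np.ndarray:
    """Per-variable missingness probability, non-increasing in baseline frequency.

    Probability is proportional to ``1 - F(mu_j)`` (the empirical survival
    percentile of the log-baseline), rescaled to average ``base_rate`` and
    capped at 0.9, so rare populations miss most often.
    """
    order = np.argsort(np.argsort(log_baselines, kind="stable"), kind="stable")
    n = len(log_baselines)
    surv = 1.0 - (order + 0.5) / n  # 1 for smallest baseline, ~0 for largest
    p = 2.0 * base_rate * surv
    return np.minimum(p, 0.9)


def generate_cohort(
    n_ad: int,
    n_hc: int,
    n_vars: int,
    truth: SyntheticTruth,
    n_pairs: int | None = None,
    age_range: tuple[float, float] = (45.0, 83.0),
    sex_effect_sd: float = 0.1,
) -> tuple[CohortTable, list[SubjectRecord], SyntheticTruth]:
    """Generate a cohort with the planted structure described in ``truth``.

    ``n_pairs`` healthy controls (default ``min(n_ad, n_hc)``) are assigned
    as opposite-sex spouses of AD subjects with closely matched ages.
    Returns the frequency table (with missingness applied), subject
    metadata, and the truth object passed in (validated).
    """
    names = variable_names(n_vars)
    truth.validate(names)
    if n_pairs is None:
        n_pairs = min(n_ad, n_hc)
    if n_pairs > min(n_ad, n_hc):
        raise ValueError("n_pairs exceeds the smaller group")

    rng = np.random.default_rng(truth.seed)
    lo, hi = age_range

    ad_ids = [f"AD{i:04d}" for i in range(n_ad)]
    hc_ids = [f"HC{i:04d}" for i in range(n_hc)]
    subject_ids = ad_ids + hc_ids
    n = n_ad + n_hc
    group = np.array(["AD"] * n_ad + ["HC"] * n_hc)

    # ages: same law for both groups (clipped normal around the clinic mean);
    # spouse ages track their partner's with small jitter.
    ages = np.clip(rng.normal(69.0, 9.0, n), lo, hi)
    for k in range(n_pairs):
        ages[n_ad + k] = np.clip(ages[k] + rng.normal(0.0, 3.0), lo, hi)

    # sexes: spouses are opposite-sex pairs; the rest are balanced coin flips
    sex = np.where(rng.random(n) < 0.5, "M", "F")
    for k in range(n_pairs):
        sex[n_ad + k] = "F" if sex[k] == "M" else "M"

    # MMSE bands for patients, APOE / serostatus for everyone
    band_idx = rng.choice(len(MMSE_BANDS), size=n_ad, p=_MMSE_BAND_PROBS)
    mmse = [MMSE_BANDS[i] for i in band_idx]
    apoe = np.where(group == "AD", rng.random(n) < 102 / 184, rng.random(n) < 22 / 105)
    ebv = rng.random(n) < 0.90
    cmv = rng.random(n) < 0.60

    # per-variable generative parameters
    mu = rng.uniform(np.log(0.05), np.log(20.0), n_vars)  # log baseline frequency
    scale = rng.uniform(0.3, 0.6, n_vars)  # latent -> log-frequency slope
    sex_coef = np.zeros(n_vars)
    sex_mask = rng.random(n_vars) < 0.2
    sex_coef[sex_mask] = rng.normal(0.0, sex_effect_sd, int(sex_mask.sum()))

    z_age = (ages - ages.mean()) / ages.std(ddof=0)
    male = (sex == "M").astype(float)

    sev_mult = np.ones(n)
    for i in range(n_ad):
        sev_mult[i] = truth.severity_gradient.get(mmse[i], 1.0)

    name_index = {v: j for j, v in enumerate(names)}
    age_slope = np.zeros(n_vars)
    for v, b in truth.age_slopes.items():
        age_slope[name_index[v]] = b
    effect = np.zeros(n_vars)
    for v, d in truth.effect_sizes.items():
        effect[name_index[v]] = d
    shared_mask = np.zeros(n_vars, dtype=bool)
    for v in truth.shared_env_variables:
        shared_mask[name_index[v]] = True

    # noise: unit variance; shared-env variables split it between a
    # pair-level component (variance share rho) and an individual residual
    rho = truth.shared_env_rho
    eps = rng.normal(0.0, 1.0, (n, n_vars))
    pair_index = np.arange(n)  # each unpaired subject is its own "pair"
    pair_index[n_ad : n_ad + n_pairs] = np.arange(n_pairs)
    u_raw = rng.normal(0.0, 1.0, (n, n_vars))
    u = u_raw[pair_index]
    noise = eps.copy()
    if rho > 0 and shared_mask.any():
        noise[:, shared_mask] = (
            np.sqrt(rho) * u[:, shared_mask] + np.sqrt(1.0 - rho) * eps[:, shared_mask]
        )

    is_ad = (group == "AD").astype(float)
    latent = (
        np.outer(z_age, age_slope)
        + np.outer(male, sex_coef)
        + np.outer(is_ad * sev_mult, effect)
        + noise
    )
    freq = np.minimum(np.exp(mu[None, :] + scale[None, :] * latent), 100.0)

    # MAR missingness, preferentially in low-baseline variables
    p_miss = missingness_probabilities(mu, truth.missingness_base_rate)
    miss = rng.random((n, n_vars)) < p_miss[None, :]
    freq = freq.astype(float)
    freq[miss] = np.nan

    data = pd.DataFrame(freq, index=subject_ids, columns=names)
    table = CohortTable(data, provenance=f"synthetic cohort seed={truth.seed}")

    records = []
    for i, sid in enumerate(subject_ids):
        spouse = None
        if i < n_pairs:
            spouse = hc_ids[i]
        elif n_ad <= i < n_ad + n_pairs:
            spouse = ad_ids[i - n_ad]
        records.append(
            SubjectRecord(
                subject_id=sid,
                group=str(group[i]),
                age=float(round(ages[i], 1)),
                sex=str(sex[i]),
                spouse_id=spouse,
                mmse_band=mmse[i] if i < n_ad else None,
                apoe_e4=bool(apoe[i]),
                ebv_pos=bool(ebv[i]),
                cmv_pos=bool(cmv[i]),
                biomarkers=(
                    {
                        "Abeta42_ttau": float(np.round(rng.normal(0.6, 0.2), 4)),
                        "Abeta42_ptau181": float(np.round(rng.normal(6.0, 2.0), 4)),
                        "ptau217": float(np.round(np.exp(rng.normal(0.0, 0.5)), 4)),
                    }
                    if group[i] == "AD"
                    else {}
                ),
            )
        )
    validate_metadata(records)
    return table, records, truth


def export_truth(truth: SyntheticTruth, path: str | Path) -> None:
    """Serialize planted parameters to JSON (read-back equality via load_truth)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(asdict(truth), fh, indent=2)


def load_truth(path: str | Path) -> SyntheticTruth:
    with open(path) as fh:
        d = json.load(fh)
    truth = SyntheticTruth(**d)
    truth.validate()
    return truth
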