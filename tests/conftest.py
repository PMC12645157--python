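"""Shared fixtures: small synthetic cohorts and transform helpers."""

import logging

import numpy as np
import pandas as pd
import pytest

from immunocohort import SyntheticTruth, generate_cohort, metadata_frame

logging.getLogger("immunocohort").setLevel(logging.ERROR)


def log_z(df: pd.DataFrame) -> pd.DataFrame:
    """Log + z-score transform (the analytic inverse of the generator's
    exponential link); NaN-aware. Used where the full Box-Cox chain would
    only add noise to a recovery test."""
    out = np.log(df)
    return (out - out.mean()) / out.std(ddof=1)


def flat_truth(n_vars, seed, **kwargs):
    """Truth with a flat severity gradient (multiplier 1 in every band) so a
    planted effect equals the marginal AD-HC standardized difference."""
    kwargs.setdefault("severity_gradient", {b: 1.0 for b in ("25-30", "20-24", "10-19", "<10")})
    kwargs.setdefault("missingness_base_rate", 0.0)
    return SyntheticTruth(seed=seed, **kwargs)


@pytest.fixture(scope="session")
def small_cohort():
    """60 AD / 40 HC cohort with 4 planted effects among 40 variables."""
    affected = ["B/naive/transitional_immature", "B/transitional",
                "T/CD8/TEM/Tbet_pos", "B/naive/IgMlow_IgDpos"]
    truth = flat_truth(
        40, seed=42,
        affected_variables=affected,
        effect_sizes={v: d for v, d in zip(affected, [-0.9, -0.8, -0.7, -0.6])},
        missingness_base_rate=0.05,
    )
    table, records, truth = generate_cohort(60, 40, 40, truth)
    return table, records, truth


@pytest.fixture(scope="session")
def small_meta(small_cohort):
    table, records, _ = small_cohort
    meta = metadata_frame(records).loc[table.subject_ids]
    disease = (meta["group"] == "AD").astype(int).to_numpy()
    return meta, disease
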