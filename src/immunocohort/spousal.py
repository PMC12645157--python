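"""Spousal shared-environment analysis via constraint-preserving re-pairings.

Cohabiting spouses share environmental exposures, so their immune profiles
are closer than those of random strangers. To test whether
disease-associated immune parameters carry such an environmental
signature, the actual spousal pairs are compared with many simulated
pairings of the same subjects that preserve the multiset of pair sex
compositions and the age structure (target-gap matching: simulated pairs
realize a random permutation of the actual within-pair age gaps). If the
actual within-pair Euclidean distance is smaller than in the simulated
pairings, the tested variables carry a shared-environment component; a
disease-intrinsic signal shows no such difference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CohortTable, SubjectRecord

logger = logging.getLogger(__name__)


@dataclass
class PairingSet:
    """Actual or simulated set of subject pairings with provenance."""

    pairs: list[tuple[str, str]]
    kind: str  # "actual" or "simulated"
    constraints: dict = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for a, b in self.pairs:
            if a == b:
                raise ValueError(f"degenerate pair ({a}, {b})")
            for s in (a, b):
                if s in seen:
                    raise ValueError(f"subject {s} appears in more than one pair")
                seen.add(s)

    @property
    def subjects(self) -> list[str]:
        return [s for p in self.pairs for s in p]


def actual_pairings(records: list[SubjectRecord]) -> PairingSet:
    """Extract the actual spousal pairs from metadata, AD partner first."""
    by_id = {r.subject_id: r for r in records}
    pairs = []
    done = set()
    for r in records:
        if r.spouse_id is None or r.subject_id in done:
            continue
        partner = by_id[r.spouse_id]
        first, second = (r, partner) if r.group == "AD" else (partner, r)
        pairs.append((first.subject_id, second.subject_id))
        done.update((r.subject_id, r.spouse_id))
    return PairingSet(pairs, kind="actual")


def pair_distances(table: CohortTable, pairing: PairingSet,
                   subset: list[str] | None = None) -> pd.Series:
    """Per-pair Euclidean distance over the selected variables.

    The table must be complete and contain every paired subject.
    """
    df = table.data[subset] if subset is not None else table.data
    if df.isna().to_numpy().any():
        raise ValueError("table must be complete (imputed) for pair distances")
    missing = [s for s in pairing.subjects if s not in df.index]
    if missing:
        raise KeyError(f"paired subjects absent from table: {missing}")
    first = [a for a, _ in pairing.pairs]
    second = [b for _, b in pairing.pairs]
    diff = df.loc[first].to_numpy() - df.loc[second].to_numpy()
    dist = np.sqrt(np.sum(diff**2, axis=1))
    return pd.Series(dist, index=[f"{a}|{b}" for a, b in pairing.pairs], name="distance")


def _sex_composition(rec_a: SubjectRecord, rec_b: SubjectRecord) -> tuple[str, str]:
    return tuple(sorted((rec_a.sex, rec_b.sex)))


def _pick_for_gap(subject: str, candidates: list[str], target_gap: float,
                  by_id, avoid: set, rng, coarseness: float = 1.0) -> str:
    """Uniform draw among the candidates whose age difference to the subject
    realizes the target gap to within ``coarseness`` years of the best
    achievable match. Treating all near-optimal candidates as
    interchangeable keeps the simulated sets well dispersed (a
    near-deterministic matcher would make the permutation null too narrow).
    The subject's actual partner is avoided unless it is the only candidate
    left."""
    pool = [c for c in candidates if frozenset((subject, c)) not in avoid] or candidates
    age = by_id[subject].age
    scores = np.array([abs(abs(by_id[c].age - age) - target_gap) for c in pool])
    near = np.flatnonzero(scores <= scores.min() + coarseness)
    return pool[int(near[rng.integers(len(near))])]


def _match_with_target_gaps(side_a: list[str], side_b: list[str], by_id,
                            target_gaps: np.ndarray, avoid: set, rng,
                            coarseness: float) -> list[tuple[str, str]]:
    """Re-pair two sides so the multiset of within-pair age gaps tracks the
    supplied targets (a permutation of the actual gaps)."""
    pairs = []
    available = sorted(side_b)
    ordered_a = sorted(side_a)
    targets = rng.permutation(target_gaps)
    for idx, i in enumerate(rng.permutation(len(ordered_a))):
        a = ordered_a[i]
        b = _pick_for_gap(a, available, float(targets[idx]), by_id, avoid, rng,
                          coarseness)
        available.remove(b)
        pairs.append((a, b))
    return pairs


def simulate_pairings(
    records: list[SubjectRecord],
    actual: PairingSet,
    n_sets: int,
    age_tolerance: float | None = None,
    seed: int = 0,
    age_bin_width: float = 10.0,
    max_retries: int = 20,
) -> list[PairingSet]:
    """Random re-pairings of the actually-paired subjects preserving structure.

    Constraints: (a) the multiset of pair sex compositions equals the actual
    one; (b) target within-pair age gaps are a random permutation of the
    actual gaps (per sex-composition class) and each pair is matched to the
    candidate best realizing its target, so the age-gap distribution is
    preserved by construction; (c) if ``age_tolerance`` is given, every
    simulated gap must not exceed the largest actual gap by more than the
    tolerance, with retries, else an error suggests the minimal feasible
    tolerance. ``age_bin_width`` sets the matching coarseness: candidates
    whose achieved gap is within bin_width/10 years of the best match are
    treated as interchangeable, so wider bins randomize more at the cost of
    gap fidelity. Simulated sets avoid reproducing an actual pair where
    possible (logged when unavoidable). Deterministic given ``seed``.
    """
    by_id = {r.subject_id: r for r in records}
    for s in actual.subjects:
        if s not in by_id:
            raise KeyError(f"paired subject {s} missing from metadata")
    comps: dict[tuple[str, str], list[str]] = {}
    comp_gaps: dict[tuple[str, str], list[float]] = {}
    for a, b in actual.pairs:
        comp = _sex_composition(by_id[a], by_id[b])
        comps.setdefault(comp, []).extend([a, b])
        comp_gaps.setdefault(comp, []).append(abs(by_id[a].age - by_id[b].age))
    actual_set = {frozenset(p) for p in actual.pairs}
    actual_gaps = [abs(by_id[a].age - by_id[b].age) for a, b in actual.pairs]
    max_actual_gap = max(actual_gaps) if actual_gaps else 0.0

    rng = np.random.default_rng(seed)
    sets: list[PairingSet] = []
    for s_idx in range(n_sets):
        best_pairs = None  # first attempt satisfying the tolerance
        clean_pairs = None  # ... that also avoids every actual pair
        min_overshoot = np.inf
        for _attempt in range(max_retries):
            pairs: list[tuple[str, str]] = []
            for comp, members in comps.items():
                sex_a, sex_b = comp
                gaps = np.array(comp_gaps[comp])
                if sex_a != sex_b:
                    side_a = [m for m in members if by_id[m].sex == sex_a]
                    side_b = [m for m in members if by_id[m].sex == sex_b]
                    pairs.extend(_match_with_target_gaps(
                        side_a, side_b, by_id, gaps, actual_set, rng,
                        age_bin_width / 10.0))
                else:
                    pool = sorted(members)
                    targets = rng.permutation(gaps)
                    available = list(pool)
                    t_idx = 0
                    while available:
                        i = rng.integers(len(available))
                        a = available.pop(i)
                        b = _pick_for_gap(a, available, float(targets[t_idx]),
                                          by_id, actual_set, rng,
                                          age_bin_width / 10.0)
                        available.remove(b)
                        pairs.append((a, b))
                        t_idx += 1
            gaps = np.array([abs(by_id[a].age - by_id[b].age) for a, b in pairs])
            overshoot = float(max(gaps.max(initial=0.0) - max_actual_gap, 0.0))
            min_overshoot = min(min_overshoot, overshoot)
            if age_tolerance is not None and overshoot > age_tolerance:
                continue
            if best_pairs is None:
                best_pairs = pairs
            if not any(frozenset(p) in actual_set for p in pairs):
                clean_pairs = pairs
                break
        if clean_pairs is not None:
            best_pairs = clean_pairs
        if best_pairs is None:
            raise ValueError(
                "age constraint infeasible under the bin structure; "
                f"minimal feasible tolerance observed >= {min_overshoot:.1f} years"
            )
        n_repro = sum(frozenset(p) in actual_set for p in best_pairs)
        if n_repro:
            logger.info("simulated set %d reproduces %d actual pair(s) (unavoidable)", s_idx, n_repro)
        sets.append(
            PairingSet(
                best_pairs,
                kind="simulated",
                constraints={
                    "age_bin_width": age_bin_width,
                    "age_tolerance": age_tolerance,
                    "reproduced_actual_pairs": n_repro,
                },
                seed=seed,
            )
        )
    return sets


def compare_distance_distributions(
    actual_distances: np.ndarray,
    simulated_distance_sets: list[np.ndarray],
) -> dict:
    """Compare actual vs simulated within-pair distances.

    Returns the two-sided Mann-Whitney U of actual vs pooled simulated
    distances, and a permutation p based on the fraction of simulated sets
    whose median distance is <= the actual median (small p means actual
    spouses are closer than chance re-pairings). The fraction carries the
    add-one finite-sample correction (the actual pairing stands in for the
    identity permutation, which the simulator deliberately excludes), so
    the p is valid at any number of simulated sets.
    """
    actual = np.asarray(actual_distances, dtype=float)
    if actual.size == 0 or not simulated_distance_sets:
        raise ValueError("need non-empty actual and simulated distance sets")
    pooled = np.concatenate([np.asarray(d, dtype=float) for d in simulated_distance_sets])
    u_res = stats.mannwhitneyu(actual, pooled, alternative="two-sided")
    med_actual = float(np.median(actual))
    sim_medians = np.array([np.median(d) for d in simulated_distance_sets])
    n_sets = len(simulated_distance_sets)
    p_perm = float((np.sum(sim_medians <= med_actual) + 1) / (n_sets + 1))
    return {
        "U": float(u_res.statistic),
        "p_mannwhitney": float(u_res.pvalue),
        "median_actual": med_actual,
        "median_simulated": float(np.median(sim_medians)),
        "p_permutation": p_perm,
        "n_sets": len(simulated_distance_sets),
    }


def _pair_correlation_p(df: pd.DataFrame, pairs: list[tuple[str, str]], variable: str,
                        order_flips: np.ndarray) -> float:
    a_vals, b_vals = [], []
    for (a, b), flip in zip(pairs, order_flips):
        if flip:
            a, b = b, a
        a_vals.append(df.at[a, variable])
        b_vals.append(df.at[b, variable])
    res = stats.spearmanr(a_vals, b_vals)
    p = float(res.pvalue)
    return p if np.isfinite(p) else 1.0


def concordance_pvalue_scatter(
    table: CohortTable,
    actual: PairingSet,
    simulated_sets: list[PairingSet],
    variables: list[str] | None = None,
    seed: int = 0,
    flagged: list[str] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Per-variable concordance p for actual vs simulated pairings.

    For each variable, ``p_actual`` is the Spearman rank-correlation p
    between partner values across the actual pairs (partner order
    randomized once per pair, seeded); ``p_simulated`` is the geometric
    mean of the same statistic over the simulated sets (the back-transform
    of the mean Fisher -2 ln p). Returns the per-variable table plus the
    least-squares regression of -log10 p_actual on -log10 p_simulated
    (identity = no shared-environment effect).
    """
    if len(actual.pairs) < 3:
        raise ValueError("need >= 3 pairs")
    df = table.data
    variables = variables or list(df.columns)
    missing = [v for v in variables if v not in df.columns]
    if missing:
        raise KeyError(f"variables absent from table: {missing}")
    rng = np.random.default_rng(seed)
    flips_actual = rng.random(len(actual.pairs)) < 0.5
    flips_sim = [rng.random(len(s.pairs)) < 0.5 for s in simulated_sets]
    flagged = set(flagged or [])
    rows = []
    for v in variables:
        col = df[v]
        if col.loc[list(actual.subjects)].nunique() <= 1:
            logger.warning("excluding constant variable %s from concordance scatter", v)
            continue
        p_act = _pair_correlation_p(df, actual.pairs, v, flips_actual)
        p_sims = [
            _pair_correlation_p(df, s.pairs, v, fl)
            for s, fl in zip(simulated_sets, flips_sim)
        ]
        p_sim = float(np.exp(np.mean(np.log(np.clip(p_sims, 1e-300, 1.0)))))
        rows.append({"variable": v, "p_actual": p_act, "p_simulated": p_sim,
                     "flagged": v in flagged})
    out = pd.DataFrame(rows)
    x = -np.log10(np.clip(out["p_simulated"].to_numpy(), 1e-300, 1.0))
    y = -np.log10(np.clip(out["p_actual"].to_numpy(), 1e-300, 1.0))
    slope, intercept = np.polyfit(x, y, 1) if len(out) >= 2 else (np.nan, np.nan)
    regression = {"slope": float(slope), "intercept": float(intercept)}
    return out, regression
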