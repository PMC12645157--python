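"""Spousal concordance: distances, constraint-preserving re-pairings, permutation tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from immunocohort import (
    CohortTable,
    PairingSet,
    actual_pairings,
    compare_distance_distributions,
    concordance_pvalue_scatter,
    generate_cohort,
    pair_distances,
    simulate_pairings,
)

from conftest import flat_truth, log_z


def _cohort(seed, n_pairs=40, n_vars=20, rho=0.0, n_shared=10, effects=None):
    shared = [f"panel/pop{i:04d}" for i in range(4, 4 + n_shared)] if rho > 0 else []
    truth = flat_truth(
        n_vars, seed=seed,
        shared_env_variables=shared, shared_env_rho=rho,
        affected_variables=list(effects) if effects else [],
        effect_sizes=dict(effects) if effects else {},
    )
    table, records, _ = generate_cohort(n_pairs, n_pairs, n_vars, truth)
    z = CohortTable(log_z(table.data), scale="transformed")
    return z, records, shared


class TestPairDistances:
    def _table(self, rows, ids):
        df = pd.DataFrame(rows, index=ids, columns=["v1", "v2"])
        return CohortTable(df, scale="transformed")

    def test_identical_profiles_zero(self):
        t = self._table([[1.0, 2.0], [1.0, 2.0]], ["A", "B"])
        d = pair_distances(t, PairingSet([("A", "B")], "actual"))
        assert d.iloc[0] == 0.0

    def test_three_four_five(self):
        t = self._table([[1.0, 2.0], [4.0, 6.0]], ["A", "B"])
        d = pair_distances(t, PairingSet([("A", "B")], "actual"))
        assert d.iloc[0] == pytest.approx(5.0)

    def test_subset_distance_never_exceeds_superset(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(size=(4, 6)),
                          index=list("ABCD"), columns=[f"v{i}" for i in range(6)])
        t = CohortTable(df, scale="transformed")
        pairing = PairingSet([("A", "B"), ("C", "D")], "actual")
        d_all = pair_distances(t, pairing)
        d_sub = pair_distances(t, pairing, subset=["v0", "v1"])
        assert (d_sub <= d_all + 1e-12).all()

    def test_missing_subject_rejected(self):
        t = self._table([[1.0, 2.0]], ["A"])
        with pytest.raises(KeyError, match="Z"):
            pair_distances(t, PairingSet([("A", "Z")], "actual"))


class TestPairingSet:
    def test_subject_reuse_rejected(self):
        with pytest.raises(ValueError, match="more than one pair"):
            PairingSet([("A", "B"), ("A", "C")], "simulated")

    def test_actual_pairs_extracted_ad_first(self, small_cohort):
        _, records, _ = small_cohort
        pairing = actual_pairings(records)
        assert len(pairing.pairs) == 40
        assert all(a.startswith("AD") and b.startswith("HC") for a, b in pairing.pairs)


class TestSimulatePairings:
    def test_sex_composition_preserved_and_deterministic(self):
        z, records, _ = _cohort(seed=11)
        actual = actual_pairings(records)
        sims1 = simulate_pairings(records, actual, 10, seed=3)
        sims2 = simulate_pairings(records, actual, 10, seed=3)
        by_id = {r.subject_id: r for r in records}
        # every actual pair is opposite-sex, so every simulated pair must be
        for s in sims1:
            assert all(by_id[a].sex != by_id[b].sex for a, b in s.pairs)
            assert len(s.pairs) == len(actual.pairs)
        assert [s.pairs for s in sims1] == [s.pairs for s in sims2]
        # sets differ from each other and rarely reproduce actual pairs
        assert sims1[0].pairs != sims1[1].pairs

    def test_age_gap_distribution_matches_actual(self):
        """Under the null generator the simulated within-pair age gaps are
        statistically indistinguishable from the actual gaps."""
        ok = 0
        n_seeds = 10
        for seed in range(n_seeds):
            z, records, _ = _cohort(seed=100 + seed, n_pairs=50)
            by_id = {r.subject_id: r for r in records}
            actual = actual_pairings(records)
            gaps_actual = [abs(by_id[a].age - by_id[b].age) for a, b in actual.pairs]
            sims = simulate_pairings(records, actual, 5, seed=seed)
            gaps_sim = [abs(by_id[a].age - by_id[b].age)
                        for s in sims for a, b in s.pairs]
            p = stats.mannwhitneyu(gaps_actual, gaps_sim).pvalue
            ok += p > 0.05
        assert ok >= 0.8 * n_seeds

    def test_infeasible_tolerance_reports_minimum(self):
        z, records, _ = _cohort(seed=12, n_pairs=30)
        actual = actual_pairings(records)
        with pytest.raises(ValueError, match="tolerance"):
            simulate_pairings(records, actual, 3, age_tolerance=-5.0, seed=0)


class TestDistanceComparison:
    def test_no_signal_when_actual_equals_simulated(self):
        d = np.array([1.0, 2.0, 3.0, 4.0])
        res = compare_distance_distributions(d, [d.copy() for _ in range(20)])
        assert res["p_permutation"] == 1.0
        assert res["p_mannwhitney"] > 0.9

    def test_power_under_shared_environment(self):
        """rho=0.6 on a third of the panel, 150 pairs: the permutation test
        detects spousal concordance in at least 90% of seeds."""
        rejections = 0
        n_seeds = 20
        for seed in range(n_seeds):
            z, records, _ = _cohort(seed=200 + seed, n_pairs=150, n_vars=30,
                                    rho=0.6, n_shared=10)
            actual = actual_pairings(records)
            sims = simulate_pairings(records, actual, 99, seed=seed)
            d_act = pair_distances(z, actual).to_numpy()
            d_sims = [pair_distances(z, s).to_numpy() for s in sims]
            res = compare_distance_distributions(d_act, d_sims)
            rejections += res["p_permutation"] < 0.05
        assert rejections >= 0.9 * n_seeds

    def test_disease_only_variables_carry_no_concordance(self):
        """Restricting to planted disease-effect variables with zero
        shared-environment loading abolishes the concordance signal."""
        affected = {"B/naive/transitional_immature": -0.9, "B/transitional": -0.8}
        rejections = 0
        n_seeds = 20
        for seed in range(n_seeds):
            z, records, shared = _cohort(seed=300 + seed, n_pairs=60, n_vars=30,
                                         rho=0.6, n_shared=10, effects=affected)
            actual = actual_pairings(records)
            sims = simulate_pairings(records, actual, 99, seed=seed)
            sub = list(affected)
            d_act = pair_distances(z, actual, subset=sub).to_numpy()
            d_sims = [pair_distances(z, s, subset=sub).to_numpy() for s in sims]
            res = compare_distance_distributions(d_act, d_sims)
            rejections += res["p_permutation"] < 0.05
        assert rejections <= 0.10 * n_seeds + 1e-9


class TestConcordanceScatter:
    def test_planted_variables_above_identity_line(self):
        z, records, shared = _cohort(seed=21, n_pairs=150, n_vars=30,
                                     rho=0.6, n_shared=10)
        actual = actual_pairings(records)
        sims = simulate_pairings(records, actual, 20, seed=5)
        scatter, reg = concordance_pvalue_scatter(z, actual, sims, seed=5)
        sub = scatter[scatter["variable"].isin(shared)]
        above = (sub["p_actual"] < sub["p_simulated"]).mean()
        assert above >= 0.8

    def test_null_regression_near_identity(self):
        """Without shared environment, concordance driven by the preserved
        age/sex structure appears equally in actual and simulated pairings:
        the p-vs-p regression tracks the identity line."""
        slopes = []
        for seed in range(20):
            rng = np.random.default_rng(800 + seed)
            names = [f"panel/pop{i:04d}" for i in range(4, 29)]
            truth = flat_truth(
                30, seed=400 + seed,
                age_slopes={v: s for v, s in
                            zip(names, rng.uniform(0.2, 0.9, len(names)))},
            )
            table, records, _ = generate_cohort(100, 100, 30, truth)
            z = CohortTable(log_z(table.data), scale="transformed")
            actual = actual_pairings(records)
            sims = simulate_pairings(records, actual, 20, seed=seed)
            _, reg = concordance_pvalue_scatter(z, actual, sims, seed=seed)
            slopes.append(reg["slope"])
        assert 0.8 <= np.mean(slopes) <= 1.2

    def test_constant_variable_excluded(self):
        rng = np.random.default_rng(6)
        df = pd.DataFrame(rng.normal(size=(8, 2)), index=[f"S{i}" for i in range(8)],
                          columns=["ok", "flat"])
        df["flat"] = 1.0
        t = CohortTable(df, scale="transformed")
        pairing = PairingSet([("S0", "S1"), ("S2", "S3"), ("S4", "S5"), ("S6", "S7")],
                             "actual")
        sims = [PairingSet([("S0", "S3"), ("S2", "S1"), ("S4", "S7"), ("S6", "S5")],
                           "simulated")]
        scatter, _ = concordance_pvalue_scatter(t, pairing, sims, seed=0)
        assert scatter["variable"].tolist() == ["ok"]

    def test_too_few_pairs_rejected(self):
        t = CohortTable(pd.DataFrame({"v": [0.1, -0.1]}, index=["A", "B"]),
                        scale="transformed")
        with pytest.raises(ValueError, match="3 pairs"):
            concordance_pvalue_scatter(t, PairingSet([("A", "B")], "actual"), [], seed=0)
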