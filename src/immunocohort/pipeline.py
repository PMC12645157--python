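"""End-to-end pipeline: preprocess -> association -> model building -> forest
-> similarity -> spousal -> clinical, with per-stage TSV outputs and a JSON
run summary.

Every output carries the config hash and master seed; reruns with the same
inputs, config and seed are byte-identical. The master seed expands into
fixed per-stage seeds (see :meth:`RunConfig.stage_seed`) so any stage can
be reproduced in isolation.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import association as assoc
from . import clinical, forest, model_selection, preprocess, similarity, spousal
from .cohort import CohortTable, RunConfig, SubjectRecord, metadata_frame, read_cohort, write_frequency_table

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")


def run_pipeline(
    config: RunConfig,
    freq_path: str | Path,
    meta_path: str | Path,
    out_dir: str | Path,
) -> dict:
    """Execute every stage on the given cohort and write results to ``out_dir``.

    Returns the run summary (also written to ``summary.json``).
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "master_seed": config.master_seed,
        "stage_seeds": {s: config.stage_seed(s) for s in config._STAGE_OFFSETS},
        "stages": {},
    }

    state: dict = {}

    def stage(name):
        def deco(fn):
            try:
                result = fn()
            except StageError:
                raise
            except Exception as exc:  # noqa: BLE001 - stage name must surface
                raise StageError(name, exc) from exc
            summary["stages"][name] = result
            return result
        return deco

    # ---- input ----------------------------------------------------------
    @stage("input")
    def _input():
        tbl, recs = read_cohort(freq_path, meta_path)
        state["table"], state["records"] = tbl, recs
        return {"n_subjects": tbl.n_subjects,
                "n_variables": tbl.n_variables,
                "n_missing_cells": tbl.n_missing}

    table: CohortTable = state["table"]
    records: list[SubjectRecord] = state["records"]
    meta = metadata_frame(records).loc[table.subject_ids]
    disease = (meta["group"] == "AD").astype(int).to_numpy()
    age = meta["age"].to_numpy(dtype=float)
    sex = meta["sex"].to_numpy()

    # ---- preprocess ------------------------------------------------------
    @stage("preprocess")
    def _pre():
        filtered, dropped = preprocess.filter_missingness(table, config.missingness_threshold)
        _write_tsv(dropped, out / "dropped_variables.tsv")
        transformed, spec = preprocess.fit_transform(filtered, config.boxcox_bounds)
        spec.save(out / "transform_spec.json")
        imputed = preprocess.knn_impute(transformed, k=config.knn_k)
        write_frequency_table(imputed, out / "imputed.tsv")
        state["imputed"] = imputed
        return {
            "n_variables_input": table.n_variables,
            "n_variables_post_filter": filtered.n_variables,
            "n_variables_dropped": int(len(dropped)),
            "n_variables_transformed": transformed.n_variables,
            "n_missing_imputed": int(transformed.n_missing),
        }

    imputed: CohortTable = state["imputed"]
    df = imputed.data

    # ---- association -----------------------------------------------------
    @stage("association")
    def _assoc():
        records_ = assoc.associate_all(df, disease, age, sex)
        frame = assoc.records_frame(records_)
        _write_tsv(frame, out / "association_disease.tsv")
        age_rows = []
        for subset in ("HC", "AD"):
            for v in df.columns:
                try:
                    r = assoc.fit_age_association(
                        df[v].to_numpy(), age, sex, meta["group"].to_numpy(),
                        subset=subset, variable=v)
                    age_rows.append(r)
                except ValueError:
                    continue
        _write_tsv(assoc.records_frame(age_rows), out / "association_age.tsv")
        state["ranking"] = assoc.rank_by_pvalue(records_)
        n_sig = sum(1 for r in records_ if r.usable and r.p < 0.05)
        return {"n_variables": len(records_), "n_raw_p_lt_05": n_sig,
                "n_flagged": sum(1 for r in records_ if not r.usable)}

    ranking = state["ranking"]

    # ---- model selection -------------------------------------------------
    @stage("model_selection")
    def _select():
        max_n = min(config.max_features, df.shape[1])
        curve = model_selection.incremental_l2_curve(
            df, disease, age, sex, ranking, max_features=max_n,
            k=config.n_folds, seed=config.stage_seed("model_selection"),
            penalty=config.ridge_penalty)
        _write_tsv(curve.to_frame(), out / "l2_cv_curve.tsv")
        n_star = model_selection.select_optimal_n(curve)
        scores, labs = model_selection.cv_scores_at_n(
            df, disease, age, sex, ranking, n_star, k=config.n_folds,
            seed=config.stage_seed("model_selection"), penalty=config.ridge_penalty)
        roc = model_selection.averaged_roc(scores, labs)
        _write_tsv(roc, out / "averaged_roc.tsv")
        state["n_star"] = n_star
        return {"optimal_n": n_star,
                "auc_at_optimal_n": float(curve.mean_auc[n_star - 1]),
                "max_features": max_n}

    n_star = state["n_star"]
    top_vars = ranking[:n_star]

    # ---- forest ----------------------------------------------------------
    @stage("forest")
    def _forest():
        seed = config.stage_seed("forest")
        depth, per_fold = forest.tune_depth_oob(
            df, disease, config.rf_depth_grid, k=config.n_folds,
            seed=seed, n_trees=config.rf_n_trees)
        _write_tsv(per_fold, out / "rf_depth_oob.tsv")
        imp = forest.gini_ranking(df, disease, depth=depth,
                                  n_trees=config.rf_n_trees, seed=seed)
        _write_tsv(imp.to_frame(), out / "rf_importance.tsv")
        max_n = min(config.max_features, df.shape[1])
        curve = forest.incremental_rf_curve(
            df, disease, imp, max_features=max_n, k=config.n_folds,
            seed=seed, n_trees=config.rf_n_trees)
        _write_tsv(curve.to_frame(), out / "rf_cv_curve.tsv")
        rf_n_star = model_selection.select_optimal_n(curve)
        return {"chosen_depth": None if depth is None else int(depth),
                "per_fold_depths": [None if d is None else int(d)
                                     for d in per_fold.attrs["per_fold_best"]],
                "rf_optimal_n": rf_n_star,
                "rf_auc_at_optimal_n": float(curve.mean_auc[rf_n_star - 1])}

    # ---- similarity ------------------------------------------------------
    @stage("similarity")
    def _sim():
        emb_all = similarity.pca_embed(df, n_components=2)
        emb_top = similarity.pca_embed(df, subset=top_vars, n_components=2) \
            if len(top_vars) >= 2 else None
        _write_tsv(emb_all.scores, out / "pca_scores_all.tsv", index=True)
        _write_tsv(emb_all.loadings, out / "pca_loadings_all.tsv", index=True)
        sep_all = similarity.group_separation(emb_all.scores, meta["group"].to_numpy())
        result = {
            "variance_share_pc1_all": float(emb_all.explained_ratio[0]),
            "separation_all": sep_all["separation"],
        }
        if emb_top is not None:
            _write_tsv(emb_top.scores, out / "pca_scores_top.tsv", index=True)
            sep_top = similarity.group_separation(emb_top.scores, meta["group"].to_numpy())
            result["separation_top"] = sep_top["separation"]
        return result

    # ---- spousal ---------------------------------------------------------
    @stage("spousal")
    def _spousal():
        actual = spousal.actual_pairings(records)
        if len(actual.pairs) < 3:
            return {"skipped": "fewer than 3 spousal pairs"}
        seed = config.stage_seed("spousal")
        sims = spousal.simulate_pairings(
            records, actual, n_sets=config.n_simulated_pairings,
            seed=seed, age_bin_width=config.age_bin_width)
        d_actual = spousal.pair_distances(imputed, actual)
        d_sims = [spousal.pair_distances(imputed, s).to_numpy() for s in sims]
        res_all = spousal.compare_distance_distributions(d_actual.to_numpy(), d_sims)
        _write_tsv(d_actual.rename("distance").reset_index(), out / "spousal_distances_actual.tsv")
        result = {"n_pairs": len(actual.pairs), "all_variables": res_all}
        if len(top_vars) >= 2:
            da = spousal.pair_distances(imputed, actual, subset=top_vars)
            ds = [spousal.pair_distances(imputed, s, subset=top_vars).to_numpy() for s in sims]
            result["ad_associated_variables"] = spousal.compare_distance_distributions(
                da.to_numpy(), ds)
        n_scatter_sets = min(len(sims), 50)  # scatter cost grows with sets x variables
        scatter, regression = spousal.concordance_pvalue_scatter(
            imputed, actual, sims[:n_scatter_sets], seed=seed, flagged=top_vars)
        _write_tsv(scatter, out / "spousal_concordance_scatter.tsv")
        result["concordance_regression"] = regression
        return result

    # ---- clinical --------------------------------------------------------
    @stage("clinical")
    def _clinical():
        result: dict = {}
        focus = top_vars if top_vars else list(df.columns[:4])
        # serology-stratified comparisons (subset declarative)
        ebv = meta["ebv_pos"].fillna(False).astype(bool).to_numpy()
        tests_ebv = clinical.group_tests(df, disease, focus, subset_mask=ebv,
                                         subset_expression="ebv_pos == True")
        _write_tsv(tests_ebv, out / "clinical_ebv_positive.tsv")
        result["ebv_positive_min_p_bh"] = float(tests_ebv["p_bh"].min())
        # CMV x disease four-group comparison for the top variable
        cmv = meta["cmv_pos"].fillna(False).astype(bool).to_numpy()
        v0 = focus[0]
        vals = df[v0].to_numpy()
        groups, labels = [], []
        for dz in (0, 1):
            for cv in (False, True):
                m = (disease == dz) & (cmv == cv)
                if m.sum() > 0:
                    groups.append(vals[m])
                    labels.append(f"{'AD' if dz else 'HC'}_{'CMVpos' if cv else 'CMVneg'}")
        if len(groups) >= 3:
            h, p_global, mat = clinical.kruskal_wallis_pairwise(groups, labels)
            _write_tsv(mat, out / "clinical_cmv_kruskal_pairwise.tsv", index=True)
            result["cmv_kruskal"] = {"variable": v0, "H": h, "p": p_global}
        # disease x serostatus interaction for the focus variables
        inter = []
        for v in focus:
            try:
                coef, p = clinical.interaction_test(df[v].to_numpy(), disease,
                                                    cmv.astype(float), age, sex)
                inter.append({"variable": v, "stratum": "cmv_pos", "coef": coef, "p": p})
            except ValueError:
                continue
        if inter:
            _write_tsv(pd.DataFrame(inter), out / "clinical_interaction.tsv")
            result["n_interaction_p_lt_05"] = int(sum(r["p"] < 0.05 for r in inter))
        # ordered severity trend: HC then MMSE bands (worst last)
        band_order = ["HC", "25-30", "20-24", "10-19", "<10"]
        trend = []
        for v in focus:
            ordered = []
            for b in band_order:
                m = (meta["group"] == "HC").to_numpy() if b == "HC" \
                    else (meta["mmse_band"] == b).to_numpy()
                if m.sum() > 0:
                    ordered.append(df[v].to_numpy()[m])
            if len(ordered) >= 2:
                jt, p = clinical.ordered_trend_test(ordered, alternative="two-sided")
                trend.append({"variable": v, "JT": jt, "p": p})
        if trend:
            tdf = pd.DataFrame(trend)
            tdf["p_bh"] = clinical.benjamini_hochberg(tdf["p"].to_numpy())
            _write_tsv(tdf, out / "clinical_mmse_trend.tsv")
            result["mmse_trend_min_p"] = float(tdf["p"].min())
        # correlation-structure deviation among the focus variables
        pairs = [(a, b) for i, a in enumerate(focus) for b in focus[i + 1:]]
        if pairs:
            hc_mask = disease == 0
            try:
                dev = clinical.correlation_deviation(df.loc[hc_mask], df.loc[~hc_mask], pairs)
                _write_tsv(dev, out / "clinical_correlation_deviation.tsv")
                result["correlation_deviation_min_p_bh"] = float(dev["p_bh"].min())
            except ValueError as exc:
                result["correlation_deviation_skipped"] = str(exc)
        # biomarker correlations within the AD group
        biom_cols = [c for c in ("Abeta42_ttau", "Abeta42_ptau181", "ptau217")
                     if c in meta.columns]
        rows = []
        for b in biom_cols:
            bvals = pd.to_numeric(meta[b], errors="coerce").to_numpy()
            m = (disease == 1) & np.isfinite(bvals)
            if m.sum() >= 4:
                try:
                    rho, p = clinical.spearman_correlation(df[focus[0]].to_numpy()[m], bvals[m])
                    rows.append({"variable": focus[0], "biomarker": b, "rho": rho, "p": p})
                except ValueError:
                    continue
        if rows:
            _write_tsv(pd.DataFrame(rows), out / "clinical_biomarker_correlation.tsv")
        return result

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=str)
    return summary
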