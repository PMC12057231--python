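"""End-to-end pipeline: simulate/load -> normalize -> network -> stage ->
associate -> trajectories -> panels -> demographics, writing TSV tables and a
provenance JSON into a run directory.

Deterministic given the config seed: two runs with identical config produce
byte-identical outputs.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import association, demographics, network, panels, preprocess, staging, trajectory
from .config import RunConfig
from .containers import AbundanceMatrix, CSF_COLUMNS, Scale, TAU_SUVR_COLUMNS
from .io import read_abundance_matrix, read_metadata, write_json, write_table
from .simulate import generate_cohort, generate_validation_cohorts


def run_pipeline(config: RunConfig) -> Path:
    """Run every stage on the configured (or simulated) cohort.

    Returns the run directory.  Any stage failure aborts with the stage name
    and cause.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    # fail fast on bad paths before any computation
    if config.matrix_path is not None and not Path(config.matrix_path).exists():
        raise FileNotFoundError(f"matrix_path does not exist: {config.matrix_path}")
    if config.metadata_path is not None and not Path(config.metadata_path).exists():
        raise FileNotFoundError(f"metadata_path does not exist: {config.metadata_path}")
    if config.matrix_path is None and config.metadata_path is not None:
        raise ValueError("metadata_path given without matrix_path")

    config.to_json(out / "provenance.json")
    state: dict = {}
    stages = [
        ("load", _stage_load),
        ("normalize", _stage_normalize),
        ("network", _stage_network),
        ("stage", _stage_staging),
        ("associate", _stage_associate),
        ("trajectory", _stage_trajectory),
        ("panel", _stage_panel),
        ("demographics", _stage_demographics),
    ]
    for name, fn in stages:
        try:
            fn(config, state, out)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
    return out


def _stage_load(config: RunConfig, state: dict, out: Path) -> None:
    if config.matrix_path is None:
        matrix, meta, truth = generate_cohort(
            n_per_stage=config.n_per_stage,
            module_sizes=config.module_sizes,
            n_background=config.n_background,
            noise_sd=config.noise_sd,
            missing_rate=config.missing_rate,
            tmt_set_size=config.tmt_set_size,
            seed=config.seed,
        )
        fluid, biopsy = generate_validation_cohorts(
            truth, overlap_frac=config.validation_overlap_frac,
            seed=config.seed + 1,
        )
        state["truth"] = truth
        state["fluid"] = fluid
        state["biopsy"] = biopsy
    else:
        matrix = read_abundance_matrix(config.matrix_path, scale=Scale.raw_intensity)
        meta = read_metadata(config.metadata_path, matrix=matrix)
        if "tmt_set" in meta.columns:
            matrix.tmt_set.update(meta["tmt_set"].dropna().to_dict())
    state["raw"] = matrix
    state["meta"] = meta


def _stage_normalize(config: RunConfig, state: dict, out: Path) -> None:
    raw = state["raw"]
    if raw.scale is Scale.raw_intensity:
        norm = preprocess.normalize_tmt(
            raw,
            exclude_reference_from_protein_median=config.exclude_reference_from_medians,
        )
    else:
        norm = raw
    qc = preprocess.qc_outliers(norm, sd_mult=config.qc_sd_mult)
    qc_table = qc.pc_coordinates.copy()
    qc_table["outlier"] = qc.outlier_flags
    write_table(qc_table.reset_index().rename(columns={"index": "sample_id"}),
                out / "qc_samples.tsv")
    norm = norm.drop_reference_channels()
    norm = preprocess.filter_missingness(norm, config.max_missing_frac)
    state["norm"] = norm
    write_table(norm.values.reset_index(), out / "normalized_matrix.tsv")


def _stage_network(config: RunConfig, state: dict, out: Path) -> None:
    model = network.build_network(
        state["norm"],
        power=config.soft_power,
        auto_power=config.auto_power,
        max_p_outliers=config.max_p_outliers,
        min_pairs=config.min_pairs,
        deep_split=config.deep_split,
        min_module_size=config.min_module_size,
        merge_cut_height=config.merge_cut_height,
        pam_stage=config.pam_stage,
        pam_respects_dendro=config.pam_respects_dendro,
        apply_reassignment=config.apply_reassignment,
        reassign_threshold=config.reassign_threshold,
    )
    state["network"] = model
    write_table(model.labels.reset_index().rename(
        columns={"index": "protein_id", 0: "module"}), out / "module_labels.tsv")
    if model.summary is not None:
        write_table(model.summary.eigenprotein.reset_index().rename(
            columns={"index": "sample_id"}), out / "eigenproteins.tsv")
        write_table(model.summary.kme.reset_index().rename(
            columns={"index": "protein_id"}), out / "kme.tsv")
    diag = {"power_beta": model.power_beta}
    if model.diagnostics is not None:
        diag.update({
            "chosen_power": model.diagnostics.chosen_power,
            "scale_free_r2": model.diagnostics.scale_free_r2,
            "mean_connectivity": model.diagnostics.mean_connectivity,
        })
    write_json(diag, out / "network_diagnostics.json")


def _stage_staging(config: RunConfig, state: dict, out: Path) -> None:
    assign = staging.assign_groups(
        state["meta"], stage_basis="pet",
        abeta_suvr_cut=config.abeta_suvr_cut,
        tau_suvr_cut=config.tau_suvr_cut,
        abeta_ratio_cut=config.abeta_ratio_cut,
    )
    assign, pooling = staging.pool_sparse_stages(assign, min_n=config.pool_min_n)
    state["staging"] = assign
    state["pooling"] = pooling
    write_table(assign.reset_index(), out / "stage_assignments.tsv")
    write_json(pooling, out / "stage_pooling.json")


def _stage_associate(config: RunConfig, state: dict, out: Path) -> None:
    model = state["network"]
    meta = state["meta"]
    assign = state["staging"]
    if model.summary is None:
        return
    eig = model.summary.eigenprotein.loc[
        [s for s in model.summary.eigenprotein.index if s in meta.index]
    ]
    bio_cols = [c for c in ("abeta_pet_suvr", *TAU_SUVR_COLUMNS, *CSF_COLUMNS)
                if c in meta.columns]
    cor_table = association.spearman_bonferroni(eig, meta.loc[eig.index, bio_cols])
    write_table(cor_table, out / "module_biomarker_spearman.tsv")

    meta_at = meta.join(assign[["at_group", "braak_stage_pooled"]])
    counts = meta_at["at_group"].value_counts()
    # PET-stratified differential abundance; pick the first contrast with
    # enough samples to satisfy the per-protein observation floor
    for pair in (("A+T+", "A-T-"), ("A+T-", "A-T-"), ("A+T+", "A+T-")):
        n_pair = counts.get(pair[0], 0) + counts.get(pair[1], 0)
        if min(counts.get(pair[0], 0), counts.get(pair[1], 0)) < 3:
            continue
        if n_pair < config.min_obs:
            continue
        norm = state["norm"]
        samples = [s for s in norm.sample_ids
                   if meta_at.loc[s, "at_group"] in pair]
        sub = norm.subset_samples(samples)
        diff = association.fit_moderated_lm(
            sub, meta_at.loc[samples], "at_group", pair,
            min_obs=config.min_obs, adj_method=config.adjust_method,
        )
        tag = f"{pair[0]}_vs_{pair[1]}".replace("+", "pos").replace("-", "neg")
        write_table(diff, out / f"differential_{tag}.tsv")
        volcano = association.volcano_table(diff, model.labels)
        write_table(volcano, out / f"volcano_{tag}.tsv")
        break

    # dual-PET model with global tau SUVR = mean over the six Braak regions
    if all(c in meta.columns for c in TAU_SUVR_COLUMNS) and "abeta_pet_suvr" in meta.columns:
        meta_dual = meta.copy()
        meta_dual["tau_suvr_global"] = meta[list(TAU_SUVR_COLUMNS)].mean(axis=1)
        dual = association.dual_pet_model(
            state["norm"], meta_dual, min_obs=config.min_obs,
        )
        write_table(dual, out / "dual_pet_models.tsv")

    # Tukey contrasts of each Eigenprotein across pooled Braak stages
    stage_col = meta_at["braak_stage_pooled"]
    usable = stage_col.notna() & ~stage_col.isin(["discordant", "unknown"])
    tukey_rows = []
    for mod in eig.columns:
        vals = eig[mod][usable.reindex(eig.index).fillna(False)]
        grp = stage_col.loc[vals.index]
        if grp.nunique() >= 2 and grp.value_counts().min() >= 2:
            tk = association.group_contrast_tukey(
                vals, grp, meta.loc[vals.index, ["age", "sex"]])
            tk.insert(0, "module", mod)
            tukey_rows.append(tk)
    if tukey_rows:
        write_table(pd.concat(tukey_rows, ignore_index=True),
                    out / "eigenprotein_tukey.tsv")

    # cross-cohort Eigenprotein projection (simulated validation cohorts)
    proj_rows = []
    for cohort_name in ("fluid", "biopsy"):
        if cohort_name not in state:
            continue
        vmatrix, vmeta, _ = state[cohort_name]
        ctrl = vmeta["is_control"].astype(bool)
        for mod in model.summary.kme.columns:
            try:
                proj = association.project_eigenprotein(
                    vmatrix, model.summary.kme, mod, ctrl, kme_cut=config.kme_cut)
            except ValueError:
                continue
            for sid, z in proj.z_to_controls.items():
                proj_rows.append({"cohort": cohort_name, "module": mod,
                                  "sample_id": sid, "z_to_controls": z,
                                  "coverage_frac": proj.coverage_frac})
    if proj_rows:
        write_table(pd.DataFrame(proj_rows), out / "projected_eigenproteins.tsv")


def _stage_trajectory(config: RunConfig, state: dict, out: Path) -> None:
    model = state["network"]
    if model.summary is None:
        return
    assign = state["staging"]
    eig = model.summary.eigenprotein
    stage_col = assign["braak_stage_pooled"].reindex(eig.index)
    usable = stage_col.notna() & ~stage_col.isin(["unknown"])
    if config.exclude_discordant:
        usable &= stage_col != "discordant"
    levels = [lvl for lvl in stage_col[usable].unique()]
    pos = staging.stage_positions(levels)
    positions = stage_col.map(pos)
    ctrl = assign["braak_stage"].reindex(eig.index) == "0"
    grid = pd.DataFrame(
        sorted(((lvl, p) for lvl, p in pos.items()), key=lambda t: t[1]),
        columns=["stage", "position"],
    )
    fits = []
    for mod in eig.columns:
        z = trajectory.zscore_to_controls(eig[mod], ctrl)
        fit = trajectory.loess_fit(
            positions[usable], z[usable], span=config.loess_span,
            degree=config.loess_degree, eval_positions=grid, series_name=mod,
        )
        fits.append(fit)
    table = pd.concat([f.to_frame() for f in fits], ignore_index=True)
    write_table(table, out / "trajectories.tsv")
    write_table(trajectory.summarize_trajectories(fits), out / "trajectory_summary.tsv")
    state["trajectories"] = fits


def _stage_panel(config: RunConfig, state: dict, out: Path) -> None:
    norm = state["norm"]
    assign = state["staging"]
    meta = state["meta"]
    # default stage contrast: early (Braak I-II) vs mid (Braak III-IV)
    # disease stages on the cohort's staging axis
    braak = assign["braak_stage"]
    early, mid = ("I", "II"), ("III", "IV")
    contrast = ("BraakI-II", "BraakIII-IV")
    samples = [s for s in norm.sample_ids if braak.get(s) in early + mid]
    y = pd.Series([1.0 if braak[s] in mid else 0.0 for s in samples],
                  index=samples)
    if y.nunique() < 2 or y.value_counts().min() < 4:
        return
    X = norm.values[samples].T
    X = X.fillna(X.median())  # whole-cohort median fill for the run table;
    # fold-safe imputation happens inside fit_elastic_net's CV when needed
    model = panels.fit_elastic_net(
        X, y.to_numpy(), alpha=config.elasticnet_alpha,
        n_folds=config.cv_folds, seed=config.seed,
        lambda_rule=config.lambda_rule,
        contrast=f"{contrast[0]}:{contrast[1]}",
    )
    coef = pd.DataFrame(model.selected, columns=["feature", "coefficient"])
    coef["contrast"] = model.contrast
    write_table(coef, out / "panel_coefficients.tsv")
    roc = panels.roc_auc(model.oof_scores.to_numpy(), y.to_numpy())
    write_table(pd.DataFrame({
        "threshold": roc.thresholds,
        "sensitivity": roc.sensitivity,
        "specificity": roc.specificity,
    }), out / "panel_roc.tsv")

    baselines = {"panel": X}
    cov_cols = [c for c in ("age",) if c in meta.columns]
    if cov_cols:
        cov = meta.loc[samples, cov_cols].astype(float)
        cov["sex_m"] = (meta.loc[samples, "sex"] == "M").astype(float)
        baselines["covariates"] = cov
    core_cols = [c for c in ("csf_abeta_ratio", "csf_ptau181", "csf_t_tau")
                 if c in meta.columns]
    if core_cols:
        baselines["core_biomarkers"] = meta.loc[samples, core_cols].astype(float)
    summary, per_fold = panels.compare_baselines(
        baselines, y.to_numpy(), alpha=config.elasticnet_alpha,
        seed=config.seed, lambda_rule=config.lambda_rule,
    )
    summary["auc_note"] = f"CV-AUC, {model.cv_folds}-fold, contrast {model.contrast}"
    write_table(summary, out / "panel_comparison.tsv")
    write_table(per_fold, out / "panel_comparison_folds.tsv")
    state["panel"] = model


def _stage_demographics(config: RunConfig, state: dict, out: Path) -> None:
    meta = state["meta"]
    assign = state["staging"]
    strata = assign["clinical_stratum"].reindex(meta.index)
    keep = strata.notna() & (strata != "unknown")
    counts = strata[keep].value_counts()
    strata = strata.where(strata.isin(counts[counts >= 2].index))
    if strata.dropna().nunique() < 2:
        return
    table = demographics.summarize_demographics(meta, strata)
    write_table(table, out / "demographics.tsv")
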