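"""Cluster-biomarker associations and protein-level differential abundance.

Implements the statistical layer around the co-expression modules:

* Spearman correlation tables of module Eigenproteins with clinical and
  analytical biomarkers, Bonferroni-corrected over all computed pairs;
* protein-wise linear models (group + age + sex) with empirical-Bayes
  variance moderation (moment-matched scaled-inverse-chi-square prior on the
  residual variances, limma-style) and BH or Bonferroni adjustment;
* covariate-adjusted group contrasts with post-hoc Tukey HSD;
* joint models with Aβ and tau PET SUVR as simultaneous predictors;
* cross-cohort Eigenprotein projection restricted to high-kME members.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .containers import AbundanceMatrix


# ---------------------------------------------------------------------------
# multiple-testing adjustment
# ---------------------------------------------------------------------------

def adjust_pvalues(p, method: str = "BH") -> np.ndarray:
    """Benjamini-Hochberg or Bonferroni adjusted p-values (NaN passed through)."""
    p = np.asarray(p, dtype=float)
    out = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    q = p[ok]
    n = q.size
    if n == 0:
        return out
    if method.upper() in ("BH", "FDR_BH", "BENJAMINI-HOCHBERG"):
        order = np.argsort(q)
        ranked = q[order] * n / np.arange(1, n + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        adj = np.empty(n)
        adj[order] = np.minimum(ranked, 1.0)
    elif method.lower() in ("bonferroni",):
        adj = np.minimum(q * n, 1.0)
    else:
        raise ValueError(f"unknown adjustment method: {method}")
    out[ok] = adj
    return out


# ---------------------------------------------------------------------------
# Spearman + Bonferroni correlation table
# ---------------------------------------------------------------------------

def spearman_bonferroni(
    eigenproteins: pd.DataFrame,
    biomarkers: pd.DataFrame,
    min_pairs: int = 5,
) -> pd.DataFrame:
    """Spearman rho of every module x biomarker pair with Bonferroni p.

    The family for Bonferroni is all pairs computed in this invocation.
    Constant biomarkers yield a missing entry with a warning.
    """
    rows = []
    for mod in eigenproteins.columns:
        for bio in biomarkers.columns:
            x = eigenproteins[mod]
            y = pd.to_numeric(biomarkers[bio], errors="coerce")
            joint = x.notna() & y.notna()
            n = int(joint.sum())
            if n < min_pairs:
                continue
            xv, yv = x[joint].to_numpy(), y[joint].to_numpy(dtype=float)
            if np.ptp(yv) == 0 or np.ptp(xv) == 0:
                warnings.warn(f"constant variable in pair ({mod}, {bio}); skipped")
                rows.append((mod, bio, np.nan, np.nan, n))
                continue
            rho, p = stats.spearmanr(xv, yv)
            rows.append((mod, bio, float(rho), float(p), n))
    table = pd.DataFrame(rows, columns=["module", "biomarker", "rho", "p", "n_pairs"])
    n_tests = int(table["p"].notna().sum())
    table["p_bonferroni"] = np.minimum(table["p"] * max(n_tests, 1), 1.0)
    table["n_tests"] = n_tests
    return table


# ---------------------------------------------------------------------------
# moderated linear models (empirical-Bayes variance shrinkage)
# ---------------------------------------------------------------------------

def _trigamma_inverse(x: float, tol: float = 1e-10, max_iter: int = 60) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton iteration on 1/trigamma)."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(max_iter):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < tol * y:
            break
    return float(y)


def estimate_variance_prior(s2: np.ndarray, df: np.ndarray) -> tuple[float, float]:
    """Moment-match a scaled-inverse-chi-square prior (d0, s0^2) to the
    observed residual variances via the log-variance moments.

    Uses z_g = log(s2_g); E[z] and Var[z] have closed forms in digamma /
    trigamma, giving d0 by trigamma inversion.  Returns (inf, geometric-mean
    variance) when the observed spread is no wider than sampling noise.
    """
    ok = np.isfinite(s2) & (s2 > 0) & (df > 0)
    s2, df = s2[ok], df[ok]
    if s2.size < 2:
        return np.inf, float(np.mean(s2)) if s2.size else 1.0
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = np.var(e, ddof=1) - np.mean(special.polygamma(1, df / 2.0))
    if evar <= 0:
        return np.inf, float(np.exp(emean))
    d0 = 2.0 * _trigamma_inverse(evar)
    s0_2 = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return float(d0), s0_2


def _design_matrix(meta: pd.DataFrame, group_col: str, covariates) -> tuple[pd.DataFrame, list[str]]:
    """Build a full-rank design: intercept + group dummies (first level ref)
    + numeric/dummy covariates.  Returns (design, group levels in order)."""
    groups = meta[group_col].astype(str)
    levels = sorted(groups.dropna().unique())
    X = pd.DataFrame(index=meta.index)
    X["Intercept"] = 1.0
    for lvl in levels[1:]:
        X[f"{group_col}[{lvl}]"] = (groups == lvl).astype(float)
    for cov in covariates:
        col = meta[cov]
        if col.dtype == object or str(col.dtype) == "category":
            for lvl in sorted(col.dropna().astype(str).unique())[1:]:
                X[f"{cov}[{lvl}]"] = (col.astype(str) == lvl).astype(float)
        else:
            X[cov] = pd.to_numeric(col, errors="raise").astype(float)
    return X, levels


def fit_moderated_lm(
    m: AbundanceMatrix,
    meta: pd.DataFrame,
    group_col: str,
    contrast: tuple[str, str],
    covariates=("age", "sex"),
    min_obs: int = 20,
    adj_method: str = "BH",
    prior_df: float | None = None,
) -> pd.DataFrame:
    """Protein-wise differential abundance with moderated t-statistics.

    For every protein an OLS model abundance ~ group + covariates is fitted on
    available cases; proteins with fewer than ``min_obs`` observations are
    excluded.  Residual variances are shrunk toward a moment-matched prior
    (``prior_df`` overrides the estimated d0; 0 disables moderation), and the
    contrast ``contrast[0] - contrast[1]`` is tested with a t distribution on
    d + d0 degrees of freedom.

    Returns a table with columns protein, contrast, log2_fc, se, t_moderated,
    df_total, p, p_adj, adj_method, n_obs.
    """
    samples = [s for s in m.sample_ids if s in meta.index]
    meta = meta.loc[samples]
    X_full, levels = _design_matrix(meta, group_col, covariates)
    for g in contrast:
        if g not in levels:
            raise ValueError(f"contrast level {g!r} not among groups {levels}")
    # contrast vector on the design coefficients
    cvec = np.zeros(X_full.shape[1])
    for g, sign in zip(contrast, (1.0, -1.0)):
        if g != levels[0]:
            cvec[X_full.columns.get_loc(f"{group_col}[{g}]")] += sign
    values = m.values[samples]
    Xf = X_full.to_numpy(dtype=float)
    valid_design = np.isfinite(Xf).all(axis=1)

    records = []
    coefs, sigma2s, dfs, ses = [], [], [], []
    kept = []
    for p in m.protein_ids:
        y = values.loc[p].to_numpy(dtype=float)
        obs = np.isfinite(y) & valid_design
        n = int(obs.sum())
        if n < min_obs:
            continue
        Xo, yo = Xf[obs], y[obs]
        rank = np.linalg.matrix_rank(Xo)
        if rank < Xo.shape[1]:
            # name collinear columns for the error
            _, R = np.linalg.qr(Xo)
            bad = [X_full.columns[j] for j in range(R.shape[1])
                   if abs(R[j, j]) < 1e-10] if R.shape[0] >= R.shape[1] else list(X_full.columns)
            raise ValueError(f"collinear design for protein {p!r}: columns {bad}")
        XtX_inv = np.linalg.inv(Xo.T @ Xo)
        beta = XtX_inv @ (Xo.T @ yo)
        resid = yo - Xo @ beta
        df = n - Xo.shape[1]
        sigma2 = float(resid @ resid / df)
        unscaled_se = float(np.sqrt(cvec @ XtX_inv @ cvec))
        coefs.append(float(cvec @ beta))
        sigma2s.append(sigma2)
        dfs.append(df)
        ses.append(unscaled_se)
        kept.append((p, n))

    if not kept:
        raise ValueError(f"no protein reached min_obs = {min_obs}")
    coefs = np.asarray(coefs)
    sigma2s = np.asarray(sigma2s)
    dfs = np.asarray(dfs, dtype=float)
    ses = np.asarray(ses)

    if prior_df is None:
        d0, s0_2 = estimate_variance_prior(sigma2s, dfs)
    else:
        d0 = float(prior_df)
        _, s0_2 = estimate_variance_prior(sigma2s, dfs)
    if np.isinf(d0):
        post_s2 = np.full_like(sigma2s, s0_2)
        df_total = np.full_like(dfs, np.inf)
    elif d0 == 0:
        post_s2 = sigma2s
        df_total = dfs
    else:
        post_s2 = (d0 * s0_2 + dfs * sigma2s) / (d0 + dfs)
        df_total = dfs + d0
    se = np.sqrt(post_s2) * ses
    with np.errstate(invalid="ignore", divide="ignore"):
        t_mod = coefs / se
    p_val = 2.0 * stats.t.sf(np.abs(t_mod), df=df_total)

    table = pd.DataFrame({
        "protein": [p for p, _ in kept],
        "contrast": f"{contrast[0]}-{contrast[1]}",
        "log2_fc": coefs,
        "se": se,
        "t_moderated": t_mod,
        "df_total": df_total,
        "p": p_val,
        "n_obs": [n for _, n in kept],
    })
    table["p_adj"] = adjust_pvalues(table["p"].to_numpy(), adj_method)
    table["adj_method"] = adj_method
    return table


# ---------------------------------------------------------------------------
# covariate-adjusted Tukey HSD
# ---------------------------------------------------------------------------

def group_contrast_tukey(
    values: pd.Series,
    groups: pd.Series,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """All pairwise group contrasts from a linear model with covariates,
    tested against the studentized-range distribution (Tukey HSD).

    Returns one row per unordered group pair with the covariate-adjusted
    difference, its SE, the Tukey-adjusted p, and the unadjusted t-test p.
    """
    df = pd.DataFrame({"y": pd.to_numeric(values, errors="coerce"),
                       "group": groups.astype(str)})
    if covariates is not None:
        for c in covariates.columns:
            df[c] = covariates[c]
    df = df.dropna(subset=["y", "group"])
    levels = sorted(df["group"].unique())
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    counts = df["group"].value_counts()
    if (counts < 2).any():
        raise ValueError("every group needs at least 2 samples")
    meta_cols = [c for c in df.columns if c not in ("y",)]
    X, _ = _design_matrix(df[meta_cols], "group", [c for c in meta_cols if c != "group"])
    Xv = X.to_numpy(dtype=float)
    y = df["y"].to_numpy(dtype=float)
    ok = np.isfinite(Xv).all(axis=1)
    Xv, y = Xv[ok], y[ok]
    if np.linalg.matrix_rank(Xv) < Xv.shape[1]:
        raise ValueError("singular design in Tukey contrast model")
    XtX_inv = np.linalg.inv(Xv.T @ Xv)
    beta = XtX_inv @ (Xv.T @ y)
    resid = y - Xv @ beta
    dof = len(y) - Xv.shape[1]
    s2 = float(resid @ resid / dof)
    k = len(levels)

    def coef_vec(a: str, b: str) -> np.ndarray:
        v = np.zeros(Xv.shape[1])
        for g, sign in ((a, 1.0), (b, -1.0)):
            if g != levels[0]:
                v[X.columns.get_loc(f"group[{g}]")] += sign
        return v

    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            v = coef_vec(levels[j], levels[i])
            diff = float(v @ beta)
            se = float(np.sqrt(s2 * (v @ XtX_inv @ v)))
            t = diff / se if se > 0 else np.nan
            q = abs(t) * np.sqrt(2.0)
            p_tukey = float(stats.studentized_range.sf(q, k, dof))
            p_unadj = float(2.0 * stats.t.sf(abs(t), df=dof))
            rows.append({
                "group_a": levels[i], "group_b": levels[j],
                "difference": diff, "se": se, "t": t, "df": dof,
                "p_tukey": min(p_tukey, 1.0), "p_unadjusted": p_unadj,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# dual PET-predictor models
# ---------------------------------------------------------------------------

def dual_pet_model(
    m: AbundanceMatrix,
    meta: pd.DataFrame,
    abeta_col: str = "abeta_pet_suvr",
    tau_col: str = "tau_suvr_global",
    covariates=("age", "sex", "diagnosis"),
    min_obs: int = 20,
) -> pd.DataFrame:
    """Per-protein joint linear model with Aβ and tau PET SUVR as
    simultaneous predictors, adjusting for age, sex and clinical diagnosis.

    Reports both partial coefficients with BH adjustment across proteins per
    predictor.  Warns (but fits) when the two SUVRs are nearly collinear.
    """
    samples = [s for s in m.sample_ids if s in meta.index]
    meta = meta.loc[samples]
    both = meta[[abeta_col, tau_col]].notna().all(axis=1)
    meta = meta.loc[both]
    samples = list(meta.index)
    r = np.corrcoef(meta[abeta_col], meta[tau_col])[0, 1]
    if abs(r) > 0.99:
        warnings.warn(f"Aβ and tau SUVR nearly collinear (r = {r:.3f})")
    X = pd.DataFrame(index=meta.index)
    X["Intercept"] = 1.0
    X[abeta_col] = meta[abeta_col].astype(float)
    X[tau_col] = meta[tau_col].astype(float)
    for cov in covariates:
        col = meta[cov]
        if col.dtype == object:
            for lvl in sorted(col.dropna().astype(str).unique())[1:]:
                X[f"{cov}[{lvl}]"] = (col.astype(str) == lvl).astype(float)
        else:
            X[cov] = col.astype(float)
    Xv = X.to_numpy(dtype=float)
    ia, it = X.columns.get_loc(abeta_col), X.columns.get_loc(tau_col)
    values = m.values[samples]
    rows = []
    for p in m.protein_ids:
        y = values.loc[p].to_numpy(dtype=float)
        obs = np.isfinite(y) & np.isfinite(Xv).all(axis=1)
        n = int(obs.sum())
        if n < min_obs or np.linalg.matrix_rank(Xv[obs]) < Xv.shape[1]:
            continue
        Xo, yo = Xv[obs], y[obs]
        XtX_inv = np.linalg.inv(Xo.T @ Xo)
        beta = XtX_inv @ (Xo.T @ yo)
        resid = yo - Xo @ beta
        dof = n - Xo.shape[1]
        s2 = float(resid @ resid / dof)
        out = {"protein": p, "n_obs": n}
        for name, idx in (("abeta", ia), ("tau", it)):
            se = np.sqrt(s2 * XtX_inv[idx, idx])
            t = beta[idx] / se
            out[f"coef_{name}"] = float(beta[idx])
            out[f"se_{name}"] = float(se)
            out[f"p_{name}"] = float(2.0 * stats.t.sf(abs(t), df=dof))
        rows.append(out)
    cols = ["protein", "n_obs", "coef_abeta", "se_abeta", "p_abeta",
            "coef_tau", "se_tau", "p_tau"]
    table = pd.DataFrame(rows, columns=cols)
    for name in ("abeta", "tau"):
        table[f"p_adj_{name}"] = adjust_pvalues(table[f"p_{name}"].to_numpy(), "BH")
    return table


# ---------------------------------------------------------------------------
# cross-cohort Eigenprotein projection
# ---------------------------------------------------------------------------

@dataclass
class ProjectedEigenprotein:
    module: str
    member_proteins_used: list[str]
    values: pd.Series          # per target sample
    z_to_controls: pd.Series
    coverage_frac: float


def project_eigenprotein(
    target: AbundanceMatrix,
    kme: pd.DataFrame,
    module: str,
    control_mask: pd.Series,
    kme_cut: float = 0.6,
    method: str = "pc",
) -> ProjectedEigenprotein:
    """Comparative Eigenprotein of a discovery module in a target cohort.

    Member set = discovery proteins with kME > ``kme_cut`` for the module,
    intersected with the target's protein universe.  Each member is
    standardized in the target cohort; the first principal component across
    target samples is the projected Eigenprotein (``method='mean_z'``
    averages member z-scores instead).  The sign is aligned so that the
    kME-sign-weighted mean correlation with the members is positive, and the
    values are z-scored to the target cohort's controls.
    """
    eligible = list(kme.index[kme[module] > kme_cut])
    members = [p for p in eligible if p in set(target.protein_ids)]
    if len(members) < 3:
        raise ValueError(
            f"module {module}: only {len(members)}/{len(eligible)} eligible "
            f"members present in target cohort"
        )
    X = target.values.loc[members].to_numpy(dtype=float)
    from .network import _standardize_impute
    Z = _standardize_impute(X)
    if method == "pc":
        _, _, Vt = np.linalg.svd(Z, full_matrices=False)
        v = Vt[0]
    elif method == "mean_z":
        v = Z.mean(axis=0)
    else:
        raise ValueError("method must be 'pc' or 'mean_z'")
    # sign alignment: kME-sign-weighted mean correlation with members positive
    signs = np.sign(kme.loc[members, module].to_numpy())
    cors = np.array([
        np.corrcoef(v, Z[i])[0, 1] if Z[i].std() > 0 else 0.0
        for i in range(len(members))
    ])
    if float(np.nansum(signs * cors)) < 0:
        v = -v
    values = pd.Series(v, index=target.values.columns, name=module)
    ctrl = control_mask.reindex(values.index).fillna(False).astype(bool)
    if ctrl.sum() < 2:
        raise ValueError("need at least 2 control samples for z-scoring")
    mu, sd = values[ctrl].mean(), values[ctrl].std(ddof=1)
    if sd == 0:
        raise ValueError("control SD is zero; cannot z-score")
    return ProjectedEigenprotein(
        module=module,
        member_proteins_used=members,
        values=values,
        z_to_controls=(values - mu) / sd,
        coverage_frac=len(members) / len(eligible),
    )


# ---------------------------------------------------------------------------
# volcano table
# ---------------------------------------------------------------------------

def volcano_table(
    diff: pd.DataFrame,
    labels: pd.Series,
    p_cut: float = 0.05,
) -> pd.DataFrame:
    """Plot-ready volcano table: log2FC, -log10 p, module label (0 = gray),
    and significance/direction flags at unadjusted and adjusted thresholds."""
    out = diff.copy()
    out["module"] = out["protein"].map(labels).fillna(0).astype(int)
    out["neg_log10_p"] = -np.log10(out["p"])
    direction = np.where(out["log2_fc"] > 0, "up", "down")
    flag = np.where(
        out["p_adj"] < p_cut, "adjusted",
        np.where(out["p"] < p_cut, "unadjusted", "ns"),
    )
    out["flag"] = [f"{d}, {f}" if f != "ns" else "ns"
                   for d, f in zip(direction, flag)]
    return out
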