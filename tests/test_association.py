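import numpy as np
import pandas as pd
import pytest
from scipy import stats

import proteostage as ps
from proteostage.association import adjust_pvalues, estimate_variance_prior

from conftest import make_matrix


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------

def bh_oracle(p):
    n = len(p)
    order = np.argsort(p)
    out = np.empty(n)
    prev = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        prev = min(prev, p[i] * n / rank)
        out[i] = prev
    return out


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_adjustments_match_brute_force(seed):
    rng = np.random.default_rng(seed)
    p = rng.uniform(size=1000)
    assert np.allclose(adjust_pvalues(p, "BH"), bh_oracle(p))
    assert np.allclose(adjust_pvalues(p, "bonferroni"), np.minimum(p * 1000, 1))


# ---------------------------------------------------------------------------
# Spearman + Bonferroni
# ---------------------------------------------------------------------------

class TestSpearman:
    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=40)
        ep = pd.DataFrame({"M1": x})
        bio = pd.DataFrame({"up": np.exp(x), "down": -np.exp(x)})
        tab = ps.spearman_bonferroni(ep, bio).set_index("biomarker")
        assert np.isclose(tab.loc["up", "rho"], 1.0)
        assert np.isclose(tab.loc["down", "rho"], -1.0)

    def test_matches_rank_pearson_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            x = rng.normal(size=20)
            y = rng.normal(size=20)
            tab = ps.spearman_bonferroni(
                pd.DataFrame({"M1": x}), pd.DataFrame({"b": y})
            )
            rx, ry = stats.rankdata(x), stats.rankdata(y)
            oracle = np.corrcoef(rx, ry)[0, 1]
            assert abs(tab["rho"].iloc[0] - oracle) < 1e-12

    def test_bonferroni_family_is_all_computed_pairs(self):
        rng = np.random.default_rng(2)
        ep = pd.DataFrame(rng.normal(size=(30, 3)), columns=["M1", "M2", "M3"])
        bio = pd.DataFrame(rng.normal(size=(30, 4)), columns=list("wxyz"))
        tab = ps.spearman_bonferroni(ep, bio)
        assert (tab["n_tests"] == 12).all()
        assert np.allclose(
            tab["p_bonferroni"], np.minimum(tab["p"] * 12, 1.0)
        )

    def test_constant_biomarker_warned_missing(self):
        ep = pd.DataFrame({"M1": np.arange(10.0)})
        bio = pd.DataFrame({"flat": np.ones(10)})
        with pytest.warns(UserWarning, match="constant"):
            tab = ps.spearman_bonferroni(ep, bio)
        assert tab["rho"].isna().all()


# ---------------------------------------------------------------------------
# moderated linear models
# ---------------------------------------------------------------------------

def _sim_matrix(rng, n_prot=60, n=40, shift_first=0, delta=0.0, sd=0.5):
    groups = ["a"] * (n // 2) + ["b"] * (n // 2)
    vals = rng.normal(0, sd, size=(n_prot, n))
    vals[:shift_first, n // 2:] += delta
    meta = pd.DataFrame({
        "grp": groups,
        "age": rng.normal(70, 5, n),
        "sex": rng.choice(["F", "M"], n),
    }, index=[f"S{j}" for j in range(n)])
    return make_matrix(vals), meta


class TestModeratedLm:
    def test_zero_prior_df_reproduces_ordinary_t(self):
        rng = np.random.default_rng(0)
        m, meta = _sim_matrix(rng, n_prot=30)
        tab = ps.fit_moderated_lm(m, meta, "grp", ("b", "a"),
                                  min_obs=10, prior_df=0.0).set_index("protein")
        import statsmodels.api as sm
        X = pd.get_dummies(meta[["grp", "sex"]], drop_first=True).astype(float)
        X["age"] = meta["age"]
        X = sm.add_constant(X)
        for p in m.protein_ids[:10]:
            fit = sm.OLS(m.values.loc[p], X).fit()
            assert abs(fit.tvalues["grp_b"] - tab.loc[p, "t_moderated"]) < 1e-8
            assert abs(fit.pvalues["grp_b"] - tab.loc[p, "p"]) < 1e-8

    def test_posterior_variance_shrinks_toward_prior(self):
        """Posterior variances lie between the per-protein variance and the
        prior, and moderation increases the degrees of freedom."""
        rng = np.random.default_rng(1)
        # heterogeneous true variances so shrinkage acts in both directions
        n_prot, n = 100, 40
        sds = rng.uniform(0.3, 1.5, n_prot)
        vals = rng.normal(0, 1, (n_prot, n)) * sds[:, None]
        meta = pd.DataFrame({
            "grp": ["a"] * 20 + ["b"] * 20,
            "age": rng.normal(70, 5, n),
            "sex": rng.choice(["F", "M"], n),
        }, index=[f"S{j}" for j in range(n)])
        m = make_matrix(vals)
        raw = ps.fit_moderated_lm(m, meta, "grp", ("b", "a"),
                                  min_obs=10, prior_df=0.0).set_index("protein")
        mod = ps.fit_moderated_lm(m, meta, "grp", ("b", "a"),
                                  min_obs=10).set_index("protein")
        s2_raw = raw["se"] ** 2      # proportional to residual variance
        s2_mod = mod["se"] ** 2
        d0, s0 = estimate_variance_prior(s2_raw.to_numpy(),
                                         raw["df_total"].to_numpy())
        assert 0 < d0 < np.inf
        # betweenness: shrinkage never overshoots the prior (on the shared
        # unscaled-SE scale, the prior corresponds to s0)
        lo = np.minimum(s2_raw, s0)
        hi = np.maximum(s2_raw, s0)
        assert ((s2_mod >= lo - 1e-12) & (s2_mod <= hi + 1e-12)).all()
        assert (mod["df_total"] > raw["df_total"]).all()
        # |t| ordering preserved where variances tie (same protein ordering
        # of effect sizes within equal-variance strata)
        same = (s2_raw / s2_raw.iloc[0]).between(0.999, 1.001)
        if same.sum() >= 2:
            sub_raw = raw.loc[same, "t_moderated"].abs().rank()
            sub_mod = mod.loc[same, "t_moderated"].abs().rank()
            assert (sub_raw == sub_mod).all()

    def test_min_obs_exclusion_counted(self):
        rng = np.random.default_rng(2)
        m, meta = _sim_matrix(rng, n_prot=20)
        vals = m.values.copy()
        vals.iloc[0, : vals.shape[1] - 5] = np.nan  # only 5 observations left
        m2 = ps.AbundanceMatrix(values=vals)
        tab = ps.fit_moderated_lm(m2, meta, "grp", ("b", "a"), min_obs=10)
        assert "P0" not in set(tab["protein"])
        assert len(tab) == 19

    def test_planted_shift_power(self):
        rng = np.random.default_rng(3)
        m, meta = _sim_matrix(rng, n_prot=200, n=60, shift_first=50,
                              delta=1.0, sd=0.5)
        tab = ps.fit_moderated_lm(m, meta, "grp", ("b", "a"), min_obs=20)
        hits = tab.set_index("protein").loc[[f"P{i}" for i in range(50)]]
        assert (hits["p_adj"] < 0.05).mean() >= 0.9
        assert (hits["log2_fc"] > 0).all()

    def test_unknown_contrast_level_rejected(self):
        rng = np.random.default_rng(4)
        m, meta = _sim_matrix(rng, n_prot=5)
        with pytest.raises(ValueError, match="contrast level"):
            ps.fit_moderated_lm(m, meta, "grp", ("b", "zz"), min_obs=5)


# ---------------------------------------------------------------------------
# Tukey HSD
# ---------------------------------------------------------------------------

class TestTukey:
    def test_two_groups_equal_model_t_test(self):
        rng = np.random.default_rng(0)
        y = pd.Series(np.r_[rng.normal(0, 1, 15), rng.normal(0.7, 1, 18)])
        g = pd.Series(["a"] * 15 + ["b"] * 18)
        tab = ps.group_contrast_tukey(y, g)
        assert len(tab) == 1
        assert abs(tab["p_tukey"].iloc[0] - tab["p_unadjusted"].iloc[0]) < 1e-6

    def test_identical_means_give_p_near_one(self):
        y = pd.Series(np.tile([1.0, 2.0, 3.0, 4.0], 3))
        g = pd.Series(np.repeat(["a", "b", "c"], 4))
        tab = ps.group_contrast_tukey(y, g)
        assert (tab["p_tukey"] > 0.95).all()

    def test_covariate_adjustment_removes_confounded_difference(self):
        rng = np.random.default_rng(1)
        age = np.r_[rng.normal(60, 3, 30), rng.normal(75, 3, 30)]
        y = pd.Series(0.1 * age + rng.normal(0, 0.3, 60))
        g = pd.Series(["young"] * 30 + ["old"] * 30)
        cov = pd.DataFrame({"age": age})
        unadj = ps.group_contrast_tukey(y, g)
        adj = ps.group_contrast_tukey(y, g, cov)
        assert unadj["p_tukey"].iloc[0] < 0.001     # confounded: hugely significant
        assert adj["p_tukey"].iloc[0] > 0.05        # adjusted: nothing left

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="2 groups"):
            ps.group_contrast_tukey(pd.Series([1.0, 2.0]), pd.Series(["a", "a"]))


# ---------------------------------------------------------------------------
# dual-PET models
# ---------------------------------------------------------------------------

class TestDualPet:
    def _cohort(self, seed=0, n=120, n_prot=30):
        rng = np.random.default_rng(seed)
        abeta = rng.uniform(1.0, 2.5, n)
        tau = 0.4 * abeta + rng.uniform(0.8, 2.0, n)
        vals = np.vstack([
            2.0 * abeta + rng.normal(0, 0.4, n),            # Aβ-driven
            1.5 * abeta + 1.5 * tau + rng.normal(0, 0.4, n),  # both
            rng.normal(0, 0.4, (n_prot - 2, n)),            # noise
        ])
        meta = pd.DataFrame({
            "abeta_pet_suvr": abeta,
            "tau_suvr_global": tau,
            "age": rng.normal(70, 5, n),
            "sex": rng.choice(["F", "M"], n),
            "diagnosis": rng.choice(["CU", "MCI", "AD"], n),
        }, index=[f"S{j}" for j in range(n)])
        return make_matrix(vals), meta

    def test_predictor_attribution(self):
        m, meta = self._cohort()
        tab = ps.dual_pet_model(m, meta).set_index("protein")
        assert tab.loc["P0", "p_adj_abeta"] < 0.05
        assert tab.loc["P0", "p_adj_tau"] > 0.05
        assert tab.loc["P1", "p_adj_abeta"] < 0.05
        assert tab.loc["P1", "p_adj_tau"] < 0.05
        noise = tab.iloc[2:]
        assert (noise["p_adj_abeta"] > 0.05).mean() > 0.9
        assert (noise["p_adj_tau"] > 0.05).mean() > 0.9

    def test_collinear_predictors_warn_but_fit(self):
        m, meta = self._cohort()
        meta = meta.copy()
        rng = np.random.default_rng(9)
        meta["tau_suvr_global"] = (meta["abeta_pet_suvr"] * 2.0
                                   + rng.normal(0, 1e-3, len(meta)))
        with pytest.warns(UserWarning, match="collinear"):
            tab = ps.dual_pet_model(m, meta)
        assert len(tab) > 0 and np.isfinite(tab["coef_abeta"]).all()


# ---------------------------------------------------------------------------
# Eigenprotein projection
# ---------------------------------------------------------------------------

class TestProjection:
    def test_control_z_scores_standardized(self, network_model, normalized, cohort):
        _, meta, _ = cohort
        kme = network_model.summary.kme
        ctrl = meta["is_control"].reindex(normalized.sample_ids).fillna(False)
        proj = ps.project_eigenprotein(normalized, kme, "M1", ctrl)
        z_ctrl = proj.z_to_controls[ctrl[ctrl].index]
        assert abs(z_ctrl.mean()) < 1e-10
        assert abs(z_ctrl.std(ddof=1) - 1.0) < 1e-10
        assert 0 < proj.coverage_frac <= 1

    def test_too_few_members_raises_with_coverage(self, network_model, normalized):
        kme = network_model.summary.kme.copy()
        kme["M1"] = -1.0  # nobody passes the cut
        ctrl = pd.Series(True, index=normalized.sample_ids)
        with pytest.raises(ValueError, match="members"):
            ps.project_eigenprotein(normalized, kme, "M1", ctrl)

    def test_mean_z_variant_close_to_pc(self, network_model, normalized, cohort):
        _, meta, _ = cohort
        ctrl = meta["is_control"].reindex(normalized.sample_ids).fillna(False)
        a = ps.project_eigenprotein(normalized, network_model.summary.kme,
                                    "M1", ctrl, method="pc")
        b = ps.project_eigenprotein(normalized, network_model.summary.kme,
                                    "M1", ctrl, method="mean_z")
        r = np.corrcoef(a.z_to_controls, b.z_to_controls)[0, 1]
        assert r > 0.95


# ---------------------------------------------------------------------------
# volcano table
# ---------------------------------------------------------------------------

def test_volcano_flags_and_bookkeeping():
    diff = pd.DataFrame({
        "protein": ["P1", "P2", "P3"],
        "log2_fc": [1.0, -0.5, 0.2],
        "p": [1e-5, 0.01, 0.5],
        "p_adj": [1e-3, 0.2, 0.9],
    })
    labels = pd.Series({"P1": 2, "P3": 1})
    out = ps.volcano_table(diff, labels)
    assert len(out) == 3
    assert out.set_index("protein").loc["P1", "flag"] == "up, adjusted"
    assert out.set_index("protein").loc["P2", "flag"] == "down, unadjusted"
    assert out.set_index("protein").loc["P3", "flag"] == "ns"
    assert out.set_index("protein").loc["P2", "module"] == 0  # unassigned -> gray
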