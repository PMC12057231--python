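"""Stage participants and associate protein modules with biomarkers.

Assigns A-beta/tau PET positivity (cut-offs 1.55 and 1.24), hierarchical
Braak stages with discordance detection, AT groups and clinical strata; then
correlates module Eigenproteins with biomarkers (Spearman + Bonferroni),
runs moderated differential abundance between PET groups, and projects
Eigenproteins into a validation cohort using kME > 0.6 members.
"""

import numpy as np

import proteostage as ps

matrix, meta, truth = ps.generate_cohort(seed=7)
norm = ps.filter_missingness(ps.normalize_tmt(matrix).drop_reference_channels())
net = ps.build_network(norm)

assign, pooling = ps.pool_sparse_stages(ps.assign_groups(meta, stage_basis="pet"))
print("Braak stage counts:", assign["braak_stage"].value_counts().to_dict())
print("AT groups:", assign["at_group"].value_counts().to_dict())

# module-biomarker correlations
eig = net.summary.eigenprotein
bio = meta[["abeta_pet_suvr", "csf_abeta_ratio", "csf_ptau181", "csf_t_tau"]]
tab = ps.spearman_bonferroni(eig.loc[meta.index], bio)
sig = tab[tab.p_bonferroni < 0.05].sort_values("rho")
print(f"\n{len(sig)}/{len(tab)} module-biomarker pairs significant after "
      "Bonferroni; strongest:")
print(sig[["module", "biomarker", "rho", "p_bonferroni"]].head(4).to_string(index=False))

# differential abundance between PET-defined groups (moderated t)
meta_at = meta.join(assign["at_group"])
samples = [s for s in norm.sample_ids if meta_at.loc[s, "at_group"] in ("A+T+", "A-T-")]
diff = ps.fit_moderated_lm(norm.subset_samples(samples), meta_at.loc[samples],
                           "at_group", ("A+T+", "A-T-"), min_obs=20)
n_sig = int((diff.p_adj < 0.05).sum())
print(f"\nA+T+ vs A-T-: {n_sig}/{len(diff)} proteins at BH-adjusted p < 0.05")

# cross-cohort Eigenprotein projection
(fmatrix, fmeta, flatent), _ = ps.generate_validation_cohorts(truth, seed=8)
proj = ps.project_eigenprotein(fmatrix, net.summary.kme, "M1",
                               fmeta["is_control"].astype(bool), kme_cut=0.6)
r = abs(np.corrcoef(proj.values,
                    flatent[flatent.columns[0]].reindex(proj.values.index))[0, 1])
print(f"\nM1 projected into the fluid cohort with "
      f"{len(proj.member_proteins_used)} members "
      f"(coverage {proj.coverage_frac:.0%})")
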