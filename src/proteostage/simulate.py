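"""Synthetic multi-cohort CSF proteome generator with planted co-expression modules.

The generator emulates the statistical structure of a TMT-based CSF proteomics
staging study: proteins organized into co-expression modules driven by latent,
disease-stage-dependent factors; TMT batch structure with a pooled reference
channel per set; abundance-dependent (left-censoring-like) missingness; and
clinical/imaging/fluid/biopsy metadata correlated with the underlying stage.

Five trajectory archetypes are planted (plus a null template), following the
qualitative shapes reported for CSF protein clusters across Braak stages:

* ``core_markers`` — stepwise increase through stage V, plateau at VI;
* ``endolysosomal`` — early rise peaking by stage II, returning toward
  pre-disease levels;
* ``immune_response`` — dip in early/mid stages with recovery by stage VI;
* ``metabolic`` — near-linear increase through stage V, sharp drop at VI;
* ``synapse_membrane`` — flat through stage V, sharp decrease at VI.

Template magnitudes are calibration choices (the source figures are
qualitative); the shapes, not the magnitudes, are the contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import AbundanceMatrix, Scale

STAGES = ("CTRL", "I", "II", "III", "IV", "V", "VI")

#: Stage means (z-units of the latent factor) over CTRL, I..VI.
TEMPLATES: dict[str, tuple[float, ...]] = {
    "core_markers":     (0.0, 0.25, 0.55, 0.90, 1.30, 1.80, 1.70),
    "endolysosomal":    (0.0, 0.50, 0.70, 0.55, 0.40, 0.25, 0.10),
    "immune_response":  (0.0, -0.20, -0.50, -0.70, -0.50, -0.25, 0.00),
    "metabolic":        (0.0, 0.15, 0.40, 0.70, 1.00, 1.30, 0.60),
    "synapse_membrane": (0.0, 0.00, 0.05, 0.05, 0.00, -0.05, -0.80),
    "null_module":      (0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0),
}

DEFAULT_MODULE_SIZES = {
    "core_markers": 60,
    "endolysosomal": 30,
    "immune_response": 20,
    "metabolic": 40,
    "synapse_membrane": 50,
}


def make_templates() -> dict[str, np.ndarray]:
    """Return the five trajectory archetypes plus the null template.

    Each template is a 7-vector of stage means in z-units over the ordered
    stages CTRL, I, ..., VI.
    """
    return {name: np.asarray(vals, dtype=float) for name, vals in TEMPLATES.items()}


@dataclass
class SyntheticTruth:
    """Planted ground truth of a generated cohort."""

    module_of_protein: dict[str, str | None]
    loadings: dict[str, float]
    latent_factor: pd.DataFrame          # samples x modules
    stage_of_sample: dict[str, int]      # 0 = CTRL .. 6 = VI
    noise_sd: float
    jitter_sd: float
    batch_sd: float
    batch_effects: pd.DataFrame          # TMT sets x proteins
    baseline_log2: dict[str, float]
    discordant: dict[str, bool]
    seed: int
    templates: dict[str, np.ndarray] = field(default_factory=make_templates)

    @property
    def module_names(self) -> list[str]:
        return sorted({m for m in self.module_of_protein.values() if m})

    def true_labels(self, protein_ids) -> np.ndarray:
        """Integer labels for ARI-style comparisons; 0 = background."""
        names = self.module_names
        idx = {m: i + 1 for i, m in enumerate(names)}
        return np.asarray(
            [idx.get(self.module_of_protein.get(p), 0) for p in protein_ids]
        )


def _draw_tau_suvrs(rng, stage: int, cut_pos=(1.35, 2.6), cut_neg=(0.85, 1.15),
                    discordant_prob: float = 0.1):
    """Regional tau SUVRs whose positivity pattern is a prefix of length=stage
    with probability 1-discordant_prob, otherwise carries one discordant flip."""
    pattern = np.zeros(6, dtype=bool)
    pattern[:stage] = True
    flipped = False
    if stage <= 4 and rng.random() < discordant_prob:
        flip = rng.integers(stage + 1, 6)  # leaves region stage+1 negative
        pattern[flip] = True
        flipped = True
    suvr = np.where(
        pattern,
        rng.uniform(cut_pos[0], cut_pos[1], size=6),
        rng.uniform(cut_neg[0], cut_neg[1], size=6),
    )
    return suvr, flipped


_DIAGNOSIS_PROBS = {
    0: (("CU", 0.9), ("SCI", 0.1)),
    1: (("CU", 0.5), ("SCI", 0.3), ("MCI", 0.2)),
    2: (("CU", 0.2), ("SCI", 0.3), ("MCI", 0.5)),
    3: (("SCI", 0.1), ("MCI", 0.7), ("AD", 0.2)),
    4: (("MCI", 0.5), ("AD", 0.5)),
    5: (("MCI", 0.2), ("AD", 0.8)),
    6: (("MCI", 0.05), ("AD", 0.95)),
}

# shapes (z-like) used for stage-correlated CSF biomarkers
_PTAU_SHAPE = np.array([0.0, 0.3, 0.6, 1.0, 1.4, 1.8, 1.85])   # plateau at VI
_ARATIO_SHAPE = np.array([0.0, -0.5, -0.8, -0.95, -1.0, -1.0, -1.0])  # early decline
_ABETA_POS_PROB = np.array([0.15, 0.7, 0.85, 0.95, 1.0, 1.0, 1.0])


def _draw_diagnosis(rng, stage: int) -> str:
    labels, probs = zip(*_DIAGNOSIS_PROBS[stage])
    return rng.choice(labels, p=np.asarray(probs) / np.sum(probs))


def generate_cohort(
    n_per_stage=(20,) * 7,
    module_sizes: dict[str, int] | None = None,
    n_background: int = 300,
    noise_sd: float = 0.5,
    missing_rate: float = 0.1,
    tmt_set_size: int = 15,
    jitter_sd: float = 0.8,
    batch_sd: float = 0.3,
    seed: int = 7,
) -> tuple[AbundanceMatrix, pd.DataFrame, SyntheticTruth]:
    """Generate a discovery cohort of raw TMT reporter intensities + metadata.

    The protein model in log2 space is

        value = baseline + loading * latent + batch_offset + noise

    where ``latent`` for a module protein is the module's stage-template value
    for the sample's stage plus per-sample Gaussian jitter (sd ``jitter_sd``),
    shared by all proteins of the module.  Background proteins carry no latent
    term.  Raw intensities are ``2**value``; each TMT set of ``tmt_set_size``
    study samples receives one pooled-CSF reference channel.  Missingness is
    protein-level Bernoulli with probability decreasing in baseline abundance
    and mean ``missing_rate``.
    """
    n_per_stage = tuple(int(n) for n in n_per_stage)
    if len(n_per_stage) != 7:
        raise ValueError("n_per_stage must have length 7 (CTRL, I..VI)")
    module_sizes = dict(module_sizes or DEFAULT_MODULE_SIZES)
    unknown = set(module_sizes) - set(TEMPLATES)
    if unknown:
        raise ValueError(f"unknown module templates: {sorted(unknown)}")
    if any(sz < 3 for sz in module_sizes.values()):
        raise ValueError("module sizes must be >= 3")
    if n_background < 0:
        raise ValueError("n_background must be non-negative")
    rng = np.random.default_rng(seed)
    templates = make_templates()

    # protein universe
    n_proteins = sum(module_sizes.values()) + n_background
    protein_ids = [f"P{i:04d}" for i in range(1, n_proteins + 1)]
    module_of_protein: dict[str, str | None] = {}
    i = 0
    for name in sorted(module_sizes):
        for _ in range(module_sizes[name]):
            module_of_protein[protein_ids[i]] = name
            i += 1
    for j in range(i, n_proteins):
        module_of_protein[protein_ids[j]] = None

    loadings = {
        p: (rng.uniform(0.4, 0.95) if module_of_protein[p] else 0.0)
        for p in protein_ids
    }
    baseline = {p: rng.normal(10.0, 1.5) for p in protein_ids}

    # samples and stages
    stages = np.repeat(np.arange(7), n_per_stage)
    n_study = stages.size
    sample_ids = [f"S{i:04d}" for i in range(1, n_study + 1)]
    stage_of_sample = dict(zip(sample_ids, stages.tolist()))

    # TMT sets: random sample-to-set assignment so stage is not confounded
    order = rng.permutation(n_study)
    n_sets = int(np.ceil(n_study / tmt_set_size))
    tmt_set = {}
    for pos, idx in enumerate(order):
        tmt_set[sample_ids[idx]] = f"set{pos // tmt_set_size + 1}"
    ref_ids = [f"REF_set{k + 1}" for k in range(n_sets)]
    for k, rid in enumerate(ref_ids):
        tmt_set[rid] = f"set{k + 1}"
    all_samples = sample_ids + ref_ids
    is_reference = {s: s.startswith("REF_") for s in all_samples}

    # latent factors per module per study sample
    module_names = sorted(module_sizes)
    latent = pd.DataFrame(
        {
            m: templates[m][stages] + rng.normal(0.0, jitter_sd, size=n_study)
            for m in module_names
        },
        index=sample_ids,
    )

    set_names = [f"set{k + 1}" for k in range(n_sets)]
    batch = pd.DataFrame(
        rng.normal(0.0, batch_sd, size=(n_sets, n_proteins)),
        index=set_names, columns=protein_ids,
    )

    # assemble log2 matrix (proteins x samples)
    log2 = np.empty((n_proteins, len(all_samples)))
    load_vec = np.array([loadings[p] for p in protein_ids])
    base_vec = np.array([baseline[p] for p in protein_ids])
    lat_mat = np.zeros((n_proteins, n_study))
    for pi, p in enumerate(protein_ids):
        m = module_of_protein[p]
        if m:
            lat_mat[pi] = latent[m].to_numpy()
    noise = rng.normal(0.0, noise_sd, size=(n_proteins, n_study))
    batch_cols = np.array(
        [batch.loc[tmt_set[s]].to_numpy() for s in sample_ids]
    ).T  # proteins x study samples
    log2[:, :n_study] = (
        base_vec[:, None] + load_vec[:, None] * lat_mat + batch_cols + noise
    )
    # pooled reference channel: cohort-average profile + batch + small noise
    for k, rid in enumerate(ref_ids):
        log2[:, n_study + k] = (
            base_vec
            + batch.loc[f"set{k + 1}"].to_numpy()
            + rng.normal(0.0, 0.05, size=n_proteins)
        )

    values = pd.DataFrame(2.0 ** log2, index=protein_ids, columns=all_samples)

    # abundance-dependent missingness: low-abundance proteins drop out more
    if missing_rate > 0:
        ranks = pd.Series(base_vec, index=protein_ids).rank(pct=True).to_numpy()
        p_miss = np.clip(missing_rate * 2.0 * (1.0 - ranks), 0.0, 0.95)
        mask = rng.random(size=values.shape) < p_miss[:, None]
        values = values.mask(mask)

    matrix = AbundanceMatrix(
        values=values, tmt_set=tmt_set, is_reference=is_reference,
        scale=Scale.raw_intensity,
    )

    # metadata
    rows = []
    discordant = {}
    for s in sample_ids:
        st = stage_of_sample[s]
        suvr, flipped = _draw_tau_suvrs(rng, st)
        discordant[s] = flipped
        abeta_pos = rng.random() < _ABETA_POS_PROB[st]
        abeta_suvr = rng.uniform(1.6, 2.4) if abeta_pos else rng.uniform(1.0, 1.5)
        ratio = max(0.02, 0.10 + 0.045 * _ARATIO_SHAPE[st] + rng.normal(0.0, 0.006))
        abeta40 = rng.normal(9000.0, 1500.0)
        shape = _PTAU_SHAPE[st]
        row = {
            "sample_id": s,
            "cohort": "discovery",
            "age": float(np.clip(rng.normal(62.0 + 1.8 * st, 6.0), 55.0, 85.0)),
            "sex": "F" if rng.random() < 0.5 else "M",
            "diagnosis": _draw_diagnosis(rng, st),
            "abeta_pet_suvr": abeta_suvr,
            "csf_abeta40": abeta40,
            "csf_abeta42": ratio * abeta40,
            "csf_abeta_ratio": ratio,
            "csf_t_tau": 200.0 + 150.0 * shape + rng.normal(0.0, 40.0),
            "csf_ptau181": 15.0 + 12.0 * shape + rng.normal(0.0, 3.0),
            "csf_ptau199": 10.0 + 8.0 * shape + rng.normal(0.0, 2.5),
            "csf_ptau202": 8.0 + 5.0 * shape + rng.normal(0.0, 2.0),
            "csf_ptau205": 5.0 + 6.0 * shape + rng.normal(0.0, 1.5),
            "csf_ptau217": 3.0 + 5.0 * shape + rng.normal(0.0, 1.0),
            "csf_ptau231": 12.0 + 9.0 * shape + rng.normal(0.0, 2.5),
            "csf_ptau396": 9.0 + 6.0 * shape + rng.normal(0.0, 2.0),
            "is_control": bool(st == 0 and not flipped),
            "tmt_set": tmt_set[s],
        }
        for r in range(6):
            row[f"tau_suvr_braak{r + 1}"] = suvr[r]
        rows.append(row)
    meta = pd.DataFrame(rows).set_index("sample_id")

    truth = SyntheticTruth(
        module_of_protein=module_of_protein,
        loadings=loadings,
        latent_factor=latent,
        stage_of_sample=stage_of_sample,
        noise_sd=noise_sd,
        jitter_sd=jitter_sd,
        batch_sd=batch_sd,
        batch_effects=batch,
        baseline_log2=baseline,
        discordant=discordant,
        seed=seed,
    )
    return matrix, meta, truth


def generate_validation_cohorts(
    truth: SyntheticTruth,
    overlap_frac: float = 0.7,
    n_per_stage_fluid=(25,) * 7,
    n_per_stage_biopsy=(12,) * 7,
    seed: int = 11,
):
    """Generate fluid- and biopsy-staged validation cohorts sharing the
    discovery truth (loadings, templates) on a subset of proteins.

    Only ``overlap_frac`` of discovery proteins are quantified in the
    validation cohorts (emulating incomplete cross-cohort protein overlap).
    The fluid cohort is staged by CSF Aβ42/40 ratio and clinical diagnosis;
    the biopsy cohort by a semiquantitative cortical Aβ plaque score (0..3)
    and a neurofibrillary-tangle flag, both drawn consistently with the
    sample's latent stage.
    """
    if not 0 < overlap_frac <= 1:
        raise ValueError("overlap_frac must be in (0, 1]")
    rng = np.random.default_rng(seed)
    all_proteins = sorted(truth.module_of_protein)
    n_keep = max(3, int(round(overlap_frac * len(all_proteins))))
    keep = sorted(rng.choice(all_proteins, size=n_keep, replace=False)) \
        if n_keep < len(all_proteins) else all_proteins

    fluid = _generate_from_truth(truth, keep, n_per_stage_fluid, rng, prefix="F")
    biopsy = _generate_from_truth(truth, keep, n_per_stage_biopsy, rng, prefix="B")

    fmatrix, fstages, flatent = fluid
    bmatrix, bstages, blatent = biopsy

    fmeta = _fluid_metadata(fstages, rng)
    bmeta = _biopsy_metadata(bstages, rng)
    return (fmatrix, fmeta, flatent), (bmatrix, bmeta, blatent)


def _generate_from_truth(truth, proteins, n_per_stage, rng, prefix, tmt_set_size=15):
    templates = truth.templates
    stages = np.repeat(np.arange(7), tuple(int(n) for n in n_per_stage))
    n = stages.size
    sample_ids = [f"{prefix}{i:04d}" for i in range(1, n + 1)]
    module_names = sorted({m for m in truth.module_of_protein.values() if m})
    latent = pd.DataFrame(
        {
            m: templates[m][stages] + rng.normal(0.0, truth.jitter_sd, size=n)
            for m in module_names
        },
        index=sample_ids,
    )
    n_sets = int(np.ceil(n / tmt_set_size))
    order = rng.permutation(n)
    tmt_set = {}
    for pos, idx in enumerate(order):
        tmt_set[sample_ids[idx]] = f"{prefix}set{pos // tmt_set_size + 1}"
    batch = rng.normal(0.0, truth.batch_sd, size=(n_sets, len(proteins)))
    set_index = {f"{prefix}set{k + 1}": k for k in range(n_sets)}

    log2 = np.empty((len(proteins), n))
    for pi, p in enumerate(proteins):
        m = truth.module_of_protein[p]
        lat = latent[m].to_numpy() if m else 0.0
        log2[pi] = (
            truth.baseline_log2[p]
            + truth.loadings[p] * lat
            + batch[[set_index[tmt_set[s]] for s in sample_ids], pi]
            + rng.normal(0.0, truth.noise_sd, size=n)
        )
    values = pd.DataFrame(log2, index=list(proteins), columns=sample_ids)
    matrix = AbundanceMatrix(
        values=values, tmt_set=tmt_set,
        is_reference={s: False for s in sample_ids}, scale=Scale.log2_ratio,
    )
    stage_of_sample = dict(zip(sample_ids, stages.tolist()))
    return matrix, stage_of_sample, latent


def _fluid_metadata(stage_of_sample, rng) -> pd.DataFrame:
    rows = []
    for s, st in stage_of_sample.items():
        abeta_pos = rng.random() < _ABETA_POS_PROB[st]
        # positivity defined by ratio < 0.061: draw consistently by construction
        ratio = rng.uniform(0.030, 0.0605) if abeta_pos else rng.uniform(0.065, 0.12)
        abeta40 = rng.normal(9000.0, 1500.0)
        rows.append({
            "sample_id": s,
            "cohort": "fluid_validation",
            "age": float(np.clip(rng.normal(64.0 + 1.5 * st, 6.0), 55.0, 85.0)),
            "sex": "F" if rng.random() < 0.5 else "M",
            "diagnosis": _draw_diagnosis(rng, st),
            "csf_abeta40": abeta40,
            "csf_abeta42": ratio * abeta40,
            "csf_abeta_ratio": ratio,
            "is_control": bool(st == 0 and not abeta_pos),
        })
    return pd.DataFrame(rows).set_index("sample_id")


def _biopsy_metadata(stage_of_sample, rng) -> pd.DataFrame:
    # semiquantitative plaque score tracks amyloid stage; tangles appear mid-late
    score_by_stage = {0: 0, 1: 1, 2: 1, 3: 2, 4: 2, 5: 3, 6: 3}
    rows = []
    for s, st in stage_of_sample.items():
        score = score_by_stage[st]
        if st == 0 and rng.random() < 0.2:
            score = 1
        tangles = bool(st >= 3 and rng.random() < 0.85)
        rows.append({
            "sample_id": s,
            "cohort": "biopsy_validation",
            "age": float(np.clip(rng.normal(70.0 + 0.8 * st, 5.0), 55.0, 85.0)),
            "sex": "F" if rng.random() < 0.5 else "M",
            "biopsy_abeta_score": score,
            "biopsy_tangles": tangles,
            "is_control": bool(score == 0 and not tangles),
        })
    return pd.DataFrame(rows).set_index("sample_id")
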