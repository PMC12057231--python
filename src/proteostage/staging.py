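"""Aβ/tau positivity, hierarchical Braak staging, AT groups, clinical strata.

Positivity conventions follow the strict-inequality wording of the underlying
cut-offs: Aβ PET positive iff SUVR > 1.55; tau PET positive iff SUVR > 1.24;
CSF Aβ42/40 positive iff ratio < 0.061.  Values exactly at a cut-off map to
negative (measured values rarely tie; the convention is documented).

Braak staging is hierarchical over the six regional tau PET SUVRs ordered
I (transentorhinal) -> VI (precentral/pericalcarine/paracentral/postcentral):
the stage is the length of the maximal all-positive prefix; any positive
region after the first negative one makes the pattern *discordant*; an
all-negative pattern is stage 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import tau_suvr_vector

BRAAK_LEVELS = ("0", "I", "II", "III", "IV", "V", "VI")
_ROMAN = {0: "0", 1: "I", 2: "II", 3: "III", 4: "IV", 5: "V", 6: "VI"}


def classify_abeta_pet(suvr, cut: float = 1.55) -> str:
    """Aβ PET status: 'pos' iff SUVR strictly exceeds the cut; missing -> 'unknown'."""
    if suvr is None or (isinstance(suvr, float) and np.isnan(suvr)):
        return "unknown"
    return "pos" if float(suvr) > cut else "neg"


def classify_tau_pet(suvr, cut: float = 1.24) -> str:
    """Tau PET status: 'pos' iff SUVR strictly exceeds the cut; missing -> 'unknown'."""
    if suvr is None or (isinstance(suvr, float) and np.isnan(suvr)):
        return "unknown"
    return "pos" if float(suvr) > cut else "neg"


def classify_abeta_csf(ratio, cut: float = 0.061) -> str:
    """CSF Aβ42/40 status: 'pos' iff ratio strictly below the cut."""
    if ratio is None or (isinstance(ratio, float) and np.isnan(ratio)):
        return "unknown"
    return "pos" if float(ratio) < cut else "neg"


def assign_braak_stage(region_suvrs, cut: float = 1.24) -> str:
    """Hierarchical Braak stage from the 6 regional tau SUVRs (I -> VI order).

    Returns '0'..'VI', 'discordant', or 'unknown' (any region missing).
    """
    if region_suvrs is None:
        return "unknown"
    suvrs = np.asarray(region_suvrs, dtype=float)
    if suvrs.shape != (6,):
        raise ValueError("expected exactly 6 regional SUVRs ordered Braak I->VI")
    if np.isnan(suvrs).any():
        return "unknown"
    pos = suvrs > cut
    prefix = 0
    while prefix < 6 and pos[prefix]:
        prefix += 1
    if pos[prefix:].any():
        return "discordant"
    return _ROMAN[prefix]


@dataclass
class StageAssignment:
    sample_id: str
    abeta_status: str
    tau_status: str
    braak_stage: str
    at_group: str
    clinical_stratum: str
    stage_basis: str


def _at_group(abeta: str, tau: str) -> str:
    if "unknown" in (abeta, tau):
        return "unknown"
    return f"A{'+' if abeta == 'pos' else '-'}T{'+' if tau == 'pos' else '-'}"


def _clinical_stratum(diagnosis, abeta: str) -> str:
    if diagnosis is None or (isinstance(diagnosis, float) and np.isnan(diagnosis)):
        return "unknown"
    if abeta == "unknown":
        return "unknown"
    dx = "CU/SCI" if diagnosis in ("CU", "SCI") else str(diagnosis)
    return f"{dx}_A{'+' if abeta == 'pos' else '-'}"


def assign_groups(
    meta: pd.DataFrame,
    stage_basis: str = "pet",
    abeta_suvr_cut: float = 1.55,
    tau_suvr_cut: float = 1.24,
    abeta_ratio_cut: float = 0.061,
    biopsy_abeta_min_score: int = 1,
) -> pd.DataFrame:
    """Stage every sample in a metadata table.

    ``stage_basis`` selects the cohort convention: 'pet' (Aβ + regional tau
    PET, hierarchical Braak stage), 'csf' (Aβ42/40 ratio), or 'biopsy'
    (semiquantitative Aβ plaque score, A+ iff score >= ``biopsy_abeta_min_score``,
    and a tangle flag for T).  Overall tau status under 'pet' is positive iff
    the Braak stage is >= I (configurable convention: the first region drives
    global tau positivity).

    Returns a DataFrame indexed by sample_id with columns abeta_status,
    tau_status, braak_stage, at_group, clinical_stratum, stage_basis.
    """
    if stage_basis not in ("pet", "csf", "biopsy"):
        raise ValueError("stage_basis must be 'pet', 'csf' or 'biopsy'")
    rows = []
    for sid, row in meta.iterrows():
        rowd = row.to_dict()
        braak = "unknown"
        if stage_basis == "pet":
            abeta = classify_abeta_pet(rowd.get("abeta_pet_suvr"), abeta_suvr_cut)
            braak = assign_braak_stage(tau_suvr_vector(rowd), tau_suvr_cut)
            if braak == "unknown":
                tau = "unknown"
            elif braak == "discordant":
                tau = "pos"  # at least one region positive by definition
            else:
                tau = "neg" if braak == "0" else "pos"
        elif stage_basis == "csf":
            abeta = classify_abeta_csf(rowd.get("csf_abeta_ratio"), abeta_ratio_cut)
            tau = "unknown"
        else:
            score = rowd.get("biopsy_abeta_score")
            if score is None or (isinstance(score, float) and np.isnan(score)):
                abeta = "unknown"
            else:
                abeta = "pos" if score >= biopsy_abeta_min_score else "neg"
            tangles = rowd.get("biopsy_tangles")
            if tangles is None or (isinstance(tangles, float) and np.isnan(tangles)):
                tau = "unknown"
            else:
                tau = "pos" if bool(tangles) else "neg"
        rows.append(StageAssignment(
            sample_id=str(sid),
            abeta_status=abeta,
            tau_status=tau,
            braak_stage=braak,
            at_group=_at_group(abeta, tau),
            clinical_stratum=_clinical_stratum(rowd.get("diagnosis"), abeta),
            stage_basis=stage_basis,
        ))
    out = pd.DataFrame([r.__dict__ for r in rows]).set_index("sample_id")
    return out


def pool_sparse_stages(assignments: pd.DataFrame, min_n: int = 3):
    """Merge adjacent Braak levels with fewer than ``min_n`` samples into the
    next level (e.g. a 2-sample stage III pools with IV into 'III-IV').

    Returns ``(assignments_with_pooled_column, pooling_map)`` where the map
    sends every original level to exactly one pooled level.
    """
    counts = assignments["braak_stage"].value_counts()
    ordered = [lvl for lvl in BRAAK_LEVELS if counts.get(lvl, 0) > 0]
    pooling: dict[str, str] = {}
    i = 0
    while i < len(ordered):
        group = [ordered[i]]
        total = counts[ordered[i]]
        while total < min_n and i + 1 < len(ordered):
            i += 1
            group.append(ordered[i])
            total += counts[ordered[i]]
        if total < min_n and pooling:
            # trailing sparse group: pool backwards with the previous level
            last_label = list(pooling.values())[-1]
            merged = sorted({*last_label.split("-"), *group},
                            key=BRAAK_LEVELS.index)
            label = "-".join(merged)
            for lvl, old in list(pooling.items()):
                if old == last_label:
                    pooling[lvl] = label
            for lvl in group:
                pooling[lvl] = label
        else:
            label = group[0] if len(group) == 1 else "-".join(group)
            for lvl in group:
                pooling[lvl] = label
        i += 1
    for lvl in ("discordant", "unknown"):
        if counts.get(lvl, 0) > 0:
            pooling[lvl] = lvl
    out = assignments.copy()
    out["braak_stage_pooled"] = out["braak_stage"].map(pooling)
    return out, pooling


def stage_positions(levels, pooled_map=None) -> dict[str, float]:
    """Numeric positions for ordered stage codes: CTRL/0 = 0, I = 1, ... VI = 6;
    pooled levels sit at the midpoint of their members."""
    pos = {lvl: float(i) for i, lvl in enumerate(BRAAK_LEVELS)}
    pos["CTRL"] = 0.0
    out = {}
    for lvl in levels:
        if lvl in pos:
            out[lvl] = pos[lvl]
        elif "-" in lvl:
            parts = lvl.split("-")
            out[lvl] = float(np.mean([pos[p] for p in parts]))
        else:
            warnings.warn(f"stage level {lvl!r} has no numeric position")
    return out
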