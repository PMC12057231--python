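"""Core in-memory containers for CSF proteome staging analyses.

The central object is :class:`AbundanceMatrix`, a proteins x samples matrix of
(log2) protein abundances together with the TMT multiplexing structure: every
sample belongs to a TMT set, and each set carries one pooled-CSF reference
channel used for batch evaluation.  Clinical, imaging, fluid and biopsy
variables live in a per-sample metadata table (:func:`validate_metadata`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Mapping

import numpy as np
import pandas as pd


class Scale(str, Enum):
    """Measurement scale of an abundance matrix."""

    raw_intensity = "raw_intensity"
    log2_ratio = "log2_ratio"


@dataclass
class AbundanceMatrix:
    """Proteins x samples abundance matrix with TMT-set annotation.

    Parameters
    ----------
    values : pandas.DataFrame
        Rows indexed by protein ID, columns by sample ID.  Missing entries are
        NaN.  Orientation is fixed: proteins are rows (they are quantified
        across participants), all internal math assumes this.
    tmt_set : mapping of sample ID -> TMT set label.
    is_reference : mapping of sample ID -> bool
        True for pooled-CSF reference channels.
    scale : Scale
        Raw reporter intensities (strictly positive) or log2 ratios.
    """

    values: pd.DataFrame
    tmt_set: dict[str, str] = field(default_factory=dict)
    is_reference: dict[str, bool] = field(default_factory=dict)
    scale: Scale = Scale.log2_ratio

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        self.scale = Scale(self.scale)
        prot = self.values.index
        samp = self.values.columns
        if prot.duplicated().any():
            dups = sorted(set(prot[prot.duplicated()]))
            raise ValueError(f"duplicate protein IDs: {dups}")
        if samp.duplicated().any():
            dups = sorted(set(samp[samp.duplicated()]))
            raise ValueError(f"duplicate sample IDs: {dups}")
        if not self.tmt_set:
            self.tmt_set = {s: "set1" for s in samp}
        if not self.is_reference:
            self.is_reference = {s: False for s in samp}
        missing_ann = [s for s in samp if s not in self.tmt_set]
        if missing_ann:
            raise ValueError(f"samples without TMT set annotation: {missing_ann}")
        arr = self.values.to_numpy()
        if np.isinf(arr).any():
            raise ValueError("abundance matrix contains infinite entries")
        if self.scale is Scale.raw_intensity and np.nanmin(arr, initial=np.inf) <= 0:
            raise ValueError("raw intensities must be strictly positive where present")

    # -- convenience accessors -------------------------------------------------
    @property
    def protein_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_proteins(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def reference_samples(self) -> list[str]:
        return [s for s in self.sample_ids if self.is_reference.get(s, False)]

    def study_samples(self) -> list[str]:
        return [s for s in self.sample_ids if not self.is_reference.get(s, False)]

    def subset_samples(self, sample_ids) -> "AbundanceMatrix":
        sample_ids = list(sample_ids)
        return replace(
            self,
            values=self.values.loc[:, sample_ids].copy(),
            tmt_set={s: self.tmt_set[s] for s in sample_ids},
            is_reference={s: self.is_reference.get(s, False) for s in sample_ids},
        )

    def subset_proteins(self, protein_ids) -> "AbundanceMatrix":
        return replace(self, values=self.values.loc[list(protein_ids)].copy())

    def drop_reference_channels(self) -> "AbundanceMatrix":
        return self.subset_samples(self.study_samples())


# Metadata column conventions.  Optional columns may be absent or NaN.
DIAGNOSES = ("CU", "SCI", "MCI", "AD")
COHORTS = ("discovery", "fluid_validation", "biopsy_validation")
TAU_SUVR_COLUMNS = tuple(f"tau_suvr_braak{i}" for i in range(1, 7))
CSF_COLUMNS = (
    "csf_abeta40",
    "csf_abeta42",
    "csf_abeta_ratio",
    "csf_t_tau",
    "csf_ptau181",
    "csf_ptau199",
    "csf_ptau202",
    "csf_ptau205",
    "csf_ptau217",
    "csf_ptau231",
    "csf_ptau396",
)

_SEX_MAP = {
    "f": "F", "female": "F", "w": "F", "woman": "F",
    "m": "M", "male": "M", "man": "M",
}


def normalize_sex(value) -> str | float:
    """Map common sex encodings ("F", "female", ...) onto {"F", "M"}."""
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return np.nan
    key = str(value).strip().lower()
    if key in _SEX_MAP:
        return _SEX_MAP[key]
    raise ValueError(f"unrecognized sex encoding: {value!r}")


def validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    """Validate and type a per-sample metadata table.

    Requires a ``sample_id`` column (or index); one row per sample.  Known
    columns are typed; unknown columns are preserved untouched.  SUVR and CSF
    ratio values must be strictly positive where present.
    """
    meta = meta.copy()
    if "sample_id" in meta.columns:
        meta = meta.set_index("sample_id")
    meta.index = meta.index.astype(str)
    meta.index.name = "sample_id"
    if meta.index.duplicated().any():
        dups = sorted(set(meta.index[meta.index.duplicated()]))
        raise ValueError(f"duplicate sample_id rows in metadata: {dups}")
    if "sex" in meta.columns:
        meta["sex"] = meta["sex"].map(normalize_sex)
    if "diagnosis" in meta.columns:
        bad = set(meta["diagnosis"].dropna()) - set(DIAGNOSES)
        if bad:
            raise ValueError(f"unknown diagnosis labels: {sorted(bad)}")
    if "cohort" in meta.columns:
        bad = set(meta["cohort"].dropna()) - set(COHORTS)
        if bad:
            raise ValueError(f"unknown cohort labels: {sorted(bad)}")
    numeric = ["age", "abeta_pet_suvr", "biopsy_abeta_score", *TAU_SUVR_COLUMNS, *CSF_COLUMNS]
    for col in numeric:
        if col in meta.columns:
            meta[col] = pd.to_numeric(meta[col], errors="raise")
    for col in ("abeta_pet_suvr", "csf_abeta_ratio", *TAU_SUVR_COLUMNS):
        if col in meta.columns:
            vals = meta[col].dropna()
            if (vals <= 0).any():
                raise ValueError(f"{col} must be strictly positive where present")
    for col in ("is_control", "biopsy_tangles"):
        if col in meta.columns:
            meta[col] = meta[col].map(_to_bool)
    return meta


def _to_bool(value):
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return np.nan
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    key = str(value).strip().lower()
    if key in {"true", "1", "yes", "t"}:
        return True
    if key in {"false", "0", "no", "f"}:
        return False
    raise ValueError(f"unrecognized boolean encoding: {value!r}")


def tau_suvr_vector(meta_row: Mapping) -> np.ndarray | None:
    """Extract the 6-vector of regional tau SUVRs in Braak I->VI order.

    Returns None if any region is missing.
    """
    vals = []
    for col in TAU_SUVR_COLUMNS:
        v = meta_row.get(col, np.nan)
        if v is None or (isinstance(v, float) and np.isnan(v)):
            return None
        vals.append(float(v))
    return np.asarray(vals)
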