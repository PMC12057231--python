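"""Readers and writers for abundance matrices and metadata tables.

All formats are plain text (TSV/CSV).  Matrices are stored proteins-as-rows
with the first column holding protein IDs and the header row holding sample
IDs.  The missing-value token set is fixed to {"", "NA", "NaN", "nan"}.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import AbundanceMatrix, Scale, validate_metadata

NA_TOKENS = ["", "NA", "NaN", "nan"]


def _sep_for(path: Path, dialect: str | None) -> str:
    if dialect == "tsv":
        return "\t"
    if dialect == "csv":
        return ","
    return "," if Path(path).suffix.lower() == ".csv" else "\t"


def read_abundance_matrix(
    path,
    dialect: str | None = None,
    scale: Scale | str = Scale.log2_ratio,
    tmt_set: dict[str, str] | None = None,
    is_reference: dict[str, bool] | None = None,
) -> AbundanceMatrix:
    """Read a proteins x samples matrix from TSV/CSV.

    Duplicated protein or sample IDs raise with the offending IDs; a
    non-numeric cell raises naming its row and column.
    """
    path = Path(path)
    sep = _sep_for(path, dialect)
    df = pd.read_csv(
        path, sep=sep, index_col=0, na_values=NA_TOKENS,
        keep_default_na=False, dtype=str,
    )
    df.index = df.index.astype(str)
    df.index.name = "protein_id"
    if df.index.duplicated().any():
        dups = sorted(set(df.index[df.index.duplicated()]))
        raise ValueError(f"duplicate protein IDs in {path.name}: {dups}")
    if df.columns.duplicated().any():
        dups = sorted(set(df.columns[df.columns.duplicated()]))
        raise ValueError(f"duplicate sample IDs in {path.name}: {dups}")
    num = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        try:
            # astype(float) parses with correct rounding (to_numeric can be
            # one ulp off, breaking bit-exact round trips)
            converted = df[col].astype(float)
        except (TypeError, ValueError):
            probe = pd.to_numeric(df[col], errors="coerce")
            bad = probe.isna() & df[col].notna()
            row = df.index[bad.to_numpy().nonzero()[0][0]]
            raise ValueError(
                f"non-numeric cell at protein {row!r}, sample {col!r}: "
                f"{df.loc[row, col]!r}"
            ) from None
        num[col] = converted
    return AbundanceMatrix(
        values=num,
        tmt_set=dict(tmt_set) if tmt_set else {},
        is_reference=dict(is_reference) if is_reference else {},
        scale=Scale(scale),
    )


def write_abundance_matrix(matrix: AbundanceMatrix, path, dialect: str | None = None) -> None:
    """Write a matrix to TSV/CSV; round-trips finite values bit-exactly."""
    path = Path(path)
    sep = _sep_for(path, dialect)
    matrix.values.to_csv(path, sep=sep, na_rep="NA", float_format="%.17g")


def read_metadata(path, matrix: AbundanceMatrix | None = None, dialect: str | None = None) -> pd.DataFrame:
    """Read and validate a per-sample metadata table keyed by sample_id.

    If a matrix is given, warns listing matrix samples absent from the
    metadata; metadata-only samples are retained and flagged in a boolean
    ``in_matrix`` column.
    """
    path = Path(path)
    sep = _sep_for(path, dialect)
    raw = pd.read_csv(path, sep=sep, na_values=NA_TOKENS, keep_default_na=False)
    if "sample_id" not in raw.columns:
        raise ValueError(f"metadata file {path.name} lacks a sample_id column")
    meta = validate_metadata(raw)
    if matrix is not None:
        matrix_samples = set(matrix.sample_ids)
        missing = sorted(matrix_samples - set(meta.index))
        if missing:
            warnings.warn(f"samples in matrix but absent from metadata: {missing}")
        meta["in_matrix"] = [s in matrix_samples for s in meta.index]
    return meta


def write_metadata(meta: pd.DataFrame, path, dialect: str | None = None) -> None:
    path = Path(path)
    sep = _sep_for(path, dialect)
    meta.to_csv(path, sep=sep, na_rep="NA")


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    """Write a result table as TSV with a stable float representation."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", na_rep="NA", index=index)


def write_json(obj, path) -> None:
    """Serialize provenance/config-style objects to deterministic JSON."""
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, Path):
            return str(o)
        return str(o)

    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=default)
        fh.write("\n")
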