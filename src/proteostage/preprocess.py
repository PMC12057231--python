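"""TMT ratio normalization, missingness filtering, and PCA/cluster QC.

Normalization follows the two-step median-ratio scheme used for multiplexed
TMT CSF proteomics: within each TMT set, every protein's intensities are
divided by that protein's set-wise median; each resulting sample column is
then divided by its sample median, and the matrix is log2-transformed.  Both
steps are carried out as median subtractions in log2 space and repeated to a
fixed point (median polish), so the stated post-states — every sample's
median log2 ratio exactly 0, and idempotence of the whole operation — hold
exactly rather than approximately.  The first sweep is exactly the classical
two-step procedure; subsequent sweeps apply corrections that are orders of
magnitude smaller.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .containers import AbundanceMatrix, Scale


def normalize_tmt(
    raw: AbundanceMatrix,
    exclude_reference_from_protein_median: bool = True,
    tol: float = 1e-12,
    max_iter: int = 100,
) -> AbundanceMatrix:
    """Median-ratio normalize raw TMT reporter intensities to log2 ratios.

    Medians are taken over observed values only; a protein entirely missing
    within a set simply stays missing.  By default the pooled reference
    channels are excluded from the set-wise protein medians (they are not
    study samples) but every column, reference or not, is normalized.

    Raises if the input is not raw-intensity scale or contains non-positive
    intensities.
    """
    if raw.scale is not Scale.raw_intensity:
        raise ValueError("normalize_tmt expects a raw_intensity matrix")
    log2 = np.log2(raw.values.to_numpy(dtype=float))
    cols = list(raw.values.columns)
    set_of = np.asarray([raw.tmt_set[s] for s in cols])
    is_ref = np.asarray([bool(raw.is_reference.get(s, False)) for s in cols])

    for _ in range(max_iter):
        delta = 0.0
        # step 1: per protein, subtract the set-wise median (log2 of ratio)
        for set_name in np.unique(set_of):
            in_set = set_of == set_name
            med_cols = in_set & ~is_ref if exclude_reference_from_protein_median else in_set
            if not med_cols.any():
                med_cols = in_set
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
                med = np.nanmedian(log2[:, med_cols], axis=1)
            med = np.where(np.isnan(med), 0.0, med)
            log2[:, in_set] -= med[:, None]
            delta = max(delta, np.abs(med).max(initial=0.0))
        # step 2: per sample, subtract the sample median
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            smed = np.nanmedian(log2, axis=0)
        smed = np.where(np.isnan(smed), 0.0, smed)
        log2 -= smed[None, :]
        delta = max(delta, np.abs(smed).max(initial=0.0))
        if delta <= tol:
            break

    out = pd.DataFrame(log2, index=raw.values.index, columns=raw.values.columns)
    return replace(raw, values=out, scale=Scale.log2_ratio)


def filter_missingness(m: AbundanceMatrix, max_missing_frac: float = 0.5) -> AbundanceMatrix:
    """Drop proteins missing in more than ``max_missing_frac`` of samples.

    The boundary is strict: a protein missing in exactly half of the samples
    is retained ("more than 50%" excluded).  Protein order is preserved.
    """
    frac = m.values.isna().mean(axis=1)
    keep = frac <= max_missing_frac
    if not keep.any():
        raise ValueError("missingness filter removed every protein")
    return m.subset_proteins(m.values.index[keep])


@dataclass
class QCReport:
    """Advisory sample-level QC from PCA on the normalized matrix."""

    pc_coordinates: pd.DataFrame      # samples x [PC1, PC2]
    outlier_flags: pd.Series          # bool per sample
    outlier_rule: str
    linkage_heights: np.ndarray       # average-linkage merge heights


def qc_outliers(m: AbundanceMatrix, sd_mult: float = 4.0) -> QCReport:
    """Flag samples far out on PC1/PC2 of the sample-wise abundance PCA.

    Missing entries are median-imputed per protein, the matrix is centered,
    and samples are scored on the first two principal components.  A sample
    is flagged if either coordinate deviates from the coordinate median by
    more than ``sd_mult`` robust standard deviations (1.4826 * MAD).  Flags
    are advisory; nothing is removed.  The PC sign is fixed by forcing the
    largest-|loading| protein positive, making flags deterministic.
    """
    if m.n_samples < 3:
        raise ValueError("qc_outliers needs at least 3 samples")
    X = m.values.to_numpy(dtype=float).copy()
    med = np.nanmedian(X, axis=1)
    med = np.where(np.isnan(med), 0.0, med)
    nan_mask = np.isnan(X)
    X[nan_mask] = np.broadcast_to(med[:, None], X.shape)[nan_mask]
    X = X - X.mean(axis=1, keepdims=True)          # center proteins
    # samples as observations: SVD of samples x proteins
    U, S, Vt = np.linalg.svd(X.T, full_matrices=False)
    coords = U[:, :2] * S[:2]
    for j in range(2):
        lead = np.argmax(np.abs(Vt[j]))
        if Vt[j, lead] < 0:
            coords[:, j] = -coords[:, j]
    pc = pd.DataFrame(coords, index=m.values.columns, columns=["PC1", "PC2"])
    center = pc.median(axis=0)
    mad = (pc - center).abs().median(axis=0)
    robust_sd = 1.4826 * mad
    robust_sd = robust_sd.replace(0.0, np.nan)
    dev = (pc - center).abs() / robust_sd
    flags = (dev > sd_mult).any(axis=1).fillna(False)
    rule = (
        f"|PC coordinate - median| > {sd_mult} * 1.4826*MAD on PC1 or PC2 "
        "(median-imputed, centered PCA)"
    )
    from scipy.cluster.hierarchy import linkage
    from scipy.spatial.distance import pdist
    heights = linkage(pdist(coords), method="average")[:, 2]
    return QCReport(pc_coordinates=pc, outlier_flags=flags,
                    outlier_rule=rule, linkage_heights=heights)
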