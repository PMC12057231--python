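"""Signed weighted protein co-expression network construction and module summaries.

Pipeline: biweight midcorrelation (bicor) between all protein pairs -> signed
adjacency a_ij = ((1 + cor_ij)/2)^beta at a soft threshold power chosen for
approximate scale-free topology -> topological overlap matrix (TOM) -> average
linkage clustering of 1 - TOM -> dynamic branch cutting with an optional PAM
assignment stage -> merging of modules with correlated Eigenproteins ->
per-module Eigenproteins (first principal components) and kME (protein-to-
Eigenprotein Pearson correlation).

The tree cut is a documented simplification of the hybrid dynamic-tree-cut
heuristic: a single height cut controlled by ``deep_split`` (mapped onto the
dendrogram's height range), followed by nearest-module PAM assignment of
unassigned proteins restricted to dendrogram-consistent candidates and capped
at a maximum assignment distance so that background proteins far from every
module remain unassigned (label 0, "gray").
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .containers import AbundanceMatrix

DEEP_SPLIT_FRACTION = {0: 0.95, 1: 0.9, 2: 0.8, 3: 0.7, 4: 0.6}


# ---------------------------------------------------------------------------
# biweight midcorrelation
# ---------------------------------------------------------------------------

def _bicor_transform(x: np.ndarray, max_p_outliers: float) -> np.ndarray:
    """Per-vector bicor transform: weighted, median-centered values.

    Returns a vector ``a`` with NaN where x is missing such that
    bicor(x, y) = sum(a*b) / sqrt(sum(a^2) * sum(b^2)) over joint observations.
    Falls back to Pearson centering when MAD = 0; returns all-zeros (flagging
    an undefined correlation) when the vector is constant.
    """
    obs = np.isfinite(x)
    xo = x[obs]
    med = np.median(xo)
    mad = np.median(np.abs(xo - med))
    a = np.full_like(x, np.nan, dtype=float)
    if mad == 0.0:
        if np.std(xo) == 0.0:
            a[obs] = 0.0  # constant: correlation undefined -> 0 downstream
            return a
        a[obs] = xo - np.mean(xo)  # Pearson fallback
        return a
    u = (x - med) / (9.0 * mad)
    uo = u[obs]
    # side-capping: at most max_p_outliers of samples per tail get zero weight
    if max_p_outliers < 0.5:
        q_lo = np.quantile(uo, max_p_outliers)
        q_hi = np.quantile(uo, 1.0 - max_p_outliers)
        if q_lo < -1.0:
            u = np.where(u < 0, u / (-q_lo), u)
        if q_hi > 1.0:
            u = np.where(u > 0, u / q_hi, u)
    w = (1.0 - u ** 2) ** 2 * (np.abs(u) < 1.0)
    a[obs] = (w * (x - med))[obs]
    return a


def bicor(x, y, max_p_outliers: float = 0.05) -> float:
    """Biweight midcorrelation of two vectors over jointly observed entries."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    joint = np.isfinite(x) & np.isfinite(y)
    a = _bicor_transform(np.where(joint, x, np.nan), max_p_outliers)[joint]
    b = _bicor_transform(np.where(joint, y, np.nan), max_p_outliers)[joint]
    denom = np.sqrt(np.sum(a ** 2) * np.sum(b ** 2))
    if denom == 0.0:
        return 0.0
    return float(np.clip(np.sum(a * b) / denom, -1.0, 1.0))


def bicor_matrix(
    m: AbundanceMatrix,
    max_p_outliers: float = 0.05,
    min_pairs: int = 10,
) -> pd.DataFrame:
    """All-pairs bicor with pairwise-complete observations.

    Per-protein medians/MADs/weights are computed once on each protein's own
    observed values (the usual treatment of missing data in biweight
    correlation matrices); pair sums then run over jointly observed samples.
    For complete data this equals the per-pair formula exactly; with missing
    entries it differs from recomputing the weights per pair only through the
    weight estimates.  Pairs with fewer than ``min_pairs`` joint observations
    (or undefined correlations) are set to 0 with a warning.
    """
    X = m.values.to_numpy(dtype=float)
    n_prot = X.shape[0]
    A = np.empty_like(X)
    for i in range(n_prot):
        A[i] = _bicor_transform(X[i], max_p_outliers)
    M = np.isfinite(A).astype(float)
    A0 = np.where(np.isfinite(A), A, 0.0)
    num = A0 @ A0.T
    ss = (A0 ** 2) @ M.T          # ss[i, j] = sum over joint of a_i^2
    with np.errstate(invalid="ignore", divide="ignore"):
        cor = num / np.sqrt(ss * ss.T)
    counts = M @ M.T
    bad = ~np.isfinite(cor)
    few = counts < min_pairs
    if (bad | few).any():
        n_zeroed = int(((bad | few).sum() - np.diag(bad | few).sum()) // 2)
        if n_zeroed:
            warnings.warn(
                f"{n_zeroed} protein pairs had undefined bicor or < {min_pairs} "
                "joint observations; set to 0"
            )
    cor[bad | few] = 0.0
    cor = np.clip(cor, -1.0, 1.0)
    np.fill_diagonal(cor, 1.0)
    cor = (cor + cor.T) / 2.0
    return pd.DataFrame(cor, index=m.values.index, columns=m.values.index)


# ---------------------------------------------------------------------------
# soft threshold selection and adjacency
# ---------------------------------------------------------------------------

@dataclass
class SoftThresholdDiagnostics:
    candidate_powers: list[int]
    scale_free_r2: list[float]
    mean_connectivity: list[float]
    median_connectivity: list[float]
    chosen_power: int
    reached_target: bool

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "power": self.candidate_powers,
            "scale_free_r2": self.scale_free_r2,
            "mean_connectivity": self.mean_connectivity,
            "median_connectivity": self.median_connectivity,
        })


def signed_adjacency(cor, beta: int) -> np.ndarray:
    """Signed network adjacency a_ij = ((1 + cor_ij)/2)^beta, unit diagonal."""
    if beta < 1:
        raise ValueError("beta must be >= 1")
    c = np.asarray(cor, dtype=float)
    a = ((1.0 + c) / 2.0) ** beta
    np.fill_diagonal(a, 1.0)
    return a


def scale_free_fit(k: np.ndarray, n_bins: int = 10) -> float:
    """Signed R^2 of the log-log degree-distribution regression.

    Connectivities are binned (equal width); log10 of the bin frequency is
    regressed on log10 of the bin mean connectivity.  The R^2 is signed
    negative-slope: positive only when the fit slopes downward.
    """
    k = np.asarray(k, dtype=float)
    if np.allclose(k, k[0]):
        return 0.0
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        sel = which == b
        if sel.sum() == 0:
            continue
        mean_k = k[sel].mean()
        freq = sel.mean()
        if mean_k > 0 and freq > 0:
            xs.append(np.log10(mean_k))
            ys.append(np.log10(freq))
    if len(xs) < 3:
        return 0.0
    xs, ys = np.asarray(xs), np.asarray(ys)
    slope, _ = np.polyfit(xs, ys, 1)
    r = np.corrcoef(xs, ys)[0, 1]
    return float(-np.sign(slope) * r ** 2)


def select_soft_threshold(
    cor,
    candidates=tuple(range(1, 21)),
    r2_target: float = 0.9,
    max_mean_connectivity: float = 100.0,
) -> SoftThresholdDiagnostics:
    """Pick the smallest power reaching the scale-free fit target under the
    mean-connectivity bound; otherwise the best-fitting power under the bound,
    with a warning."""
    c = np.asarray(cor, dtype=float)
    off = c[~np.eye(c.shape[0], dtype=bool)]
    if off.size and np.allclose(off, off[0]):
        raise ValueError("degenerate correlation matrix: all correlations equal")
    fits, means, medians = [], [], []
    for beta in candidates:
        a = signed_adjacency(c, int(beta))
        np.fill_diagonal(a, 0.0)
        k = a.sum(axis=1)
        fits.append(scale_free_fit(k))
        means.append(float(k.mean()))
        medians.append(float(np.median(k)))
    chosen = None
    for i, beta in enumerate(candidates):
        if fits[i] >= r2_target and means[i] < max_mean_connectivity:
            chosen = int(beta)
            reached = True
            break
    if chosen is None:
        ok = [i for i in range(len(candidates)) if means[i] < max_mean_connectivity]
        pool = ok if ok else list(range(len(candidates)))
        best = max(pool, key=lambda i: fits[i])
        chosen = int(candidates[best])
        reached = False
        warnings.warn(
            f"no candidate power reached scale-free R^2 >= {r2_target}; "
            f"choosing power {chosen} with best fit {fits[best]:.3f}"
        )
    return SoftThresholdDiagnostics(
        candidate_powers=[int(b) for b in candidates],
        scale_free_r2=fits,
        mean_connectivity=means,
        median_connectivity=medians,
        chosen_power=chosen,
        reached_target=reached,
    )


# ---------------------------------------------------------------------------
# topological overlap
# ---------------------------------------------------------------------------

def topological_overlap(a) -> np.ndarray:
    """TOM_ij = (L_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij), TOM_ii = 1,

    where L_ij = sum_{u != i,j} a_iu * a_uj and k_i = sum_{u != i} a_iu.
    Expects a symmetric adjacency with unit diagonal and entries in [0, 1].
    """
    a = np.asarray(a, dtype=float)
    if not np.allclose(a, a.T):
        raise ValueError("adjacency must be symmetric")
    if a.min() < -1e-12 or a.max() > 1 + 1e-12:
        raise ValueError("adjacency entries must lie in [0, 1]")
    a0 = a.copy()
    np.fill_diagonal(a0, 0.0)
    L = a0 @ a0                      # diag of a0 is 0, so u = i, j drop out
    k = a0.sum(axis=1)
    denom = np.minimum.outer(k, k) + 1.0 - a0
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = (L + a0) / denom
    tom[~np.isfinite(tom)] = 0.0
    np.fill_diagonal(tom, 1.0)
    return tom


# ---------------------------------------------------------------------------
# dynamic tree cut (simplified hybrid) + PAM stage
# ---------------------------------------------------------------------------

def _tree_arrays(Z: np.ndarray, n: int):
    """Leaf lists and minimum internal merge height per dendrogram node.

    Node ids: 0..n-1 are leaves; n + t is the cluster formed by merge row t.
    """
    n_nodes = n + Z.shape[0]
    leaves: list[list[int]] = [[] for _ in range(n_nodes)]
    submin = np.full(n_nodes, np.inf)
    for i in range(n):
        leaves[i] = [i]
    for t in range(Z.shape[0]):
        a, b = int(Z[t, 0]), int(Z[t, 1])
        node = n + t
        leaves[node] = leaves[a] + leaves[b]
        submin[node] = min(Z[t, 2], submin[a], submin[b])
    return leaves, submin


def _cut_subtree(node: int, cut: float, Z: np.ndarray, n: int) -> list[int]:
    """Component roots of the subtree under ``node`` when cut at ``cut``.

    Average linkage is monotone, so a node whose merge height is <= cut is a
    complete component."""
    out, stack = [], [node]
    while stack:
        v = stack.pop()
        if v < n or Z[v - n, 2] <= cut:
            out.append(v)
        else:
            stack.extend((int(Z[v - n, 0]), int(Z[v - n, 1])))
    return out


def cut_tree_dynamic(
    dissim,
    deep_split: int = 4,
    min_size: int = 10,
    pam_stage: bool = True,
    pam_respects_dendro: bool = True,
    max_pam_dist: float | None = None,
    base_cut_frac: float = 0.95,
):
    """Cluster a dissimilarity matrix into modules.

    Average-linkage hierarchical clustering followed by a two-level branch
    cut: a base cut high on the dendrogram (``base_cut_frac`` of the merge
    height range) identifies coarse branches, and each branch with at least
    ``min_size`` leaves is then recursively refined by cutting its own
    subtree at ``deep_split``'s fraction of the *local* height range (higher
    deep_split -> lower relative cut -> more, smaller modules).  A branch is
    split only when the split yields at least two children of ``min_size``
    leaves.  Everything outside a module is label 0 unless the PAM stage
    assigns it to the nearest module; PAM candidates are restricted to
    dendrogram-consistent modules when ``pam_respects_dendro`` and the
    assignment distance is capped at ``max_pam_dist`` (default: the base cut
    height) so that proteins far from every module stay unassigned.

    Returns ``(Z, labels)``: the scipy linkage matrix and an integer label
    array (0 = unassigned/"gray", modules 1..K by decreasing size).
    """
    if deep_split not in DEEP_SPLIT_FRACTION:
        raise ValueError(f"deep_split must be in {sorted(DEEP_SPLIT_FRACTION)}")
    D = np.asarray(dissim, dtype=float)
    n = D.shape[0]
    if n < 2:
        raise ValueError("need at least 2 items to cluster")
    Z = linkage(squareform(D, checks=False), method="average")
    labels = np.zeros(n, dtype=int)
    if n < min_size:
        warnings.warn("fewer proteins than min_size: all unassigned")
        return Z, labels
    heights = Z[:, 2]
    h_min, h_max = float(heights.min()), float(heights.max())
    if h_max - h_min < 1e-12:
        warnings.warn("degenerate dendrogram (all merges at one height): no modules")
        return Z, labels
    cut = h_min + base_cut_frac * (h_max - h_min)
    frac = DEEP_SPLIT_FRACTION[deep_split]
    leaves, submin = _tree_arrays(Z, n)
    root = n + Z.shape[0] - 1

    def refine(node: int) -> list[int]:
        if node < n or len(leaves[node]) < 2 * min_size:
            return [node]
        top = Z[node - n, 2]
        lmin = submin[node]
        if not np.isfinite(lmin) or top - lmin < 1e-12:
            return [node]
        local_cut = lmin + frac * (top - lmin)
        children = _cut_subtree(node, local_cut, Z, n)
        big = [c for c in children if len(leaves[c]) >= min_size]
        if len(big) >= 2:
            out = []
            for c in big:
                out.extend(refine(c))
            return out
        return [node]

    branches = [b for b in _cut_subtree(root, cut, Z, n) if len(leaves[b]) >= min_size]
    modules: list[list[int]] = []
    for b in branches:
        modules.extend(leaves[node] for node in refine(b))
    modules.sort(key=lambda mem: (-len(mem), min(mem)))
    for new, mem in enumerate(modules, start=1):
        labels[np.asarray(mem)] = new
    n_modules = len(modules)

    if pam_stage and n_modules > 0 and (labels == 0).any():
        if max_pam_dist is None:
            max_pam_dist = cut
        unassigned = np.flatnonzero(labels == 0)
        members = {k: np.flatnonzero(labels == k) for k in range(1, n_modules + 1)}
        mean_d = {
            k: D[np.ix_(unassigned, members[k])].mean(axis=1)
            for k in members
        }
        if pam_respects_dendro:
            candidates = _dendro_candidates(Z, labels, n)
        else:
            allmods = set(members)
            candidates = {i: allmods for i in unassigned}
        for pos, i in enumerate(unassigned):
            cands = candidates.get(i, set())
            if not cands:
                continue
            best = min(cands, key=lambda k: mean_d[k][pos])
            if mean_d[best][pos] <= max_pam_dist:
                labels[i] = best
        labels = _relabel_by_size(labels)
    return Z, labels


def _dendro_candidates(Z, labels, n) -> dict[int, set[int]]:
    """For each unassigned leaf, the module labels present in its dendrogram
    component at the first merge that brings it together with any module."""
    mods: dict[int, set[int]] = {}
    waiting: dict[int, list[int]] = {}
    out: dict[int, set[int]] = {}
    for i in range(n):
        mods[i] = {labels[i]} if labels[i] > 0 else set()
        waiting[i] = [i] if labels[i] == 0 else []
    for t in range(Z.shape[0]):
        a, b = int(Z[t, 0]), int(Z[t, 1])
        node = n + t
        new_mods = mods[a] | mods[b]
        if new_mods:
            for leaf in waiting[a] + waiting[b]:
                out[leaf] = set(new_mods)
            waiting[node] = []
        else:
            waiting[node] = waiting[a] + waiting[b]
        mods[node] = new_mods
        for child in (a, b):
            mods.pop(child, None)
            waiting.pop(child, None)
    return out


def _relabel_by_size(labels: np.ndarray) -> np.ndarray:
    out = np.zeros_like(labels)
    sizes = pd.Series(labels[labels > 0]).value_counts()
    order = sorted(sizes.index, key=lambda k: (-sizes[k], int(np.argmax(labels == k))))
    for new, old in enumerate(order, start=1):
        out[labels == old] = new
    return out


# ---------------------------------------------------------------------------
# Eigenproteins, kME, module merging
# ---------------------------------------------------------------------------

@dataclass
class ModuleSummary:
    """Eigenproteins (unit-norm first PCs), variance explained, and kME."""

    eigenprotein: pd.DataFrame            # samples x modules ("M1", "M2", ...)
    variance_explained: pd.Series
    labels: pd.Series                     # protein -> module int (0 = gray)
    kme: pd.DataFrame | None = None       # proteins x modules

    def module_members(self, module: str) -> list[str]:
        k = int(module.lstrip("M"))
        return list(self.labels.index[self.labels == k])


def _standardize_impute(X: np.ndarray) -> np.ndarray:
    """Row z-scores over observed values, residual NaN -> row median z-score."""
    Z = X.copy()
    for i in range(Z.shape[0]):
        obs = np.isfinite(Z[i])
        if obs.sum() < 2:
            Z[i] = 0.0
            continue
        mu = Z[i, obs].mean()
        sd = Z[i, obs].std(ddof=0)
        Z[i] = (Z[i] - mu) / sd if sd > 0 else 0.0
        if (~obs).any():
            Z[i, ~obs] = np.median(Z[i, obs])
    return Z


def compute_eigenproteins(m: AbundanceMatrix, labels) -> ModuleSummary:
    """First principal component of each module's standardized submatrix.

    Proteins are z-scored over their observed values, residual missingness is
    median-imputed, and the first right singular vector across samples is the
    Eigenprotein (unit norm).  Its sign is fixed so that it correlates
    positively with the module's mean standardized abundance.
    """
    labels = pd.Series(np.asarray(labels, dtype=int), index=m.values.index)
    module_ids = sorted(k for k in labels.unique() if k > 0)
    eig = {}
    varex = {}
    X = m.values.to_numpy(dtype=float)
    for k in module_ids:
        rows = np.flatnonzero(labels.to_numpy() == k)
        if rows.size < 2:
            raise ValueError(f"module M{k} has fewer than 2 proteins")
        Zk = _standardize_impute(X[rows])
        if np.isnan(Zk).any():
            warnings.warn(f"module M{k}: residual missing values imputed to 0")
            Zk = np.nan_to_num(Zk)
        U, S, Vt = np.linalg.svd(Zk, full_matrices=False)
        v = Vt[0]
        mean_profile = Zk.mean(axis=0)
        c = np.corrcoef(v, mean_profile)[0, 1] if mean_profile.std() > 0 else 1.0
        if c < 0:
            v = -v
        eig[f"M{k}"] = v
        varex[f"M{k}"] = float(S[0] ** 2 / np.sum(S ** 2))
    eigenprotein = pd.DataFrame(eig, index=m.values.columns)
    return ModuleSummary(
        eigenprotein=eigenprotein,
        variance_explained=pd.Series(varex),
        labels=labels,
    )


def compute_kme(m: AbundanceMatrix, summary: ModuleSummary, min_joint: int = 3) -> pd.DataFrame:
    """kME(p, module) = Pearson correlation of protein p with the module
    Eigenprotein over jointly observed samples (< ``min_joint`` -> NaN)."""
    X = m.values.to_numpy(dtype=float)
    M = np.isfinite(X)
    X0 = np.where(M, X, 0.0)
    out = {}
    for mod in summary.eigenprotein.columns:
        e = summary.eigenprotein[mod].to_numpy()
        n = M.sum(axis=1).astype(float)
        Sx = X0.sum(axis=1)
        Sxx = (X0 ** 2).sum(axis=1)
        Se = M @ e
        See = M @ (e ** 2)
        Sxe = X0 @ e
        with np.errstate(invalid="ignore", divide="ignore"):
            cov = Sxe - Sx * Se / n
            varx = Sxx - Sx ** 2 / n
            vare = See - Se ** 2 / n
            r = cov / np.sqrt(varx * vare)
        r[n < min_joint] = np.nan
        out[mod] = np.clip(r, -1.0, 1.0)
    kme = pd.DataFrame(out, index=m.values.index)
    summary.kme = kme
    return kme


def merge_close_modules(m: AbundanceMatrix, labels, cut_height: float = 0.2):
    """Iteratively merge module pairs whose Eigenprotein dissimilarity
    (1 - correlation) is below ``cut_height``, closest pair first,
    recomputing Eigenproteins after every merge."""
    labels = np.asarray(labels, dtype=int).copy()
    if not (labels > 0).any():
        return labels
    while True:
        summary = compute_eigenproteins(m, labels)
        cols = list(summary.eigenprotein.columns)
        if len(cols) < 2:
            break
        E = summary.eigenprotein.to_numpy()
        C = np.corrcoef(E.T)
        np.fill_diagonal(C, -np.inf)
        i, j = np.unravel_index(np.argmax(C), C.shape)
        if 1.0 - C[i, j] >= cut_height:
            break
        ki, kj = int(cols[i].lstrip("M")), int(cols[j].lstrip("M"))
        keep, drop = min(ki, kj), max(ki, kj)
        labels[labels == drop] = keep
    return _relabel_by_size(labels)


def reassign_by_kme(m: AbundanceMatrix, labels, threshold: float = 0.05):
    """Optional post-pass: relabel a protein whose kME to another module
    exceeds its own-module kME with two-sided p < ``threshold``."""
    from scipy import stats

    labels = np.asarray(labels, dtype=int).copy()
    summary = compute_eigenproteins(m, labels)
    kme = compute_kme(m, summary)
    n = m.n_samples
    for pi, p in enumerate(m.values.index):
        own = labels[pi]
        if own == 0:
            continue
        row = kme.loc[p]
        best = row.idxmax()
        best_k = int(best.lstrip("M"))
        if best_k == own or not np.isfinite(row[best]):
            continue
        if row[best] <= row.get(f"M{own}", -np.inf):
            continue
        r = row[best]
        t = r * np.sqrt((n - 2) / max(1e-12, 1 - r ** 2))
        p_val = 2 * stats.t.sf(abs(t), df=n - 2)
        if p_val < threshold:
            labels[pi] = best_k
    return _relabel_by_size(labels)


# ---------------------------------------------------------------------------
# end-to-end network model
# ---------------------------------------------------------------------------

@dataclass
class NetworkModel:
    cor: pd.DataFrame
    power_beta: int
    adjacency: np.ndarray
    tom: np.ndarray
    dendrogram: np.ndarray                 # scipy linkage matrix
    labels: pd.Series                      # protein -> module int
    diagnostics: SoftThresholdDiagnostics | None = None
    summary: ModuleSummary | None = None


def build_network(
    m: AbundanceMatrix,
    power: int = 10,
    auto_power: bool = False,
    max_p_outliers: float = 0.05,
    min_pairs: int = 10,
    deep_split: int = 4,
    min_module_size: int = 10,
    merge_cut_height: float = 0.2,
    pam_stage: bool = True,
    pam_respects_dendro: bool = True,
    apply_reassignment: bool = False,
    reassign_threshold: float = 0.05,
) -> NetworkModel:
    """Full network stage: bicor -> adjacency -> TOM -> modules -> summaries."""
    cor = bicor_matrix(m, max_p_outliers=max_p_outliers, min_pairs=min_pairs)
    diagnostics = None
    if auto_power:
        diagnostics = select_soft_threshold(cor.to_numpy())
        power = diagnostics.chosen_power
    adj = signed_adjacency(cor.to_numpy(), power)
    tom = topological_overlap(adj)
    Z, labels = cut_tree_dynamic(
        1.0 - tom, deep_split=deep_split, min_size=min_module_size,
        pam_stage=pam_stage, pam_respects_dendro=pam_respects_dendro,
    )
    labels = merge_close_modules(m, labels, cut_height=merge_cut_height)
    if apply_reassignment and (labels > 0).any():
        labels = reassign_by_kme(m, labels, threshold=reassign_threshold)
    labels = pd.Series(labels, index=m.values.index, name="module")
    summary = None
    if (labels > 0).any():
        summary = compute_eigenproteins(m, labels)
        compute_kme(m, summary)
    return NetworkModel(
        cor=cor, power_beta=int(power), adjacency=adj, tom=tom,
        dendrogram=Z, labels=labels, diagnostics=diagnostics, summary=summary,
    )
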