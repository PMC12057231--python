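"""Stage-trajectory modelling: loess fits of Eigenproteins and biomarkers
across ordered disease stages, z-scored to controls.

Stages are encoded ordinally and equidistantly (CTRL = 0, Braak I = 1, ...,
VI = 6; pooled levels at the midpoint of their members).  The smoother is a
tricube-weighted local polynomial (default degree 2, span 0.75) with
pointwise 95% confidence bands from the linear-smoother variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


def zscore_to_controls(values: pd.Series, control_mask: pd.Series) -> pd.Series:
    """z = (x - mean(controls)) / sd(controls), sd with n-1 denominator."""
    values = pd.to_numeric(values, errors="coerce")
    ctrl = control_mask.reindex(values.index).fillna(False).astype(bool)
    ref = values[ctrl].dropna()
    if len(ref) < 2:
        raise ValueError("need at least 2 controls with finite values")
    sd = ref.std(ddof=1)
    if sd == 0:
        raise ValueError("control SD is zero; z-scores undefined")
    return (values - ref.mean()) / sd


@dataclass
class TrajectoryFit:
    series_name: str
    stage_grid: pd.DataFrame      # columns: stage (code), position
    fitted: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    span: float
    degree: int
    n_per_stage: dict[str, int] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        out = self.stage_grid.copy()
        out["fitted"] = self.fitted
        out["ci_low"] = self.ci_low
        out["ci_high"] = self.ci_high
        out["series"] = self.series_name
        return out


def _loess_smoother_row(x: np.ndarray, x0: float, span: float, degree: int) -> np.ndarray:
    """Row of the linear smoother: weights such that fit(x0) = row @ y."""
    n = x.size
    k = max(int(np.ceil(min(span, 1.0) * n)), degree + 2)
    k = min(k, n)
    d = np.abs(x - x0)
    order = np.argsort(d, kind="stable")
    # ordinal positions are heavily tied: the farthest included position gets
    # zero tricube weight, so grow the window until at least degree + 2
    # distinct positions are inside (keeping the local polynomial well-posed)
    while k < n and np.unique(x[order[:k]]).size < degree + 2:
        k += 1
    idx = order[:k]
    if np.unique(x[idx]).size < degree + 2:
        raise ValueError(
            f"need at least degree + 2 = {degree + 2} distinct positions "
            "in the data for a stable local fit; increase span or reduce degree"
        )
    dmax = d[idx].max()
    if dmax == 0:
        dmax = 1.0
    if span > 1.0:
        # R loess convention: bandwidth inflated by the span beyond the data
        # range, so span -> inf approaches the global polynomial fit
        dmax *= span
    w = np.zeros(n)
    w[idx] = (1.0 - np.minimum(d[idx] / dmax, 1.0) ** 3) ** 3
    P = np.vander(x, N=degree + 1, increasing=True)
    p0 = np.vander(np.array([x0]), N=degree + 1, increasing=True)[0]
    W = w[:, None]
    A = P.T @ (W * P)
    row = p0 @ np.linalg.solve(A, (W * P).T)
    return row


def loess_fit(
    stage_positions: pd.Series,
    values: pd.Series,
    span: float = 0.75,
    degree: int = 2,
    eval_positions: pd.DataFrame | None = None,
    level: float = 0.95,
    series_name: str = "series",
) -> TrajectoryFit:
    """Tricube-weighted local polynomial fit over ordinal stage positions.

    ``stage_positions`` maps each sample to its numeric stage code; the fit is
    evaluated at the distinct observed positions (no extrapolation).
    Pointwise CIs use the linear-smoother variance with residual degrees of
    freedom n - tr(L).
    """
    df = pd.DataFrame({"x": pd.to_numeric(stage_positions, errors="coerce"),
                       "y": pd.to_numeric(values, errors="coerce")}).dropna()
    x, y = df["x"].to_numpy(), df["y"].to_numpy()
    if np.unique(x).size < degree + 2:
        raise ValueError(f"need at least degree + 2 = {degree + 2} distinct positions")
    if eval_positions is None:
        uniq = np.unique(x)
        eval_positions = pd.DataFrame({"stage": [str(u) for u in uniq], "position": uniq})
    grid = eval_positions["position"].to_numpy(dtype=float)

    L_grid = np.vstack([_loess_smoother_row(x, x0, span, degree) for x0 in grid])
    fitted = L_grid @ y
    # residual variance from the smoother evaluated at the data points
    # (rows are shared across samples at the same ordinal position)
    uniq = np.unique(x)
    row_of = {xi: _loess_smoother_row(x, xi, span, degree) for xi in uniq}
    resid = y - np.array([row_of[xi] @ y for xi in x])
    trace = float(np.sum([row_of[xi][i] for i, xi in enumerate(x)]))
    df_resid = max(len(y) - trace, 1.0)
    sigma2 = float(resid @ resid) / df_resid
    se = np.sqrt(sigma2 * (L_grid ** 2).sum(axis=1))
    tq = stats.t.ppf(0.5 + level / 2.0, df=df_resid)
    n_per = df.groupby("x").size()
    return TrajectoryFit(
        series_name=series_name,
        stage_grid=eval_positions.reset_index(drop=True),
        fitted=fitted,
        ci_low=fitted - tq * se,
        ci_high=fitted + tq * se,
        span=span,
        degree=degree,
        n_per_stage={str(k): int(v) for k, v in n_per.items()},
    )


def summarize_trajectories(
    fits: list[TrajectoryFit],
    offset_step: float = 0.5,
) -> pd.DataFrame:
    """Align loess fits on a common grid for a summary display.

    Every series is z-scored over the grid and shifted vertically by a
    recorded offset for comparability; stages where the discrete derivative
    changes sign are flagged as candidate inflection points.  Un-shifting
    (display - offset) reproduces the z-scored fits exactly.
    """
    if not fits:
        raise ValueError("no fits given")
    grid0 = fits[0].stage_grid["position"].to_numpy()
    for f in fits[1:]:
        if not np.array_equal(f.stage_grid["position"].to_numpy(), grid0):
            raise ValueError("fits must share a common stage grid")
    rows = []
    for i, f in enumerate(fits):
        z = (f.fitted - f.fitted.mean()) / (f.fitted.std(ddof=0) or 1.0)
        offset = i * offset_step
        d = np.diff(z)
        sign_change = np.zeros(len(z), dtype=bool)
        for j in range(1, len(d)):
            if d[j - 1] != 0 and d[j] != 0 and np.sign(d[j]) != np.sign(d[j - 1]):
                sign_change[j] = True
        for j in range(len(z)):
            rows.append({
                "series": f.series_name,
                "stage": f.stage_grid["stage"].iloc[j],
                "position": grid0[j],
                "z_fitted": z[j],
                "offset": offset,
                "display": z[j] + offset,
                "inflection": bool(sign_change[j]),
            })
    return pd.DataFrame(rows)
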