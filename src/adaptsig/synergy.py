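"""Bliss-independence synergy and rank-correlation biomarker screens.

For two drugs X and Y with single-agent activity fractions I_X and I_Y
(apoptotic fraction by default; 1 - relative viability via config), the
Bliss independence null model predicts the combined activity::

    I_XY = I_X + I_Y - I_X * I_Y

and the excess over Bliss independence (EOBI = observed - predicted) scores
synergy per dose pair. The biomarker screen ranks candidate signaling
read-outs by the Spearman correlation between their (z-scored) dose-response
AUCs and the viability AUCs across cell line/drug pairs; partial Spearman
correlations quantify how much of a biomarker's predictivity survives
controlling for a second read-out (e.g., pS6 given pERK).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "bliss_predict",
    "eobi_grid",
    "SynergyGrid",
    "spearman",
    "partial_from_rhos",
    "partial_spearman",
    "biomarker_screen",
    "CorrelationResult",
]


def bliss_predict(i_x, i_y):
    """Bliss independence prediction ``I_X + I_Y - I_X * I_Y`` (vectorized)."""
    ix = np.asarray(i_x, dtype=float)
    iy = np.asarray(i_y, dtype=float)
    if ((ix < 0) | (ix > 1)).any() or ((iy < 0) | (iy > 1)).any():
        raise ValueError("activities must lie in [0, 1]")
    out = ix + iy - ix * iy
    return out if out.ndim else float(out)


@dataclass
class SynergyGrid:
    """Single-agent and combination activities with per-pair Bliss excess."""

    doses_x: np.ndarray
    doses_y: np.ndarray
    i_x: np.ndarray          # single-agent activity at each dose of X
    i_y: np.ndarray
    i_obs: np.ndarray        # observed combination activity, len(x) x len(y)
    i_pred: np.ndarray
    eobi: np.ndarray

    @property
    def max_eobi(self) -> float:
        return float(self.eobi.max())

    @property
    def mean_eobi(self) -> float:
        return float(self.eobi.mean())

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for i, cx in enumerate(self.doses_x):
            for j, cy in enumerate(self.doses_y):
                recs.append((cx, cy, self.i_x[i], self.i_y[j],
                             self.i_obs[i, j], self.i_pred[i, j],
                             self.eobi[i, j]))
        return pd.DataFrame(recs, columns=[
            "dose_x", "dose_y", "activity_x", "activity_y",
            "activity_obs", "activity_pred", "eobi"])


def eobi_grid(doses_x, doses_y, i_x, i_y, i_obs) -> SynergyGrid:
    """Excess over Bliss independence per dose pair.

    ``i_obs`` must be shaped (len(doses_x), len(doses_y)); matched-ratio
    (1:1) designs can pass the diagonal of a square grid afterwards.
    """
    dx = np.asarray(doses_x, dtype=float)
    dy = np.asarray(doses_y, dtype=float)
    ix = np.asarray(i_x, dtype=float)
    iy = np.asarray(i_y, dtype=float)
    obs = np.asarray(i_obs, dtype=float)
    if ix.shape != dx.shape or iy.shape != dy.shape:
        raise ValueError("single-agent activities must match dose grids")
    if obs.shape != (dx.size, dy.size):
        raise ValueError(
            f"observed grid shape {obs.shape} != {(dx.size, dy.size)}")
    if ((obs < 0) | (obs > 1)).any():
        raise ValueError("observed activities must lie in [0, 1]")
    pred = bliss_predict(ix[:, None], iy[None, :])
    return SynergyGrid(doses_x=dx, doses_y=dy, i_x=ix, i_y=iy,
                       i_obs=obs, i_pred=pred, eobi=obs - pred)


def eobi_from_table(table: pd.DataFrame) -> SynergyGrid:
    """Build a SynergyGrid from the long-format combination activity table."""
    dx = np.sort(table["dose_x"].unique())
    dy = np.sort(table["dose_y"].unique())
    ix = (table.groupby("dose_x")["activity_x"].first().reindex(dx)
          .to_numpy())
    iy = (table.groupby("dose_y")["activity_y"].first().reindex(dy)
          .to_numpy())
    obs = (table.pivot_table(index="dose_x", columns="dose_y",
                             values="activity_obs")
           .reindex(index=dx, columns=dy).to_numpy())
    if np.isnan(obs).any():
        raise ValueError("combination table does not cover the full grid")
    return eobi_grid(dx, dy, ix, iy, obs)


@dataclass
class CorrelationResult:
    """Spearman (optionally partial) correlation with significance."""

    rho: float
    p_value: float
    n: int
    rho_partial: float | None = None
    undefined: bool = False
    label: str | None = None


def spearman(x, y) -> CorrelationResult:
    """Spearman rank correlation (average ranks, Pearson on ranks).

    The p-value uses the standard large-sample t approximation. Constant
    input yields an undefined correlation, flagged rather than raised.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(rho=np.nan, p_value=np.nan, n=x.size,
                                 undefined=True)
    rho, p = stats.spearmanr(x, y)
    return CorrelationResult(rho=float(rho), p_value=float(p), n=int(x.size))


def partial_from_rhos(rho_xy: float, rho_xz: float, rho_yz: float) -> float:
    """First-order partial correlation from three pairwise coefficients."""
    denom = (1 - rho_xz ** 2) * (1 - rho_yz ** 2)
    if denom <= 0:
        raise ValueError("partial correlation undefined: perfect "
                         "correlation with the control variable")
    rp = (rho_xy - rho_xz * rho_yz) / np.sqrt(denom)
    return float(np.clip(rp, -1.0, 1.0))


def partial_spearman(x, y, z) -> CorrelationResult:
    """Spearman correlation of x and y controlling for z.

    Uses the first-order recursion on the pairwise Spearman coefficients::

        rho_xy.z = (rho_xy - rho_xz rho_yz)
                   / sqrt((1 - rho_xz^2)(1 - rho_yz^2))

    with a t-approximate p-value on n - 3 degrees of freedom. Perfect
    correlation with the control renders the coefficient undefined (flagged).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    if not (x.size == y.size == z.size):
        raise ValueError("x, y, z must have equal length")
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 observations")
    r_xy = spearman(x, y)
    r_xz = spearman(x, z)
    r_yz = spearman(y, z)
    if r_xy.undefined or r_xz.undefined or r_yz.undefined:
        return CorrelationResult(rho=r_xy.rho, p_value=np.nan, n=n,
                                 rho_partial=np.nan, undefined=True)
    try:
        rp = partial_from_rhos(r_xy.rho, r_xz.rho, r_yz.rho)
    except ValueError:
        return CorrelationResult(rho=r_xy.rho, p_value=np.nan, n=n,
                                 rho_partial=np.nan, undefined=True)
    df = n - 3
    if abs(rp) >= 1.0:
        p = 0.0
    else:
        tstat = rp * np.sqrt(df / (1 - rp ** 2))
        p = float(2 * stats.t.sf(abs(tstat), df))
    return CorrelationResult(rho=float(r_xy.rho), p_value=p, n=n,
                             rho_partial=rp)


def biomarker_screen(signal_aucs: pd.DataFrame, viability_aucs: pd.Series,
                     exclude_cell_lines=None) -> pd.DataFrame:
    """Rank candidate biomarkers by Spearman correlation with viability.

    ``signal_aucs`` has one row per (cell line, drug) pair and one column per
    candidate biomarker (z-scored dose-response AUCs of the signal change);
    ``viability_aucs`` is aligned on the same index. Rows whose cell line is
    in ``exclude_cell_lines`` are dropped first (with the reduced n
    reported), reproducing exclusion analyses of strongly adapting lines.
    Spearman correlation is rank-based, so prior z-scoring does not change
    rho; it is accepted as-is. Biomarkers with fewer than 3 usable pairs are
    skipped with a warning.
    """
    X = signal_aucs.copy()
    y = viability_aucs.reindex(X.index)
    if exclude_cell_lines:
        excl = set(exclude_cell_lines)
        if isinstance(X.index, pd.MultiIndex):
            keep = ~X.index.get_level_values(0).isin(excl)
        else:
            keep = ~X.index.isin(excl)
        X, y = X.loc[keep], y.loc[keep]
    rows = []
    for name in X.columns:
        pair = pd.concat([X[name], y], axis=1).dropna()
        if len(pair) < 3:
            warnings.warn(f"biomarker {name!r} skipped: fewer than 3 pairs",
                          RuntimeWarning)
            continue
        res = spearman(pair.iloc[:, 0], pair.iloc[:, 1])
        rows.append({"biomarker": name, "rho": res.rho,
                     "p_value": res.p_value, "n": res.n,
                     "undefined": res.undefined})
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    out["abs_rho"] = out["rho"].abs()
    out = (out.sort_values("abs_rho", ascending=False)
           .drop(columns="abs_rho").reset_index(drop=True))
    out.index = pd.RangeIndex(1, len(out) + 1, name="rank")
    return out
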