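"""Two-marker single-cell gating into High/Low quadrants.

Drug-induced shifts between proliferative and quiescent subpopulations are
quantified by thresholding single-cell marker intensities (e.g., p-cJun vs
pRb) into High/Low states. Thresholds are fitted reproducibly -- a
two-component Gaussian mixture on log intensities with the threshold at the
equal-posterior point between the components -- rather than drawn by eye;
a manual-threshold override is available for parity checks. Gates should be
fitted on vehicle-control cells and applied unchanged to all conditions of
the same cell line and marker, so drug-induced shifts are measured against a
fixed reference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

__all__ = [
    "GateFit",
    "GateResult",
    "fit_gate",
    "quadrant_fractions",
    "population_shift",
]


@dataclass
class GateFit:
    """Mixture-based High/Low gate on log intensities."""

    threshold: float
    means: tuple[float, float]       # (low, high)
    sds: tuple[float, float]
    weights: tuple[float, float]
    degenerate: bool
    n_cells: int

    @property
    def high_weight(self) -> float:
        return self.weights[1]


def _equal_posterior_threshold(m: np.ndarray, s: np.ndarray,
                               w: np.ndarray) -> float:
    """Root of w0 N(x|m0,s0) = w1 N(x|m1,s1) between the two means."""
    a = 1.0 / (2 * s[0] ** 2) - 1.0 / (2 * s[1] ** 2)
    b = m[1] / (s[1] ** 2) - m[0] / (s[0] ** 2)
    c = (m[0] ** 2 / (2 * s[0] ** 2) - m[1] ** 2 / (2 * s[1] ** 2)
         + np.log(w[0] * s[1]) - np.log(w[1] * s[0]))
    if abs(a) < 1e-12:  # equal variances: linear equation
        return float(-c / b) if abs(b) > 1e-12 else float(m.mean())
    roots = np.roots([a, b, c])
    roots = roots[np.isreal(roots)].real
    inside = roots[(roots > m[0]) & (roots < m[1])]
    if inside.size:
        return float(inside[0])
    return float(m.mean())


def fit_gate(log_intensities, random_state: int = 0,
             min_weight: float = 0.02) -> GateFit:
    """Fit a two-component Gaussian mixture gate on log intensities.

    The threshold sits where the posterior probabilities of the two
    components are equal. Fits judged unimodal -- the one-component model has
    the better BIC, or one component collapses below ``min_weight`` -- are
    flagged degenerate with the threshold at +inf (all cells Low) and a
    warning, so downstream code never silently gates noise.
    """
    x = np.asarray(log_intensities, dtype=float).ravel()
    x = x[np.isfinite(x)]
    if np.unique(x).size < 2:
        raise ValueError("gate fitting requires >= 2 distinct values")
    if x.size < 100:
        warnings.warn(f"only {x.size} cells; gate estimate will be noisy",
                      RuntimeWarning)
    X = x.reshape(-1, 1)
    gm2 = GaussianMixture(n_components=2, n_init=5,
                          random_state=random_state).fit(X)
    gm1 = GaussianMixture(n_components=1,
                          random_state=random_state).fit(X)
    order = np.argsort(gm2.means_.ravel())
    m = gm2.means_.ravel()[order]
    s = np.sqrt(gm2.covariances_.ravel()[order])
    w = gm2.weights_[order]
    degenerate = (gm1.bic(X) <= gm2.bic(X)) or (w.min() < min_weight)
    if degenerate:
        warnings.warn("unimodal intensity distribution; gate degenerate "
                      "(threshold = +inf, all cells Low)", RuntimeWarning)
        thr = np.inf
    else:
        thr = _equal_posterior_threshold(m, s, w)
    return GateFit(threshold=float(thr), means=(float(m[0]), float(m[1])),
                   sds=(float(s[0]), float(s[1])),
                   weights=(float(w[0]), float(w[1])),
                   degenerate=bool(degenerate), n_cells=int(x.size))


@dataclass
class GateResult:
    """Quadrant fractions of cells gated on two markers."""

    markers: tuple[str, str]
    thresholds: dict
    fractions: dict               # (level_m1, level_m2) -> fraction
    n_cells: int
    n_excluded: int
    method: str = "gaussian-mixture equal-posterior"

    def fraction(self, level_1: str, level_2: str) -> float:
        return self.fractions[(level_1, level_2)]


QUADRANTS = (("High", "High"), ("High", "Low"), ("Low", "High"),
             ("Low", "Low"))


def quadrant_fractions(cells: pd.DataFrame, thresholds: dict,
                       markers: tuple[str, str] | None = None) -> GateResult:
    """Assign each cell to a High/Low quadrant by strict > threshold.

    ``cells`` is a wide table with one log-intensity column per marker;
    ``thresholds`` maps marker -> gate threshold (on the same scale). Cells
    with a missing value in either marker are excluded and counted.
    """
    if markers is None:
        markers = tuple(k for k in thresholds if k in cells.columns)
    if len(markers) != 2:
        raise ValueError("exactly two markers required")
    m1, m2 = markers
    for m in markers:
        if m not in cells.columns:
            raise ValueError(f"marker {m!r} missing from cell table")
        if m not in thresholds:
            raise ValueError(f"no threshold for marker {m!r}")
    sub = cells[[m1, m2]]
    ok = sub.notna().all(axis=1)
    n_excluded = int((~ok).sum())
    sub = sub[ok]
    n = len(sub)
    if n == 0:
        raise ValueError("no cells with both markers present")
    hi1 = sub[m1].to_numpy() > thresholds[m1]
    hi2 = sub[m2].to_numpy() > thresholds[m2]
    counts = {
        ("High", "High"): int(np.sum(hi1 & hi2)),
        ("High", "Low"): int(np.sum(hi1 & ~hi2)),
        ("Low", "High"): int(np.sum(~hi1 & hi2)),
        ("Low", "Low"): int(np.sum(~hi1 & ~hi2)),
    }
    fractions = {k: v / n for k, v in counts.items()}
    return GateResult(markers=(m1, m2),
                      thresholds={m1: thresholds[m1], m2: thresholds[m2]},
                      fractions=fractions, n_cells=n, n_excluded=n_excluded)


def population_shift(before: GateResult, after: GateResult) -> pd.DataFrame:
    """Per-quadrant fold changes and differences between two conditions.

    A fourfold depletion of a proliferative (pRb-High / p-cJun-High)
    quadrant, say 35% -> 9%, appears as fold_change ~ 0.26. Empty-before
    quadrants yield an undefined fold change, flagged not raised.
    """
    if before.markers != after.markers:
        raise ValueError("gate results use different markers")
    if before.thresholds != after.thresholds:
        raise ValueError("gate results use different thresholds; refit on a "
                         "common control reference")
    rows = []
    for quad in QUADRANTS:
        b = before.fractions[quad]
        a = after.fractions[quad]
        undefined = b == 0
        rows.append({
            "quadrant": f"{before.markers[0]}-{quad[0]}/"
                        f"{before.markers[1]}-{quad[1]}",
            "before": b, "after": a,
            "fold_change": (a / b) if not undefined else np.nan,
            "difference": a - b,
            "undefined": undefined,
        })
    return pd.DataFrame(rows).set_index("quadrant")
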