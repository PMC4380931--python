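"""Single-response partial least squares regression (NIPALS) with CV metrics.

Implements the latent-variable regression at the center of the pipeline as a
statsmodels-style Model/Results pair. The NIPALS algorithm is used (rather
than SIMPLS) because the downstream VIP formula consumes the per-component
predictor weights ``w_nk`` directly, and NIPALS defines them unambiguously;
for a single response the two algorithms give identical predictions.

Per component ``n`` (on centered/scaled data, deflating both blocks)::

    w_n = E' f / ||E' f||        (unit-norm weights)
    t_n = E w_n                  (scores)
    p_n = E' t_n / t_n' t_n      (predictor loadings)
    q_n = f' t_n / t_n' t_n      (response loading)
    E <- E - t_n p_n',  f <- f - q_n t_n

``SS_n = q_n^2 t_n' t_n`` is the response sum of squares explained by
component ``n``; the coefficient vector on scaled predictors is
``B = W (P'W)^{-1} q``. Each weight column's largest-magnitude element is
made positive so results reproduce across platforms.

Model quality is reported as in-sample ``R^2``, cross-validated ``Q^2 =
1 - PRESS/TSS`` under a seeded tenfold partition (centering and scaling are
re-estimated inside each training split, so no information leaks from held-out
rows), and MSPE expressed as a percent of the response variance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["PLSRModel", "PLSRResults", "CVResult"]


def _scale_columns(A: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = A.mean(axis=0)
    sd = A.std(axis=0, ddof=1)
    safe = np.where(sd < 1e-12, 1.0, sd)
    return (A - mean) / safe, mean, sd


class PLSRModel:
    """PLSR of a single response on a predictor block.

    Parameters
    ----------
    endog : array-like, shape (n,)
        Response (e.g., non-apoptotic viability per condition).
    exog : array-like or DataFrame, shape (n, K)
        Predictor matrix (e.g., z-scored log2 fold changes per condition and
        signal x time variable). Internally re-centered and unit-variance
        scaled; scaling parameters are stored on the results.
    """

    def __init__(self, endog, exog, var_names=None, scale: bool = True):
        if isinstance(exog, pd.DataFrame):
            if var_names is None:
                var_names = list(exog.columns)
            exog = exog.to_numpy(dtype=float)
        if isinstance(endog, (pd.Series, pd.DataFrame)):
            endog = np.asarray(endog, dtype=float).ravel()
        self.endog = np.asarray(endog, dtype=float).ravel()
        self.exog = np.asarray(exog, dtype=float)
        if self.exog.ndim != 2:
            raise ValueError("exog must be 2-D")
        if self.exog.shape[0] != self.endog.size:
            raise ValueError("endog length must match exog rows")
        self.var_names = (list(var_names) if var_names is not None
                          else [f"x{k}" for k in range(self.exog.shape[1])])
        self.scale = scale
        if np.std(self.endog) < 1e-14:
            raise ValueError("zero response variance")

    @classmethod
    def from_design(cls, design, response: pd.Series) -> "PLSRModel":
        """Build from a DesignMatrix and a (drug, dose)-keyed response."""
        y = response.reindex(design.values.index)
        if y.isna().any():
            raise ValueError("response rows do not match the design matrix")
        return cls(y, design.values)

    @property
    def nobs(self) -> int:
        return self.endog.size

    @property
    def k_vars(self) -> int:
        return self.exog.shape[1]

    def fit(self, n_components: int) -> "PLSRResults":
        """Fit by NIPALS with deflation of both blocks."""
        if n_components < 1:
            raise ValueError("n_components must be >= 1")
        if n_components > min(self.nobs - 1, self.k_vars):
            raise ValueError(
                f"n_components={n_components} exceeds min(rows-1, columns)="
                f"{min(self.nobs - 1, self.k_vars)}")

        X, y = self.exog, self.endog
        if self.scale:
            Xs, xm, xs = _scale_columns(X)
            ym, ysd = y.mean(), y.std(ddof=1)
            ys = (y - ym) / ysd
        else:
            Xs, xm, xs = X - X.mean(axis=0), X.mean(axis=0), np.ones(X.shape[1])
            ym, ysd = y.mean(), 1.0
            ys = y - ym

        E, f = Xs.copy(), ys.copy()
        W, P, T, q, ss = [], [], [], [], []
        for n in range(n_components):
            w = E.T @ f
            nw = np.linalg.norm(w)
            if nw < 1e-12:
                warnings.warn(
                    f"rank exhausted after {n} components; truncating",
                    RuntimeWarning)
                break
            w = w / nw
            imax = int(np.argmax(np.abs(w)))
            if w[imax] < 0:
                w = -w
            t = E @ w
            tt = float(t @ t)
            if tt < 1e-12:
                warnings.warn(
                    f"degenerate score at component {n + 1}; truncating",
                    RuntimeWarning)
                break
            p = E.T @ t / tt
            qn = float(f @ t) / tt
            E = E - np.outer(t, p)
            f = f - qn * t
            W.append(w)
            P.append(p)
            T.append(t)
            q.append(qn)
            ss.append(qn ** 2 * tt)

        if not W:
            raise ValueError("no informative PLSR component could be "
                             "extracted (response orthogonal to predictors)")
        W = np.column_stack(W)
        P = np.column_stack(P)
        T = np.column_stack(T)
        q = np.asarray(q)
        ss = np.asarray(ss)
        B = W @ np.linalg.solve(P.T @ W, q)
        tss = float(ys @ ys)
        return PLSRResults(
            model=self, n_components=W.shape[1], weights=W, x_loadings=P,
            scores=T, y_loadings=q, coef=B, ss=ss, tss=tss,
            x_mean=xm, x_sd=xs, y_mean=ym, y_sd=ysd)

    def cross_validate(self, n_components: int, n_folds: int = 10,
                       seed: int = 0) -> "CVResult":
        """Seeded k-fold cross-validation; scaling re-estimated per fold.

        Q^2 = 1 - PRESS/TSS on the original response scale; MSPE =
        (PRESS / n) as a percent of the response variance (ddof=1).
        """
        n = self.nobs
        if n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if n < n_folds:
            raise ValueError("more folds than observations")
        rng = np.random.default_rng(seed)
        perm = rng.permutation(n)
        folds = np.array_split(perm, n_folds)
        assignment = np.empty(n, dtype=int)
        preds = np.full(n, np.nan)
        for k, idx in enumerate(folds):
            if idx.size < 1:
                raise ValueError("empty cross-validation fold")
            assignment[idx] = k
            tr = np.setdiff1d(perm, idx)
            ncomp = min(n_components, tr.size - 1, self.k_vars)
            sub = PLSRModel(self.endog[tr], self.exog[tr],
                            var_names=self.var_names, scale=self.scale)
            res = sub.fit(ncomp)
            preds[idx] = res.predict(self.exog[idx])
        press = float(np.sum((self.endog - preds) ** 2))
        tss = float(np.sum((self.endog - self.endog.mean()) ** 2))
        q2 = 1.0 - press / tss
        mspe = 100.0 * (press / n) / np.var(self.endog, ddof=1)
        r2 = self.fit(min(n_components, self.nobs - 1, self.k_vars)).r2
        return CVResult(q2=q2, mspe=mspe, r2=r2,
                        per_fold_predictions=preds,
                        fold_assignment=assignment, seed=seed,
                        n_components=n_components, n_folds=n_folds)

    def select_ncomp(self, max_components: int, n_folds: int = 10,
                     seed: int = 0, tol: float = 0.01
                     ) -> tuple[int, pd.DataFrame]:
        """Smallest component count whose Q^2 is within ``tol`` of the best.

        Emulates adding components until prediction stops improving relative
        to noise. Returns (chosen N, metric trace over 1..max_components).
        """
        if max_components < 1:
            raise ValueError("max_components must be >= 1")
        rows = []
        for ncomp in range(1, max_components + 1):
            cv = self.cross_validate(ncomp, n_folds=n_folds, seed=seed)
            rows.append({"n_components": ncomp, "Q2": cv.q2,
                         "MSPE_percent": cv.mspe, "R2": cv.r2})
        trace = pd.DataFrame(rows)
        best = trace["Q2"].max()
        chosen = int(trace.loc[trace["Q2"] >= best - tol,
                               "n_components"].iloc[0])
        return chosen, trace


@dataclass
class PLSRResults:
    """Fitted PLSR: weights, loadings, scores, and explained sums of squares.

    ``ss[n]`` is the response sum of squares (scaled units) explained by
    component n; ``sum(ss) / tss`` is the in-sample R^2. ``coef`` acts on
    z-scored predictors; ``predict`` handles the scaling round trip.
    """

    model: PLSRModel
    n_components: int
    weights: np.ndarray        # K x N, unit-norm columns
    x_loadings: np.ndarray     # K x N
    scores: np.ndarray         # n x N, mutually orthogonal
    y_loadings: np.ndarray     # N
    coef: np.ndarray           # K, on scaled predictors
    ss: np.ndarray             # N, explained response SS
    tss: float
    x_mean: np.ndarray
    x_sd: np.ndarray
    y_mean: float
    y_sd: float
    _vip_cache: np.ndarray | None = field(default=None, repr=False)

    @property
    def r2(self) -> float:
        return float(self.ss.sum() / self.tss)

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.y_mean + self.y_sd * (self.scores @ self.y_loadings)

    @property
    def resid(self) -> np.ndarray:
        return self.model.endog - self.fittedvalues

    def predict(self, exog) -> np.ndarray:
        if isinstance(exog, pd.DataFrame):
            exog = exog.to_numpy(dtype=float)
        X = np.atleast_2d(np.asarray(exog, dtype=float))
        safe = np.where(self.x_sd < 1e-12, 1.0, self.x_sd)
        Xs = (X - self.x_mean) / safe
        return self.y_mean + self.y_sd * (Xs @ self.coef)

    def vip(self) -> pd.Series:
        """Variable importance in the projection for every predictor."""
        from adaptsig.vip import compute_vip
        return pd.Series(compute_vip(self.weights, self.ss),
                         index=self.model.var_names, name="vip")

    def variance_explained(self) -> pd.DataFrame:
        """Per-component explained response SS and cumulative R^2."""
        cum = np.cumsum(self.ss) / self.tss
        return pd.DataFrame({
            "component": np.arange(1, self.n_components + 1),
            "SS_n": self.ss,
            "fraction": self.ss / self.tss,
            "cumulative_R2": cum,
        })

    def summary(self) -> str:
        lines = [
            "PLSR Results",
            "=" * 46,
            f"No. observations: {self.model.nobs:>6}",
            f"No. predictors:   {self.model.k_vars:>6}",
            f"Components:       {self.n_components:>6}",
            f"R-squared:        {self.r2:>10.4f}",
            "-" * 46,
            f"{'comp':>4} {'SS_n':>12} {'frac':>8} {'cum R2':>8}",
        ]
        for _, row in self.variance_explained().iterrows():
            lines.append(f"{int(row['component']):>4} {row['SS_n']:>12.4f} "
                         f"{row['fraction']:>8.4f} {row['cumulative_R2']:>8.4f}")
        top = self.vip().sort_values(ascending=False).head(5)
        lines.append("-" * 46)
        lines.append("Top VIP variables:")
        for name, v in top.items():
            lines.append(f"  {str(name):<30} {v:>8.3f}")
        return "\n".join(lines)

    def plot_scores(self, components=(0, 1), ax=None):
        """Scatter the condition scores on two latent components."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        i, j = components
        ax.scatter(self.scores[:, i], self.scores[:, j],
                   c=self.model.endog, cmap="viridis")
        ax.set_xlabel(f"component {i + 1} score")
        ax.set_ylabel(f"component {j + 1} score")
        return ax

    def to_csv(self, out_dir) -> None:
        """Export T, P, W, q, SS_n and scaling parameters as plain CSV."""
        from pathlib import Path
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        names = self.model.var_names
        comp = [f"c{n + 1}" for n in range(self.n_components)]
        pd.DataFrame(self.weights, index=names, columns=comp).to_csv(
            out / "weights.csv")
        pd.DataFrame(self.x_loadings, index=names, columns=comp).to_csv(
            out / "x_loadings.csv")
        pd.DataFrame(self.scores, columns=comp).to_csv(
            out / "scores.csv", index=False)
        pd.DataFrame({"component": comp, "q": self.y_loadings,
                      "SS_n": self.ss}).to_csv(
            out / "components.csv", index=False)
        pd.DataFrame({"mean": self.x_mean, "sd": self.x_sd},
                     index=names).to_csv(out / "x_scaling.csv")


@dataclass
class CVResult:
    """Cross-validation metrics for one component count."""

    q2: float
    mspe: float                # percent of response variance
    r2: float
    per_fold_predictions: np.ndarray
    fold_assignment: np.ndarray
    seed: int
    n_components: int
    n_folds: int
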