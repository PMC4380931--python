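"""Phenotype response construction and dose-response summaries.

From per-condition cell counts (total and apoptotic nuclei) the module
builds the single response variable the PLSR models predict -- non-apoptotic
viability relative to vehicle, averaged over the 48 h and 72 h read-outs --
and summarizes dose-response behavior per drug:

* a four-parameter Hill fit ``v(d) = E_inf + (1 - E_inf) / (1 + (d/EC50)^h)``
  on log10 dose (statsmodels-style Model/Results pair);
* IC50 as the absolute 50%-viability crossing of the fitted curve (distinct
  from the half-maximal-effect EC50), reported absent when the curve never
  reaches 0.5 within 100x the tested dose range;
* Emax as the fractional effect at the top tested dose, ``1 - v(top)``;
* normalized AUC over log10 dose, and the relative-resistance score
  averaging the 48 h and 72 h AUCs (1 = fully unresponsive, 0 = complete
  killing at all doses);
* the sensitivity rule ``log10(IC50 [M]) < -6.5`` (strict).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "nonapoptotic_viability",
    "raw_phenotype_matrix",
    "assemble_response",
    "DoseResponseModel",
    "DoseResponseResults",
    "classify_sensitivity",
    "resistance_auc",
]

CONTROL_LABEL = "DMSO"


def nonapoptotic_viability(records: pd.DataFrame,
                           control_drug: str = CONTROL_LABEL) -> pd.DataFrame:
    """Non-apoptotic viability relative to vehicle, per condition and time.

    value = mean over replicates of (total - apoptotic), normalized to the
    mean non-apoptotic count of the time-matched vehicle control of the same
    cell line. The vehicle condition itself maps to 1 exactly.
    """
    df = records.copy()
    if ((df["apoptotic_cells"] < 0)
            | (df["apoptotic_cells"] > df["total_cells"])).any():
        raise ValueError("apoptotic_cells must lie in [0, total_cells]")
    df["alive"] = df["total_cells"] - df["apoptotic_cells"]
    mean_alive = (df.groupby(["cell_line", "drug", "dose", "time"],
                             sort=False)["alive"].mean().reset_index())
    is_ctrl = ((mean_alive["drug"] == control_drug)
               | (mean_alive["dose"] == 0))
    ctrl = (mean_alive[is_ctrl]
            .set_index(["cell_line", "time"])["alive"])
    if ctrl.index.has_duplicates:
        ctrl = ctrl.groupby(level=[0, 1]).mean()
    if (ctrl <= 0).any():
        raise ValueError("vehicle control has zero mean non-apoptotic count")
    key = pd.MultiIndex.from_frame(mean_alive[["cell_line", "time"]])
    if (~key.isin(ctrl.index)).any():
        raise ValueError("missing time-matched vehicle control")
    mean_alive["viability"] = mean_alive["alive"] / ctrl.reindex(key).to_numpy()
    mean_alive.loc[is_ctrl, "viability"] = 1.0
    return mean_alive[["cell_line", "drug", "dose", "time", "viability"]]


def raw_phenotype_matrix(records: pd.DataFrame, cell_line: str,
                         control_drug: str = CONTROL_LABEL) -> pd.DataFrame:
    """Condition x (measure, time) block before collapsing to one response.

    Rows are the treated (drug, dose) conditions ordered by drug and
    descending dose; columns pair relative viability and apoptotic fraction
    at each phenotype time point (with the default three times: a 6-column
    block; 35 x 6 for the dense 5-drug x 7-dose design).
    """
    sub = records[records["cell_line"] == cell_line]
    if sub.empty:
        raise ValueError(f"no records for cell line {cell_line!r}")
    viab = nonapoptotic_viability(sub, control_drug=control_drug)
    viab = viab[viab["dose"] > 0]
    apop = sub[sub["dose"] > 0].copy()
    apop["apoptotic_fraction"] = (apop["apoptotic_cells"]
                                  / apop["total_cells"])
    apop = (apop.groupby(["drug", "dose", "time"], sort=False)
            ["apoptotic_fraction"].mean().reset_index())

    v = viab.pivot_table(index=["drug", "dose"], columns="time",
                         values="viability")
    a = apop.pivot_table(index=["drug", "dose"], columns="time",
                         values="apoptotic_fraction")
    wide = pd.concat({"viability": v, "apoptotic_fraction": a}, axis=1)
    wide.columns.names = ["measure", "time"]
    drugs = list(pd.unique(viab["drug"]))
    doses = sorted(pd.unique(viab["dose"]), reverse=True)
    rows = pd.MultiIndex.from_product([drugs, doses], names=["drug", "dose"])
    return wide.reindex(rows)


def assemble_response(viability: pd.DataFrame,
                      cell_line: str | None = None,
                      times: tuple[float, float] = (48.0, 72.0)) -> pd.Series:
    """Collapse per-time viability into the single PLSR output variable.

    The response is the mean of the 48 h and 72 h non-apoptotic viability per
    treated condition, which absorbs cell-line differences in response
    timing; when the later time point is unavailable the 48 h value is used
    alone (documented fallback). Returns a Series indexed by (drug, dose),
    ordered by drug and descending dose to match the design matrix rows.
    """
    df = viability
    if cell_line is not None:
        df = df[df["cell_line"] == cell_line]
    elif df["cell_line"].nunique() > 1:
        raise ValueError("multiple cell lines present; pass cell_line")
    df = df[df["dose"] > 0]
    t_early, t_late = times
    early = df[df["time"] == t_early]
    if early.empty:
        raise ValueError(f"no viability data at {t_early} h")
    late = df[df["time"] == t_late]

    e = early.set_index(["drug", "dose"])["viability"]
    if late.empty:
        warnings.warn(f"no {t_late} h data; using {t_early} h viability "
                      "alone", RuntimeWarning)
        resp = e
    else:
        l = late.set_index(["drug", "dose"])["viability"]
        if not e.index.sort_values().equals(l.index.sort_values()):
            raise ValueError("condition keys differ between time points")
        resp = (e + l.reindex(e.index)) / 2.0
    drugs = list(pd.unique(early["drug"]))
    doses = sorted(pd.unique(early["dose"]), reverse=True)
    order = pd.MultiIndex.from_product([drugs, doses], names=["drug", "dose"])
    resp = resp.reindex(order)
    resp.name = "response"
    return resp


def _hill_curve(d: np.ndarray, log_ec50: float, h: float,
                e_inf: float) -> np.ndarray:
    x = h * (np.log10(d) - log_ec50)
    return e_inf + (1.0 - e_inf) / (1.0 + 10.0 ** x)


def _norm_auc(log_d: np.ndarray, v: np.ndarray) -> float:
    span = log_d[-1] - log_d[0]
    return float(np.trapezoid(v, log_d) / span)


class DoseResponseModel:
    """Hill-curve model of relative viability against dose (uM)."""

    def __init__(self, doses, viability):
        d = np.asarray(doses, dtype=float)
        v = np.asarray(viability, dtype=float)
        if d.size != v.size:
            raise ValueError("doses and viability must have equal length")
        if d.size < 4:
            raise ValueError("at least 4 dose points required")
        if (d <= 0).any():
            raise ValueError("doses must be positive")
        order = np.argsort(d)
        self.doses = d[order]
        self.viability = v[order]

    def fit(self) -> "DoseResponseResults":
        d, v = self.doses, self.viability
        log_d = np.log10(d)
        lo, hi = log_d[0], log_d[-1]

        def resid(theta):
            return _hill_curve(d, *theta) - v

        best = None
        e0 = float(np.clip(v.min(), 0.0, 1.5))
        # data-driven start: log-dose where v crosses halfway to its floor
        mid = (1.0 + e0) / 2.0
        start0 = float(np.interp(-mid, -v, log_d))  # v decreasing in d
        starts = [start0, lo - 1, (lo + hi) / 2, hi + 1]
        for start in starts:
            for h0 in (1.0, 3.0):
                try:
                    sol = least_squares(
                        resid, x0=[start, h0, e0],
                        bounds=([lo - 4.0, 0.05, 0.0],
                                [hi + 4.0, 10.0, 1.5]),
                        xtol=1e-15, ftol=1e-15, gtol=1e-15,
                        x_scale="jac", max_nfev=5000)
                except Exception:  # pragma: no cover - scipy failure path
                    continue
                if best is None or sol.cost < best.cost:
                    best = sol
        tss = float(np.sum((v - v.mean()) ** 2))
        converged = best is not None and (
            best.success or best.cost <= 1e-18 * max(tss, 1.0))
        if converged:
            log_ec50, h, e_inf = best.x
            fit_v = _hill_curve(d, log_ec50, h, e_inf)
            ec50 = 10.0 ** log_ec50
            emax = float(1.0 - _hill_curve(np.array([d[-1]]),
                                           log_ec50, h, e_inf)[0])
            # absolute 50%-viability crossing of the fitted curve
            if e_inf < 0.5:
                ic50 = ec50 * (0.5 / (0.5 - e_inf)) ** (1.0 / h)
                if ic50 > 100.0 * d[-1]:
                    ic50 = np.nan
            else:
                ic50 = np.nan
            auc = _norm_auc(log_d, fit_v)
        else:  # fallback interpolation estimates
            warnings.warn("Hill fit did not converge; reporting "
                          "interpolation estimates", RuntimeWarning)
            ec50, h, e_inf = np.nan, np.nan, float(v[-1])
            emax = float(1.0 - v[-1])
            below = np.where(v <= 0.5)[0]
            if below.size and below[0] > 0:
                i = below[0]
                frac = (0.5 - v[i - 1]) / (v[i] - v[i - 1])
                ic50 = 10.0 ** (log_d[i - 1] + frac * (log_d[i] - log_d[i - 1]))
            elif below.size:
                ic50 = d[0]
            else:
                ic50 = np.nan
            auc = _norm_auc(log_d, v)
        return DoseResponseResults(
            model=self, ec50=float(ec50), hill_slope=float(h),
            e_inf=float(e_inf), ic50=float(ic50), emax=emax,
            auc=float(auc), converged=bool(converged))


@dataclass
class DoseResponseResults:
    """Fitted dose-response summary (doses in uM)."""

    model: DoseResponseModel
    ec50: float          # half-maximal-effect concentration of the fit
    hill_slope: float
    e_inf: float         # asymptotic relative viability
    ic50: float          # absolute 50%-viability crossing; NaN if absent
    emax: float          # 1 - fitted viability at the top tested dose
    auc: float           # normalized AUC over log10 dose
    converged: bool

    @property
    def log10_ic50_molar(self) -> float:
        return float(np.log10(self.ic50 * 1e-6)) if np.isfinite(self.ic50) \
            else np.nan

    @property
    def sensitivity(self) -> str:
        return classify_sensitivity(self)

    def predict(self, doses) -> np.ndarray:
        return _hill_curve(np.asarray(doses, dtype=float),
                           np.log10(self.ec50), self.hill_slope, self.e_inf)

    def summary(self) -> str:
        ic50 = f"{self.ic50:.4g} uM" if np.isfinite(self.ic50) else "absent"
        return "\n".join([
            "Dose-Response Results",
            "=" * 38,
            f"EC50:        {self.ec50:.4g} uM",
            f"Hill slope:  {self.hill_slope:.3f}",
            f"E_inf:       {self.e_inf:.3f}",
            f"IC50:        {ic50}",
            f"Emax:        {self.emax:.3f}",
            f"AUC (norm):  {self.auc:.3f}",
            f"converged:   {self.converged}",
            f"class:       {self.sensitivity}",
        ])

    def plot(self, ax=None):
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        d = self.model.doses
        ax.semilogx(d, self.model.viability, "o", label="data")
        grid = np.logspace(np.log10(d[0]), np.log10(d[-1]), 100)
        ax.semilogx(grid, self.predict(grid), "-", label="Hill fit")
        ax.set_xlabel("dose (uM)")
        ax.set_ylabel("relative viability")
        ax.legend()
        return ax


def classify_sensitivity(fit) -> str:
    """Sensitive iff log10(IC50 [M]) < -6.5, strictly; absent IC50 -> resistant.

    Accepts a DoseResponseResults or an IC50 in uM.
    """
    ic50_um = fit.ic50 if hasattr(fit, "ic50") else float(fit)
    if not np.isfinite(ic50_um) or ic50_um <= 0:
        return "resistant"
    return "sensitive" if np.log10(ic50_um * 1e-6) < -6.5 else "resistant"


def resistance_auc(viability: pd.DataFrame,
                   cell_line: str | None = None,
                   drug: str | None = None,
                   times: tuple[float, float] = (48.0, 72.0)) -> float:
    """Relative resistance: time-averaged normalized viability AUC.

    The trapezoid AUC of relative viability over log10 dose is computed at
    each of the two late time points, normalized by the log-dose span, and
    averaged, so a fully unresponsive line scores 1 and complete killing at
    every dose scores 0. Falls back to the earlier time alone when the later
    one is unavailable.
    """
    df = viability
    if cell_line is not None:
        df = df[df["cell_line"] == cell_line]
    if drug is not None:
        df = df[df["drug"] == drug]
    df = df[df["dose"] > 0]
    aucs = []
    for t in times:
        sub = df[df["time"] == t].sort_values("dose")
        if sub.empty:
            continue
        if sub["dose"].nunique() < 2:
            raise ValueError("resistance AUC requires >= 2 doses")
        log_d = np.log10(sub["dose"].to_numpy())
        aucs.append(_norm_auc(log_d, sub["viability"].to_numpy()))
    if not aucs:
        raise ValueError(f"no viability data at times {times}")
    if len(aucs) < len(times):
        warnings.warn("one time point unavailable; using the other alone",
                      RuntimeWarning)
    return float(np.mean(aucs))
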