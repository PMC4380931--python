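"""Replicate-level signal preprocessing into a z-scored design matrix.

The pipeline turns raw replicate intensities (long format: cell line, drug,
dose, time, antibody, bio/tech replicate, scanner, value) into the
condition x variable matrix consumed by PLSR:

1. per-condition removal of replicate values outside 1.5x the interquartile
   range of the pooled biological x technical replicates;
2. per-cell-line antibody QC dropping antibodies whose biological-replicate
   condition profiles correlate poorly (mean pairwise Pearson r < 0.5);
3. median collapse of the retained replicates, log2-normalized to the
   matching vehicle control at the same time point;
4. assembly into a (drug x dose) x (signal x time) matrix, z-scored per
   column (sample sd, ddof=1), with scaling parameters retained so the
   transform is invertible;
5. an optional dual-analysis consistency mask keeping only variables whose
   condition-mean fold change has the same sign in two independent
   quantifications (e.g., two array scanners).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "DesignMatrix",
    "iqr_outlier_filter",
    "antibody_qc",
    "collapse_log2fc",
    "assemble_design",
    "consistency_mask",
]

_COND_KEYS = ["cell_line", "drug", "dose", "time", "antibody"]


def iqr_outlier_filter(values) -> np.ndarray:
    """Drop values outside [Q1 - 1.5*IQR, Q3 + 1.5*IQR].

    Quartiles use linear interpolation between order statistics (the common
    "type 7" convention). At least one value always survives: the median lies
    inside the fences by construction.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("iqr_outlier_filter requires at least one value")
    # applied to a fixed point so the filter is idempotent; replicate sets
    # in practice converge in one or two passes
    while True:
        q1, q3 = np.quantile(v, [0.25, 0.75])
        iqr = q3 - q1
        keep = (v >= q1 - 1.5 * iqr) & (v <= q3 + 1.5 * iqr)
        if keep.all():
            return v
        v = v[keep]


def antibody_qc(tensor: pd.DataFrame, cell_line: str,
                threshold: float = 0.5
                ) -> tuple[list[str], pd.DataFrame]:
    """Drop antibodies whose biological replicates disagree for a cell line.

    Technical replicates are averaged first; each biological replicate then
    yields one profile across all (drug, dose, time) conditions. An
    antibody's score is the mean pairwise Pearson correlation between those
    profiles; antibodies scoring below ``threshold`` are dropped. Antibodies
    with fewer than two complete replicate profiles are flagged
    ``insufficient`` and retained.

    Returns (retained antibody labels, per-antibody score table with columns
    ``score`` and ``insufficient``).
    """
    sub = tensor[tensor["cell_line"] == cell_line]
    if sub.empty:
        raise ValueError(f"no records for cell line {cell_line!r}")
    if sub["bio_rep"].nunique() < 2:
        raise ValueError("antibody QC requires >= 2 biological replicates")
    # average technical replicates, then pivot to condition x bio_rep
    tech_mean = (sub.groupby(["antibody", "drug", "dose", "time", "bio_rep"],
                             sort=False)["value"].mean().reset_index())
    rows = []
    for ab, grp in tech_mean.groupby("antibody", sort=False):
        prof = grp.pivot_table(index=["drug", "dose", "time"],
                               columns="bio_rep", values="value")
        prof = prof.dropna(axis=0)
        complete = prof.shape[1]
        if complete < 2 or prof.shape[0] < 3:
            rows.append({"antibody": ab, "score": np.nan,
                         "insufficient": True})
            continue
        corr = prof.corr(method="pearson").to_numpy()
        iu = np.triu_indices_from(corr, k=1)
        rows.append({"antibody": ab, "score": float(np.nanmean(corr[iu])),
                     "insufficient": False})
    scores = pd.DataFrame(rows).set_index("antibody")
    keep = scores["insufficient"] | (scores["score"] >= threshold)
    retained = [ab for ab in scores.index[keep]]
    return retained, scores


def _collapsed_medians(tensor: pd.DataFrame) -> pd.Series:
    """Median of IQR-retained replicate values per condition (vectorized)."""
    df = tensor[_COND_KEYS + ["value"]].copy()
    df["_rep"] = df.groupby(_COND_KEYS, sort=False).cumcount()
    wide = df.pivot_table(index=_COND_KEYS, columns="_rep", values="value")
    arr = wide.to_numpy()
    # vectorized fixed-point IQR filter (matches iqr_outlier_filter)
    while True:
        q1 = np.nanquantile(arr, 0.25, axis=1)
        q3 = np.nanquantile(arr, 0.75, axis=1)
        iqr = q3 - q1
        lo = (q1 - 1.5 * iqr)[:, None]
        hi = (q3 + 1.5 * iqr)[:, None]
        out = ~((arr >= lo) & (arr <= hi)) & ~np.isnan(arr)
        if not out.any():
            break
        arr = np.where(out, np.nan, arr)
    med = np.nanmedian(arr, axis=1)
    return pd.Series(med, index=wide.index, name="median")


def collapse_log2fc(tensor: pd.DataFrame,
                    control_drug: str = "DMSO") -> pd.DataFrame:
    """Per-condition log2 fold change of replicate medians vs vehicle control.

    Replicates are pooled (all biological x technical values for a
    condition), 1.5x-IQR filtered, and collapsed to their median; the value
    reported is ``log2(median / control median)`` against the vehicle control
    of the same cell line, antibody, and time. Control conditions map to 0.
    Apply per scanner subset when the tensor holds two quantifications.

    Returns a long table (cell_line, drug, dose, time, antibody, log2fc).
    """
    if (tensor["value"] <= 0).any():
        raise ValueError("raw intensities must be strictly positive")
    med = _collapsed_medians(tensor).reset_index()
    is_ctrl = (med["drug"] == control_drug) | (med["dose"] == 0)
    ctrl = (med[is_ctrl]
            .set_index(["cell_line", "antibody", "time"])["median"])
    if ctrl.index.has_duplicates:
        ctrl = ctrl.groupby(level=[0, 1, 2]).median()

    treated = med[~is_ctrl].copy()
    key = pd.MultiIndex.from_frame(treated[["cell_line", "antibody", "time"]])
    missing = ~key.isin(ctrl.index)
    if missing.any():
        bad = sorted(set(key[missing]))[:5]
        raise ValueError(f"missing vehicle control for (cell_line, antibody, "
                         f"time): {bad}")
    denom = ctrl.reindex(key).to_numpy()
    treated["log2fc"] = np.log2(treated["median"].to_numpy() / denom)

    ctrl_rows = med[is_ctrl].copy()
    ctrl_rows["log2fc"] = 0.0
    out = pd.concat([treated, ctrl_rows], ignore_index=True)
    return out[_COND_KEYS + ["log2fc"]]


@dataclass
class DesignMatrix:
    """Z-scored (drug, dose) x (signal, time) predictor matrix.

    ``values`` holds z-scores (per-column mean 0 and sample sd 1 across
    conditions); ``column_means``/``column_sds`` allow exact inversion.
    Columns with zero variance are flagged and set to 0, not divided.
    """

    values: pd.DataFrame
    column_means: pd.Series
    column_sds: pd.Series
    zero_variance: pd.Series

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def unscale(self) -> pd.DataFrame:
        """Invert z-scoring back to the fold-change table."""
        sds = self.column_sds.where(~self.zero_variance, 0.0)
        return self.values.mul(sds, axis=1).add(self.column_means, axis=1)

    def to_csv(self, out_dir: str | Path, stem: str = "design") -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.values.to_csv(out / f"{stem}.csv")
        pd.DataFrame({
            "mean": self.column_means,
            "sd": self.column_sds,
            "zero_variance": self.zero_variance,
        }).to_csv(out / f"{stem}_scaling.csv")


def assemble_design(fc_table: pd.DataFrame,
                    signals: list[str] | None = None,
                    times: list[float] | None = None,
                    drugs: list[str] | None = None,
                    impute: bool = False) -> DesignMatrix:
    """Pivot a fold-change table into the z-scored PLSR design matrix.

    Rows are treated conditions ordered by (drug, descending dose); columns
    are (signal, time) ordered by the given label lists. With the default
    dense design (5 drugs x 7 doses; 21 signals x 5 times) this yields the
    35 x 105 per-cell-line input matrix. Missing cells raise unless
    ``impute`` enables column-mean imputation.
    """
    fc = fc_table[fc_table["dose"] > 0]
    if fc.empty:
        raise ValueError("fold-change table holds no treated conditions")
    if fc["cell_line"].nunique() != 1:
        raise ValueError("assemble_design expects a single cell line; "
                         "filter first")
    if signals is None:
        signals = list(pd.unique(fc["antibody"]))
    if times is None:
        times = sorted(pd.unique(fc["time"]))
    if drugs is None:
        drugs = list(pd.unique(fc["drug"]))

    wide = fc.pivot_table(index=["drug", "dose"], columns=["antibody", "time"],
                          values="log2fc")
    cols = pd.MultiIndex.from_product([signals, times],
                                      names=["signal", "time"])
    doses = sorted(pd.unique(fc["dose"]), reverse=True)
    rows = pd.MultiIndex.from_product([drugs, doses], names=["drug", "dose"])
    wide = wide.reindex(index=rows, columns=cols)

    if wide.isna().any().any():
        if impute:
            wide = wide.fillna(wide.mean())
        else:
            missing = [(r, c) for r, c in
                       zip(*np.where(wide.isna().to_numpy()))]
            labels = [(wide.index[r], wide.columns[c])
                      for r, c in missing[:10]]
            raise ValueError(
                f"{len(missing)} missing (condition, variable) cells, e.g. "
                f"{labels}; pass impute=True for column-mean imputation")

    means = wide.mean(axis=0)
    sds = wide.std(axis=0, ddof=1)
    zero_var = (sds < 1e-12) | sds.isna()
    safe_sd = sds.where(~zero_var, 1.0)
    scaled = (wide - means) / safe_sd
    scaled.loc[:, zero_var] = 0.0
    return DesignMatrix(values=scaled, column_means=means, column_sds=sds,
                        zero_variance=zero_var)


def consistency_mask(fc_a: pd.DataFrame, fc_b: pd.DataFrame
                     ) -> tuple[pd.Series, float]:
    """Keep variables whose condition-mean fold change agrees in sign.

    ``fc_a`` and ``fc_b`` are fold-change tables from two independent
    quantifications of the same samples with identical condition keys. A
    (signal, time) variable is kept iff the sign of its mean fold change over
    treated conditions is the same in both. Returns (boolean mask indexed by
    (antibody, time), fraction kept).
    """
    def var_means(fc: pd.DataFrame) -> pd.Series:
        t = fc[fc["dose"] > 0]
        return t.groupby(["antibody", "time"])["log2fc"].mean()

    ma, mb = var_means(fc_a), var_means(fc_b)
    if not ma.index.equals(mb.index):
        if set(ma.index) != set(mb.index):
            raise ValueError("fold-change tables cover different variables")
        mb = mb.reindex(ma.index)
    keys_a = fc_a[fc_a["dose"] > 0].groupby(["drug", "dose", "time"]).size()
    keys_b = fc_b[fc_b["dose"] > 0].groupby(["drug", "dose", "time"]).size()
    if not keys_a.index.equals(keys_b.index):
        raise ValueError("fold-change tables cover different conditions")

    mask = np.sign(ma) == np.sign(mb)
    mask.name = "kept"
    return mask, float(mask.mean())
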