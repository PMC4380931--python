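"""Signed VIP signatures and clustering of cell lines on them.

VIP (variable importance in the projection) scores summarize how much each
predictor (a signal measured at a time point) contributes to the response
variance a PLSR model explains::

    VIP_k = sqrt( K * sum_n w_nk^2 SS_n / sum_n SS_n )

with K predictors, unit-norm weight columns ``w_n`` and per-component
explained response sums of squares ``SS_n``. Because the weight columns have
unit norm, ``sum_k VIP_k^2 = K`` holds identically and is asserted here.

Scores are made directional by attaching the sign of the Pearson correlation
between the predictor column and the response (a minus sign marks variables
anti-correlated with viability), thresholded at |VIP| > 1 (scores in (0, 1]
are zeroed; the boundary value 1 maps to zero), filtered for sign
consistency between two independent quantifications, averaged, and finally
used to cluster cell lines (Euclidean distance, average linkage), optionally
excluding direct drug-target read-outs such as pMEK and pERK.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

__all__ = [
    "compute_vip",
    "sign_and_threshold",
    "merge_consistent_vip",
    "cluster_cell_lines",
    "ClusterResult",
]


def compute_vip(weights, ss=None) -> np.ndarray:
    """Evaluate the VIP formula from weight matrix (K x N) and SS_n (N,).

    Accepts a fitted PLSRResults as the single argument as a convenience.
    """
    if ss is None and hasattr(weights, "weights"):  # PLSRResults
        ss = weights.ss
        weights = weights.weights
    W = np.asarray(weights, dtype=float)
    s = np.asarray(ss, dtype=float).ravel()
    if W.ndim != 2 or W.shape[1] != s.size:
        raise ValueError("weights must be K x N with one SS_n per component")
    total = s.sum()
    if total <= 0:
        raise ValueError("model explains nothing (all SS_n = 0)")
    K = W.shape[0]
    vip = np.sqrt(K * (W ** 2 @ s) / total)
    return vip


def sign_and_threshold(vip, X, y, threshold: float = 1.0,
                       sign_from: str = "correlation",
                       coef=None) -> pd.DataFrame:
    """Attach signs from the viability correlation and zero |VIP| <= 1.

    ``sign_from='correlation'`` (default) uses the Pearson correlation of
    each predictor column with the response; zero correlation maps to +1.
    ``sign_from='coefficient'`` uses the sign of the PLSR coefficient vector
    (pass ``coef``) for comparison.

    Returns a DataFrame (vip, sign, signed_vip, kept) indexed like ``vip``.
    """
    if isinstance(vip, pd.Series):
        index = vip.index
        v = vip.to_numpy(dtype=float)
    else:
        v = np.asarray(vip, dtype=float).ravel()
        index = pd.RangeIndex(v.size)
    if isinstance(X, pd.DataFrame):
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[1] != v.size:
        raise ValueError("vip length must equal number of predictor columns")

    if sign_from == "correlation":
        xc = X - X.mean(axis=0)
        yc = y - y.mean()
        num = xc.T @ yc
        den = np.sqrt((xc ** 2).sum(axis=0) * (yc ** 2).sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.where(den > 0, num / den, 0.0)
        sign = np.where(corr < 0, -1.0, 1.0)  # zero correlation -> +1
    elif sign_from == "coefficient":
        if coef is None:
            raise ValueError("sign_from='coefficient' requires coef")
        sign = np.where(np.asarray(coef, dtype=float) < 0, -1.0, 1.0)
    else:
        raise ValueError("sign_from must be 'correlation' or 'coefficient'")

    signed = np.where(v > threshold, sign * v, 0.0)
    return pd.DataFrame({"vip": v, "sign": sign, "signed_vip": signed,
                         "kept": True}, index=index)


def merge_consistent_vip(profile_a: pd.DataFrame, profile_b: pd.DataFrame,
                         mask: pd.Series
                         ) -> tuple[pd.DataFrame, dict]:
    """Average two signed VIP profiles over the consistent variables.

    Variables failing the dual-analysis mask are dropped, as are variables
    whose (nonzero) signed scores disagree in sign between the two profiles;
    the remaining signed scores are averaged. Returns the merged profile and
    a report counting removals.
    """
    if not profile_a.index.equals(profile_b.index):
        raise ValueError("profiles cover different variables")
    mask = mask.reindex(profile_a.index)
    if mask.isna().any():
        raise ValueError("mask does not cover all profile variables")

    a = profile_a["signed_vip"]
    b = profile_b["signed_vip"]
    discordant = (a * b < 0)  # both nonzero, opposite sign
    keep = mask.astype(bool) & ~discordant
    merged = profile_a.loc[keep].copy()
    merged["signed_vip"] = (a[keep] + b[keep]) / 2.0
    merged["vip"] = merged["signed_vip"].abs()
    merged["sign"] = np.where(merged["signed_vip"] < 0, -1.0, 1.0)
    report = {
        "n_variables": int(len(mask)),
        "n_masked_out": int((~mask.astype(bool)).sum()),
        "n_sign_discordant": int((discordant & mask.astype(bool)).sum()),
        "n_kept": int(keep.sum()),
        "fraction_kept": float(keep.mean()),
    }
    return merged, report


def _signal_of(label) -> str:
    if isinstance(label, tuple):
        return str(label[0])
    return str(label).split("@")[0]


@dataclass
class ClusterResult:
    """Agglomerative clustering of cell lines on signed VIP vectors."""

    linkage: np.ndarray          # scipy linkage matrix
    labels: list[str]
    method: str
    metric: str

    @property
    def leaf_order(self) -> list[str]:
        return [self.labels[i] for i in hierarchy.leaves_list(self.linkage)]

    def cophenetic(self) -> np.ndarray:
        """Condensed cophenetic distance matrix."""
        return hierarchy.cophenet(self.linkage)

    def merge_table(self) -> pd.DataFrame:
        return pd.DataFrame(self.linkage,
                            columns=["left", "right", "height", "size"])

    def to_newick(self) -> str:
        """Dendrogram as a newick string with branch lengths."""
        tree = hierarchy.to_tree(self.linkage)

        def rec(node, parent_height):
            length = parent_height - (0.0 if node.is_leaf() else node.dist)
            if node.is_leaf():
                length = parent_height
                return f"{self.labels[node.id]}:{length:.6g}"
            left = rec(node.left, node.dist)
            right = rec(node.right, node.dist)
            return f"({left},{right}):{parent_height - node.dist:.6g}"

        left = rec(tree.left, tree.dist)
        right = rec(tree.right, tree.dist)
        return f"({left},{right});"


def cluster_cell_lines(profiles, exclude=("pMEK", "pERK"),
                       method: str = "average") -> ClusterResult:
    """Cluster cell lines on signed, thresholded VIP vectors.

    ``profiles`` is a mapping cell line -> signed VIP Series over identical
    variables, or an equivalent DataFrame with cell lines as rows. Variables
    whose signal is in ``exclude`` (by default the direct drug-target
    read-outs pMEK and pERK) are removed before computing Euclidean
    distances; linkage is average by default. All-zero profiles are retained
    and clustered like any other vector.
    """
    if isinstance(profiles, dict):
        mat = pd.DataFrame({k: v for k, v in profiles.items()}).T
    else:
        mat = pd.DataFrame(profiles)
    if mat.shape[0] < 2:
        raise ValueError("clustering requires at least two profiles")
    if exclude:
        drop = [c for c in mat.columns if _signal_of(c) in set(exclude)]
        mat = mat.drop(columns=drop)
    dist = pdist(mat.to_numpy(dtype=float), metric="euclidean")
    Z = hierarchy.linkage(dist, method=method)
    return ClusterResult(linkage=Z, labels=[str(i) for i in mat.index],
                         method=method, metric="euclidean")
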