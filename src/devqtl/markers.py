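"""Cell-type specificity scoring and marker-gene selection.

Works on a gene x cluster matrix of mean log-scale expression (log2 TPM
or log2 UMI per platform; any non-negative log-scale matrix is
accepted). Specificity is the tau index: 0 for uniform expression,
1 for expression confined to a single cluster. Markers for a cluster
are its rank-1 genes passing a tau floor, taken top-N by expression.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "tau_specificity",
    "rank_clusters",
    "select_markers",
    "marker_profile",
]


def tau_specificity(cluster_expr: pd.DataFrame) -> pd.Series:
    """Yanai-style tau per gene.

    With x_hat_i = x_i / max_i x_i, tau = sum_i (1 - x_hat_i) / (n - 1).
    Negative inputs are floored at 0 first (tau assumes non-negative
    expression); genes whose maximum is 0 get NaN.
    """
    if cluster_expr.shape[1] < 2:
        raise ValueError("tau requires at least 2 clusters")
    X = np.maximum(cluster_expr.to_numpy(float), 0.0)
    mx = X.max(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        xhat = X / mx[:, None]
        tau = (1.0 - xhat).sum(axis=1) / (X.shape[1] - 1)
    tau[mx == 0] = np.nan
    return pd.Series(tau, index=cluster_expr.index, name="tau")


def rank_clusters(cluster_expr: pd.DataFrame) -> pd.DataFrame:
    """Dense descending ranks per gene; the highest cluster is rank 1 and
    ties share the smaller rank ((3,1,1) -> (1,2,2))."""
    return cluster_expr.rank(axis=1, method="dense", ascending=False).astype(int)


def select_markers(
    cluster_expr: pd.DataFrame,
    cluster: str,
    top_n: int = 10,
    min_tau: float = 0.8,
) -> list[str]:
    """Top-``top_n`` marker genes for a cluster.

    Candidates must have their highest expression in the cluster (dense
    rank 1) and tau >= min_tau; they are ordered by expression in the
    cluster, descending. Fewer than top_n may qualify.
    """
    if cluster not in cluster_expr.columns:
        raise KeyError(f"unknown cluster: {cluster!r}")
    tau = tau_specificity(cluster_expr)
    ranks = rank_clusters(cluster_expr)
    ok = (ranks[cluster] == 1) & (tau >= min_tau)
    chosen = cluster_expr.loc[ok, cluster].sort_values(ascending=False)
    return list(chosen.index[:top_n])


def marker_profile(
    log2cpm: pd.DataFrame,
    marker_sets: dict[str, list[str]],
    sample_table: pd.DataFrame,
    bandwidth: float = 0.5,
) -> pd.DataFrame:
    """Smoothed temporal profile of each marker set with a 95% band.

    Per sample, expression is averaged over the set's genes; the profile
    is a local linear regression on log2 age with tricube weights over a
    fractional bandwidth (LOESS-style), evaluated at each sample age.
    The band is +-1.96 standard errors of the local fit. As bandwidth
    approaches 1 the fit approaches a single global weighted linear fit.
    """
    st = sample_table.set_index("sample_id").loc[log2cpm.columns]
    x = np.log2(st["age_days"].to_numpy(float))
    order = np.argsort(x)
    rows = []
    for name, genes in marker_sets.items():
        present = [g for g in genes if g in log2cpm.index]
        if not present:
            raise ValueError(f"marker set {name!r} has no genes in the matrix")
        y = log2cpm.loc[present].mean(axis=0).to_numpy(float)
        fitted, se = _loess(x[order], y[order], bandwidth)
        for xi, fi, si, sid in zip(x[order], fitted, se, log2cpm.columns[order]):
            rows.append(
                {
                    "cell_type": name,
                    "sample_id": sid,
                    "log2_age": float(xi),
                    "fit": float(fi),
                    "lo": float(fi - 1.96 * si),
                    "hi": float(fi + 1.96 * si),
                }
            )
    return pd.DataFrame(rows)


def _loess(x: np.ndarray, y: np.ndarray, span: float) -> tuple[np.ndarray, np.ndarray]:
    """Local linear regression with tricube weights at each x.

    Returns fitted values and pointwise standard errors (from the
    weighted-least-squares sandwich with a local residual variance).
    """
    n = len(x)
    k = max(int(np.ceil(span * n)), 3)
    fitted = np.empty(n)
    se = np.empty(n)
    for i in range(n):
        d = np.abs(x - x[i])
        h = np.partition(d, k - 1)[k - 1]
        if h == 0:
            h = np.finfo(float).eps
        w = np.clip(1 - (d / h) ** 3, 0, None) ** 3
        use = w > 0
        X = np.column_stack([np.ones(use.sum()), x[use] - x[i]])
        W = w[use]
        XtWX = X.T @ (X * W[:, None])
        XtWy = X.T @ (W * y[use])
        try:
            beta = np.linalg.solve(XtWX, XtWy)
            cov_core = np.linalg.inv(XtWX)
        except np.linalg.LinAlgError:
            beta = np.array([np.average(y[use], weights=W), 0.0])
            cov_core = np.array([[1.0 / W.sum(), 0.0], [0.0, 0.0]])
        resid = y[use] - X @ beta
        dof = max(use.sum() - 2, 1)
        # local weighted residual variance with a small-sample correction
        s2 = float((W * resid**2).sum() / W.sum()) * (use.sum() / dof)
        fitted[i] = beta[0]
        var = s2 * (cov_core @ (X.T @ (X * (W**2)[:, None])) @ cov_core)[0, 0]
        se[i] = np.sqrt(max(var, 0.0))
    return fitted, se
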