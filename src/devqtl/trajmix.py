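"""Finite mixtures of polynomial expression trajectories.

Genes are clustered into K temporal groups by EM on a mixture of
polynomial regressions: each gene's IQR-normalized log2 CPM profile
across samples is one observation sequence, modelled as a component
polynomial of (standardized log2) age plus Gaussian noise with a
component-specific variance. Components whose mixing proportion drops
below a floor are pruned during EM, mirroring the automatic merging of
adjacent classes when priors collapse. Model order is chosen by BIC,
components are labelled rising / falling / non_transitional by the
epoch-3 vs epoch-1 contrast of their fitted curves, and genes are
hard-assigned by maximum responsibility.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .simgen import epoch_of_period

__all__ = [
    "TrajectoryFit",
    "iqr_normalize",
    "fit_mixture",
    "select_k",
    "label_components",
    "assign_genes",
]

LABEL_TIE_ORDER = ("non_transitional", "falling", "rising")


def iqr_normalize(log2cpm: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Per-gene (x - median) / IQR with linear-interpolation quartiles.

    Genes with zero IQR are returned unscaled (and uncentered) with a
    flag; scaling them would divide by zero and they carry no temporal
    signal anyway.
    """
    X = log2cpm.to_numpy(float)
    med = np.median(X, axis=1, keepdims=True)
    q1, q3 = np.percentile(X, [25, 75], axis=1)
    iqr = (q3 - q1)[:, None]
    flat = iqr[:, 0] == 0
    out = np.where(flat[:, None], X, (X - med) / np.where(flat[:, None], 1.0, iqr))
    return (
        pd.DataFrame(out, index=log2cpm.index, columns=log2cpm.columns),
        pd.Series(flat, index=log2cpm.index, name="zero_iqr"),
    )


@dataclass
class TrajectoryFit:
    """EM fit of a K-component polynomial trajectory mixture."""

    K: int
    degree: int
    coef: np.ndarray          # K x (degree+1), increasing powers of scaled age
    sigma2: np.ndarray        # K
    pi: np.ndarray            # K
    resp: np.ndarray          # genes x K
    loglik: float
    n_genes: int
    n_samples: int
    age_center: float
    age_scale: float
    gene_ids: np.ndarray
    loglik_trace: list[float]
    labels: list[str] | None = None

    @property
    def n_params(self) -> int:
        # per component: degree+1 coefficients + 1 variance; K-1 free weights
        return self.K * (self.degree + 2) + (self.K - 1)

    @property
    def aic(self) -> float:
        return 2 * self.n_params - 2 * self.loglik

    @property
    def bic(self) -> float:
        return self.n_params * np.log(self.n_genes) - 2 * self.loglik

    def predict(self, age_days) -> np.ndarray:
        """Fitted component curves (K x len(age_days))."""
        u = (np.log2(np.asarray(age_days, dtype=float)) - self.age_center) / self.age_scale
        return np.polynomial.polynomial.polyval(u, self.coef.T)


def _design(age_days: np.ndarray, degree: int, center: float, scale: float) -> np.ndarray:
    u = (np.log2(age_days) - center) / scale
    return np.vander(u, degree + 1, increasing=True)


def _component_loglik(X, B, coef, sigma2):
    """genes x K matrix of per-gene log densities."""
    S = X.shape[1]
    fit = B @ coef.T  # samples x K
    # sum over samples of squared residuals, per gene and component
    sq = (
        np.einsum("gs,gs->g", X, X)[:, None]
        - 2.0 * X @ fit
        + np.einsum("sk,sk->k", fit, fit)[None, :]
    )
    return -0.5 * (S * np.log(2 * np.pi * sigma2)[None, :] + sq / sigma2[None, :])


def fit_mixture(
    normalized: pd.DataFrame,
    ages: np.ndarray,
    K: int,
    degree: int = 4,
    min_prior: float = 0.05,
    n_starts: int = 10,
    max_iter: int = 300,
    tol: float = 1e-6,
    seed: int = 0,
) -> TrajectoryFit:
    """EM fit of a K-component mixture of degree-``degree`` polynomial
    trajectories with component-specific Gaussian noise.

    Each gene contributes one likelihood term: the product over samples
    of Normal(x_gs; poly_k(age_s), sigma_k^2). The M-step is a weighted
    polynomial least-squares fit per component; components whose mixing
    proportion falls below ``min_prior`` are deleted and EM continues
    with fewer components. The best of ``n_starts`` random restarts by
    final log-likelihood is returned.
    """
    X = normalized.to_numpy(float)
    ages = np.asarray(ages, dtype=float)
    G, S = X.shape
    if S != len(ages):
        raise ValueError("ages length must match the number of samples")
    if S < degree + 2:
        raise ValueError("need at least degree + 2 samples")
    if not (1 <= K <= 10):
        raise ValueError("K must be in 1..10")

    logage = np.log2(ages)
    center, scale = float(logage.mean()), float(logage.std() or 1.0)
    B = _design(ages, degree, center, scale)
    BtB = B.T @ B

    rng = np.random.default_rng(seed)
    best: TrajectoryFit | None = None
    for _start in range(n_starts):
        fit = _em_once(X, B, BtB, K, degree, min_prior, max_iter, tol, rng)
        if best is None or fit[2] > best_ll:
            best = fit
            best_ll = fit[2]
    coef, sigma2, loglik, pi, resp, trace = best
    return TrajectoryFit(
        K=len(pi), degree=degree, coef=coef, sigma2=sigma2, pi=pi, resp=resp,
        loglik=loglik, n_genes=G, n_samples=S, age_center=center, age_scale=scale,
        gene_ids=np.asarray(normalized.index), loglik_trace=trace,
    )


def _em_once(X, B, BtB, K, degree, min_prior, max_iter, tol, rng):
    G, S = X.shape
    # init: random soft assignment
    resp = rng.dirichlet(np.ones(K) * 2.0, size=G)
    pi = resp.mean(axis=0)
    coef = np.zeros((K, degree + 1))
    sigma2 = np.ones(K)
    _m_step(X, B, BtB, resp, coef, sigma2)
    prev_ll = -np.inf
    trace: list[float] = []
    for it in range(max_iter):
        # E-step
        logdens = _component_loglik(X, B, coef, sigma2) + np.log(pi)[None, :]
        norm = logsumexp(logdens, axis=1)
        if not np.all(np.isfinite(norm)):
            raise FloatingPointError(f"non-finite likelihood at EM iteration {it}")
        resp = np.exp(logdens - norm[:, None])
        ll = float(norm.sum())
        trace.append(ll)
        # M-step
        pi = resp.mean(axis=0)
        # prune collapsed components (keep at least one)
        if len(pi) > 1 and pi.min() < min_prior:
            keep = pi >= min_prior
            if not keep.any():
                keep[np.argmax(pi)] = True
            resp = resp[:, keep]
            resp /= resp.sum(axis=1, keepdims=True)
            pi = resp.mean(axis=0)
            coef = coef[keep]
            sigma2 = sigma2[keep]
            prev_ll = -np.inf  # likelihood not comparable across K
        _m_step(X, B, BtB, resp, coef, sigma2)
        if np.isfinite(prev_ll) and abs(ll - prev_ll) <= tol * (abs(prev_ll) + 1.0):
            break
        prev_ll = ll
    logdens = _component_loglik(X, B, coef, sigma2) + np.log(pi)[None, :]
    norm = logsumexp(logdens, axis=1)
    resp = np.exp(logdens - norm[:, None])
    return coef, sigma2, float(norm.sum()), pi, resp, trace


def _m_step(X, B, BtB, resp, coef, sigma2):
    S = X.shape[1]
    w = resp.sum(axis=0)  # effective genes per component
    for k in range(resp.shape[1]):
        xbar = (resp[:, k] @ X) / w[k]  # weighted mean profile
        coef[k] = np.linalg.solve(BtB, B.T @ xbar)
        fit = B @ coef[k]
        sq = np.einsum("gs,gs->g", X - fit[None, :], X - fit[None, :])
        sigma2[k] = max((resp[:, k] @ sq) / (w[k] * S), 1e-10)


def select_k(fits: list[TrajectoryFit], override: int | None = None) -> tuple[pd.DataFrame, int]:
    """AIC/BIC table over candidate fits and the chosen K (argmin BIC).

    Note the fitted K may be smaller than requested when components were
    pruned; the table reports the final K of each fit. Ties go to the
    smallest K.
    """
    if not fits:
        raise ValueError("empty fit list")
    table = pd.DataFrame(
        {
            "K": [f.K for f in fits],
            "n_params": [f.n_params for f in fits],
            "loglik": [f.loglik for f in fits],
            "aic": [f.aic for f in fits],
            "bic": [f.bic for f in fits],
        }
    ).sort_values(["K"], ignore_index=True)
    if override is not None:
        return table, int(override)
    best = table.loc[table["bic"].idxmin(), "K"]
    ties = table[np.isclose(table["bic"], table["bic"].min())]
    return table, int(ties["K"].min()) if len(ties) > 1 else int(best)


def label_components(
    fit: TrajectoryFit,
    sample_table: pd.DataFrame,
    delta: float = 0.5,
) -> list[str]:
    """Label each component rising / falling / non_transitional.

    The contrast is the mean fitted value over epoch-3 sample ages minus
    the mean over epoch-1 ages; |contrast| <= delta (normalized units)
    is non_transitional. Labels are stored on the fit and returned.
    """
    epochs = sample_table["period"].map(epoch_of_period).to_numpy()
    ages = sample_table["age_days"].to_numpy(float)
    a1, a3 = ages[epochs == 1], ages[epochs == 3]
    if len(a1) == 0 or len(a3) == 0:
        raise ValueError("sample table lacks epoch-1 or epoch-3 samples")
    curves = fit.predict(np.concatenate([a1, a3]))
    d = curves[:, len(a1):].mean(axis=1) - curves[:, : len(a1)].mean(axis=1)
    labels = ["rising" if x > delta else "falling" if x < -delta else "non_transitional"
              for x in d]
    fit.labels = labels
    return labels


def assign_genes(fit: TrajectoryFit) -> pd.DataFrame:
    """Hard-assign genes to components by maximum responsibility.

    Exact ties between components are broken toward non_transitional,
    then falling, then rising (by label when labels are set, otherwise
    by component index).
    """
    resp = fit.resp
    best = np.argmax(resp, axis=1)
    maxr = resp[np.arange(len(resp)), best]
    if fit.labels is not None:
        order = {lab: i for i, lab in enumerate(LABEL_TIE_ORDER)}
        for g in range(len(resp)):
            tied = np.flatnonzero(np.isclose(resp[g], maxr[g]))
            if len(tied) > 1:
                best[g] = min(tied, key=lambda k: (order.get(fit.labels[k], 99), k))
    out = pd.DataFrame(
        {
            "gene_id": fit.gene_ids,
            "component": best,
            "max_responsibility": maxr,
        }
    )
    if fit.labels is not None:
        out["label"] = [fit.labels[k] for k in best]
    return out
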