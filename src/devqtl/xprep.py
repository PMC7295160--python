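"""Expression preparation: normalization, filtering, and adjustment.

Stages, in the documented order: raw counts -> CPM -> log2 CPM
(pseudocounted, voom-style) -> adjusted (hidden-factor residual-PCA
removal, with period and sex signal retained). Also houses the
PCA/covariate variance partition, expression-based sex inference, and
epoch-3-vs-epoch-1 delta statistics.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "compute_cpm",
    "compute_log2cpm",
    "filter_expressed",
    "adjust_expression",
    "pca_variance_partition",
    "infer_sex",
    "epoch_delta",
    "DEFAULT_SEX_MARKERS",
]

# XIST is female-high; the remainder are chrY genes, male-high.
DEFAULT_SEX_MARKERS = {
    "female_high": ["XIST"],
    "male_high": [
        "RPS4Y1", "DDX3Y", "KDM5D", "UTY", "USP9Y", "EIF1AY", "NLGN4Y",
        "ZFY", "TMSB4Y", "PRKY", "TXLNGY", "KDM5DP1", "TTTY14", "RPS4Y2",
        "PCDH11Y", "TBL1Y", "AMELY", "SRY",
    ],
}


def compute_cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts per million without pseudocount (used for the expressed filter)."""
    libsize = counts.sum(axis=0)
    _check_counts(counts, libsize)
    return counts / libsize * 1e6


def compute_log2cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Pseudocounted log2 CPM: log2((c + 0.5) / (L + 1) * 1e6).

    The +0.5/+1 offsets keep zero counts finite while leaving large
    counts essentially untouched; this is the convention the limma voom
    transform uses.
    """
    libsize = counts.sum(axis=0)
    _check_counts(counts, libsize)
    return np.log2((counts + 0.5) / (libsize + 1.0) * 1e6)


def _check_counts(counts: pd.DataFrame, libsize: pd.Series) -> None:
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    zero = libsize[libsize == 0]
    if len(zero):
        raise ValueError(f"all-zero sample(s): {list(zero.index)}")


def filter_expressed(
    cpm: pd.DataFrame,
    sample_table: pd.DataFrame,
    cpm_min: float = 1.0,
    fraction: float = 0.5,
) -> list[str]:
    """Genes with CPM >= cpm_min in >= fraction of samples of any one sex
    in any one period.

    The fraction test is exact (count/denominator >= fraction, so 3 of 6
    passes at 0.5); sex-period strata with no samples are skipped.
    """
    st = sample_table.set_index("sample_id").loc[cpm.columns]
    keep = np.zeros(len(cpm), dtype=bool)
    for (_, _), idx in st.groupby(["period", "sex"], observed=True).groups.items():
        cols = cpm[list(idx)]
        keep |= ((cols >= cpm_min).sum(axis=1) / cols.shape[1] >= fraction).to_numpy()
    return list(cpm.index[keep])


def _design_period_sex(sample_table: pd.DataFrame) -> np.ndarray:
    period = pd.get_dummies(sample_table["period"].astype("category"), drop_first=True)
    sex = (sample_table["sex"] == "male").astype(float)
    X = np.column_stack([np.ones(len(sample_table)), period.to_numpy(float), sex.to_numpy()])
    return X


def adjust_expression(
    log2cpm: pd.DataFrame,
    sample_table: pd.DataFrame,
    n_hidden: int,
) -> pd.DataFrame:
    """Remove hidden technical structure by residual PCA.

    Each gene is regressed on developmental period (categorical) and sex;
    the top ``n_hidden`` principal components of the residual matrix are
    reconstructed and subtracted from log2 CPM. Period and sex signal is
    deliberately retained — those covariates re-enter the eQTL model
    downstream.
    """
    if n_hidden < 0:
        raise ValueError("n_hidden must be >= 0")
    if n_hidden == 0:
        return log2cpm.copy()
    if n_hidden >= min(log2cpm.shape):
        raise ValueError("n_hidden must be < min(n_genes, n_samples)")
    st = sample_table.set_index("sample_id").loc[log2cpm.columns].reset_index()
    X = _design_period_sex(st)
    Y = log2cpm.to_numpy(float)
    beta, *_ = np.linalg.lstsq(X, Y.T, rcond=None)
    resid = Y - (X @ beta).T
    # sample-space PCs of the residual matrix; subtract their reconstruction
    U, s, Vt = np.linalg.svd(resid, full_matrices=False)
    recon = (U[:, :n_hidden] * s[:n_hidden]) @ Vt[:n_hidden]
    return pd.DataFrame(Y - recon, index=log2cpm.index, columns=log2cpm.columns)


def pca_variance_partition(
    log2cpm: pd.DataFrame,
    covariates: pd.DataFrame,
    n_pcs: int = 10,
) -> pd.DataFrame:
    """Partial R^2 of each covariate with each expression PC.

    PCs are computed from the centered log2 CPM matrix with samples as
    observations. For covariate c and PC j, partial R^2 compares the
    full linear model (all covariates) to the model with c removed:
    (SSE_reduced - SSE_full) / SSE_reduced. Categorical covariates are
    dummy-expanded as a block.
    """
    Y = log2cpm.to_numpy(float).T  # samples x genes
    Y = Y - Y.mean(axis=0)
    U, s, _ = np.linalg.svd(Y, full_matrices=False)
    n_pcs = min(n_pcs, len(s))
    scores = U[:, :n_pcs] * s[:n_pcs]
    var_frac = s**2 / np.sum(s**2)

    blocks: dict[str, np.ndarray] = {}
    for name in covariates.columns:
        col = covariates[name]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            blocks[name] = pd.get_dummies(col, drop_first=True).to_numpy(float)
        else:
            blocks[name] = col.to_numpy(float)[:, None]
    full = np.column_stack([np.ones(len(covariates))] + list(blocks.values()))
    rank = np.linalg.matrix_rank(full)
    if rank < full.shape[1]:
        aliased = _aliased_columns(full, list(blocks))
        raise ValueError(f"collinear covariates: {aliased}")

    rows = []
    for j in range(n_pcs):
        y = scores[:, j]
        sse_full = _sse(full, y)
        row = {"pc": j + 1, "variance_fraction": float(var_frac[j])}
        for name in blocks:
            cols = [np.ones(len(covariates))] + [blocks[k] for k in blocks if k != name]
            reduced = np.column_stack(cols)
            sse_red = _sse(reduced, y)
            row[name] = float((sse_red - sse_full) / sse_red) if sse_red > 0 else 0.0
        rows.append(row)
    return pd.DataFrame(rows)


def _sse(X: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def _aliased_columns(X: np.ndarray, names: list[str]) -> list[str]:
    kept: list[int] = [0]
    aliased = []
    # greedy rank check over covariate blocks (column 0 is the intercept)
    for i in range(1, X.shape[1]):
        trial = X[:, kept + [i]]
        if np.linalg.matrix_rank(trial) == len(kept) + 1:
            kept.append(i)
        else:
            aliased.append(i)
    # map column indices back to covariate names coarsely
    return names if not aliased else [names[min(len(names) - 1, a - 1)] for a in aliased]


def _two_means_threshold(values: np.ndarray) -> float:
    """Midpoint of the two means from 1-D 2-means clustering (exact scan)."""
    x = np.sort(values)
    best, thr = np.inf, x.mean()
    for cut in range(1, len(x)):
        lo, hi = x[:cut], x[cut:]
        ss = ((lo - lo.mean()) ** 2).sum() + ((hi - hi.mean()) ** 2).sum()
        if ss < best:
            best = ss
            thr = (lo.mean() + hi.mean()) / 2.0
    return float(thr)


def infer_sex(
    log2cpm: pd.DataFrame,
    marker_config: dict | None = None,
) -> pd.DataFrame:
    """Call sample sex from sex-linked marker expression.

    Each available marker gene splits samples at the midpoint of its two
    1-D 2-means cluster centers; female-high markers (XIST) vote female
    above threshold, male-high (chrY) vote male above threshold. The
    call is the majority vote; a sample is flagged ambiguous when the
    minority vote share reaches 25%, and single_marker when only one
    marker was available.
    """
    cfg = marker_config if marker_config is not None else DEFAULT_SEX_MARKERS
    markers = [(g, "female") for g in cfg.get("female_high", []) if g in log2cpm.index]
    markers += [(g, "male") for g in cfg.get("male_high", []) if g in log2cpm.index]
    if not markers:
        raise ValueError("no sex marker genes present in the expression matrix")
    votes_female = np.zeros(log2cpm.shape[1])
    for gene, high_sex in markers:
        v = log2cpm.loc[gene].to_numpy(float)
        thr = _two_means_threshold(v)
        high = v > thr
        votes_female += high if high_sex == "female" else ~high
    n_markers = len(markers)
    frac_female = votes_female / n_markers
    call = np.where(frac_female > 0.5, "female", "male")
    minority = np.minimum(frac_female, 1 - frac_female)
    return pd.DataFrame(
        {
            "sample_id": log2cpm.columns,
            "sex_call": call,
            "female_vote_fraction": frac_female,
            "ambiguous": minority >= 0.25,
            "single_marker": n_markers == 1,
            "n_markers": n_markers,
        }
    )


def epoch_delta(
    log2cpm: pd.DataFrame,
    sample_table: pd.DataFrame,
    floor: float = -5.0,
) -> pd.DataFrame:
    """Per-gene epoch-3 minus epoch-1 median log2 CPM with specificity flags.

    A gene is epoch3_specific when essentially unexpressed in epoch 1
    (median <= floor) while expressed in epoch 3, and vice versa.
    """
    st = sample_table.set_index("sample_id").loc[log2cpm.columns]
    e1 = log2cpm.loc[:, (st["epoch"] == 1).to_numpy()]
    e3 = log2cpm.loc[:, (st["epoch"] == 3).to_numpy()]
    if e1.shape[1] == 0 or e3.shape[1] == 0:
        raise ValueError("cohort lacks epoch-1 or epoch-3 samples")
    m1 = e1.median(axis=1)
    m3 = e3.median(axis=1)
    return pd.DataFrame(
        {
            "gene_id": log2cpm.index,
            "median_epoch1": m1.to_numpy(),
            "median_epoch3": m3.to_numpy(),
            "delta": (m3 - m1).to_numpy(),
            "epoch3_specific": ((m1 <= floor) & (m3 > floor)).to_numpy(),
            "epoch1_specific": ((m3 <= floor) & (m1 > floor)).to_numpy(),
        }
    )
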