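"""Cis-eQTL mapping on developmental sample cuts.

Associations are ordinary least squares of adjusted expression on
alt-allele dosage with developmental period (categorical), sex, and
five ancestry principal components as covariates, run separately on
three cuts of the cohort: complete (all periods), prenatal (periods
1-6), and postnatal (periods 8-12). Benjamini-Hochberg FDR is computed
within each cut over all tested pairs.

The scan uses Frisch-Waugh-Lovell residualization: expression and
dosage are projected off the covariate design once per cut, after which
each pair's beta, SE and t-test are closed-form dot products — exactly
equal to the full-design OLS coefficients.

Also here: the variant frequency/HWE filter, cis-pair enumeration,
TSS distances, and the genomic-control lambda procedure on distant
(10-100 Mb) same-chromosome gene-variant pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CUTS",
    "cut_mask",
    "filter_variants",
    "cis_pairs",
    "scan",
    "bh_fdr",
    "tss_distance",
    "genomic_control",
    "LambdaResult",
    "CHI2_1_MEDIAN",
]

CUTS = ("complete", "prenatal", "postnatal")

# median of the chi-square distribution with 1 df
CHI2_1_MEDIAN = float(stats.chi2.median(1))


def cut_mask(sample_table: pd.DataFrame, cut: str) -> np.ndarray:
    """Boolean sample mask for a cut: complete = all samples, prenatal =
    periods 1-6, postnatal = periods 8-12 (period 7 is in neither subset)."""
    period = sample_table["period"].to_numpy()
    if cut == "complete":
        return np.ones(len(sample_table), dtype=bool)
    if cut == "prenatal":
        return (period >= 1) & (period <= 6)
    if cut == "postnatal":
        return (period >= 8) & (period <= 12)
    raise ValueError(f"unknown cut {cut!r}; expected one of {CUTS}")


def filter_variants(
    variants: pd.DataFrame,
    dosage: np.ndarray,
    sample_table: pd.DataFrame,
    maf_min: float = 0.05,
    hwe_p_min: float = 1e-12,
) -> pd.DataFrame:
    """Keep variants common in BOTH the prenatal and postnatal subsets and
    consistent with Hardy-Weinberg equilibrium on the full cohort.

    MAF is recomputed from the dosage matrix on each subset; the HWE
    p-value is taken from the ``hwe_p`` column (an exact test on all
    samples).
    """
    from .simgen import hwe_exact_test

    pre = cut_mask(sample_table, "prenatal")
    post = cut_mask(sample_table, "postnatal")
    if pre.sum() < 2 or post.sum() < 2:
        raise ValueError("prenatal and postnatal subsets each need >= 2 samples")

    def _maf(mask):
        f = dosage[:, mask].mean(axis=1) / 2.0
        return np.minimum(f, 1 - f)

    if "hwe_p" in variants.columns:
        hwe_p = variants["hwe_p"].to_numpy(float)
    else:
        hwe_p = np.array([
            hwe_exact_test(int((row == 1).sum()),
                           int((row == 2).sum()), int((row == 0).sum()))
            for row in dosage
        ])
    keep = (_maf(pre) >= maf_min) & (_maf(post) >= maf_min) & (hwe_p >= hwe_p_min)
    out = variants.loc[keep].copy()
    out["maf_pre"] = _maf(pre)[keep]
    out["maf_post"] = _maf(post)[keep]
    return out


def cis_pairs(
    variants: pd.DataFrame,
    gene_annotation: pd.DataFrame,
    window: int = 1_000_000,
) -> pd.DataFrame:
    """Enumerate (gene, variant) pairs with the variant within ``window``
    of the gene boundaries: start - window <= pos < end + window
    (0-based half-open), same chromosome."""
    rows = []
    for chrom, vgrp in variants.groupby("chrom", sort=False):
        genes = gene_annotation[gene_annotation["chrom"] == chrom]
        pos = vgrp["pos"].to_numpy()
        order = np.argsort(pos)
        pos_sorted = pos[order]
        vid = vgrp["variant_id"].to_numpy()[order]
        for _, g in genes.iterrows():
            lo = np.searchsorted(pos_sorted, g["start"] - window, side="left")
            hi = np.searchsorted(pos_sorted, g["end"] + window, side="left")
            for v in vid[lo:hi]:
                rows.append((g["gene_id"], v))
    return pd.DataFrame(rows, columns=["gene_id", "variant_id"])


@dataclass
class _Residualizer:
    """Covariate projection for one cut, shared across pairs."""

    mask: np.ndarray
    q: np.ndarray       # orthonormal basis of the covariate design
    df_resid: int       # n - rank(design) - 1 (the dosage term)

    def residualize(self, M: np.ndarray) -> np.ndarray:
        """Project rows of M (features x samples-in-cut) off the design."""
        return M - (M @ self.q) @ self.q.T


def _make_residualizer(sample_table: pd.DataFrame, cut: str) -> _Residualizer:
    mask = cut_mask(sample_table, cut)
    st = sample_table.loc[mask]
    period = pd.get_dummies(st["period"].astype("category"), drop_first=True)
    cols = [np.ones(mask.sum()), period.to_numpy(float),
            (st["sex"] == "male").to_numpy(float)[:, None],
            st[[f"pc{i}" for i in range(1, 6)]].to_numpy(float)]
    X = np.column_stack(cols)
    q, r = np.linalg.qr(X)
    rank = int(np.sum(np.abs(np.diag(r)) > np.abs(r).max() * 1e-10 * max(X.shape)))
    if rank < X.shape[1]:
        d = np.abs(np.diag(r))
        aliased = np.flatnonzero(d <= d.max() * 1e-10 * max(X.shape))
        raise np.linalg.LinAlgError(
            f"rank-deficient covariate design in cut {cut!r}; aliased columns {aliased.tolist()}"
        )
    df = mask.sum() - X.shape[1] - 1
    if df <= 0:
        raise ValueError(f"cut {cut!r} has no residual degrees of freedom")
    return _Residualizer(mask=mask, q=q, df_resid=df)


def scan(
    adjusted_expr: pd.DataFrame,
    dosage: np.ndarray,
    variants: pd.DataFrame,
    sample_table: pd.DataFrame,
    pairs: pd.DataFrame,
    cut: str,
) -> pd.DataFrame:
    """Per-pair OLS association statistics for one sample cut.

    Returns pairs with beta (dosage coefficient, per alt allele), se,
    two-sided t-test p, fdr (BH within the cut over tested pairs) and n.
    Pairs whose dosage is constant within the cut get NaN statistics and
    are excluded from the FDR family.
    """
    rz = _make_residualizer(sample_table, cut)
    sample_ids = sample_table["sample_id"].to_numpy()[rz.mask]
    E = adjusted_expr[sample_ids].to_numpy(float)
    G = dosage[:, rz.mask].astype(float)

    gene_pos = pd.Index(adjusted_expr.index).get_indexer(pairs["gene_id"])
    var_pos = pd.Index(variants["variant_id"]).get_indexer(pairs["variant_id"])
    if (gene_pos < 0).any() or (var_pos < 0).any():
        raise KeyError("pairs reference genes or variants absent from the inputs")

    Er = rz.residualize(E)
    Gr = rz.residualize(G)
    gss = np.einsum("vs,vs->v", Gr, Gr)
    ess = np.einsum("gs,gs->g", Er, Er)

    beta = np.full(len(pairs), np.nan)
    se = np.full(len(pairs), np.nan)
    constant = G.std(axis=1) == 0

    # group pairs by variant for cache-friendly dot products
    for v in np.unique(var_pos):
        sel = np.flatnonzero(var_pos == v)
        if constant[v] or gss[v] <= 0:
            continue
        gi = gene_pos[sel]
        num = Er[gi] @ Gr[v]
        b = num / gss[v]
        rss = ess[gi] - b * num
        s2 = np.maximum(rss, 0.0) / rz.df_resid
        beta[sel] = b
        se[sel] = np.sqrt(s2 / gss[v])

    with np.errstate(invalid="ignore", divide="ignore"):
        t = beta / se
    p = 2.0 * stats.t.sf(np.abs(t), rz.df_resid)
    out = pairs.copy()
    out["beta"] = beta
    out["se"] = se
    out["p"] = p
    out["n"] = int(rz.mask.sum())
    fdr = np.full(len(out), np.nan)
    tested = np.isfinite(p)
    if tested.any():
        fdr[tested] = bh_fdr(p[tested])
    out["fdr"] = fdr
    return out


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def tss_distance(variant_pos: int, gene: pd.Series | dict, variant_chrom: str | None = None) -> int:
    """Signed distance from the gene's TSS to the variant, oriented by
    strand: positive downstream of the TSS, negative upstream."""
    if variant_chrom is not None and variant_chrom != gene["chrom"]:
        raise ValueError("variant and gene are on different chromosomes")
    d = int(variant_pos) - int(gene["tss"])
    return d if gene["strand"] == "+" else -d


@dataclass
class LambdaResult:
    """Genomic-control inflation estimates for one cut."""

    cut: str
    lambdas: np.ndarray   # one per repetition
    median: float


def lambda_from_pvalues(p: np.ndarray) -> float:
    """Genomic-control lambda: median chi-square(1) quantile of the
    p-values over the chi-square(1) median (~0.4549)."""
    p = np.asarray(p, dtype=float)
    p = p[np.isfinite(p)]
    chi2 = stats.chi2.isf(p, 1)
    return float(np.median(chi2) / CHI2_1_MEDIAN)


def genomic_control(
    adjusted_expr: pd.DataFrame,
    dosage: np.ndarray,
    variants: pd.DataFrame,
    sample_table: pd.DataFrame,
    gene_annotation: pd.DataFrame,
    cut: str = "complete",
    n_pairs: int = 500,
    n_reps: int = 100,
    min_dist: int = 10_000_000,
    max_dist: int = 100_000_000,
    seed: int = 0,
) -> LambdaResult:
    """Lambda from repeated random draws of distant gene-variant pairs.

    Distant pairs share a chromosome with TSS-to-variant distance in
    [min_dist, max_dist]; such pairs should carry no true cis signal, so
    a well-calibrated scan gives lambda near 1. Each repetition samples
    ``n_pairs`` pairs without replacement, scans them on the requested
    cut, and converts the p-values to a lambda; the median over
    repetitions is the headline number.
    """
    genes = gene_annotation[gene_annotation["gene_id"].isin(adjusted_expr.index)]
    vid_by_chrom = {}
    for chrom, vgrp in variants.groupby("chrom", sort=False):
        pos = vgrp["pos"].to_numpy()
        order = np.argsort(pos)
        vid_by_chrom[chrom] = (pos[order], vgrp["variant_id"].to_numpy()[order])

    gene_rows = []
    for _, g in genes.iterrows():
        if g["chrom"] not in vid_by_chrom:
            continue
        pos_sorted, vids = vid_by_chrom[g["chrom"]]
        tss = g["tss"]
        l1 = np.searchsorted(pos_sorted, tss - max_dist, side="left")
        h1 = np.searchsorted(pos_sorted, tss - min_dist, side="right")
        l2 = np.searchsorted(pos_sorted, tss + min_dist, side="left")
        h2 = np.searchsorted(pos_sorted, tss + max_dist, side="right")
        count = (h1 - l1) + (h2 - l2)
        if count > 0:
            gene_rows.append((g["gene_id"], g["chrom"], l1, h1, l2, h2, count))
    total = sum(r[-1] for r in gene_rows)
    if total < n_pairs:
        raise ValueError(f"only {total} eligible distant pairs; need {n_pairs}")

    counts = np.array([r[-1] for r in gene_rows], dtype=float)
    cum = np.concatenate([[0], np.cumsum(counts)]).astype(int)
    rng = np.random.default_rng(seed)
    lambdas = np.empty(n_reps)
    for rep in range(n_reps):
        flat = rng.choice(total, size=n_pairs, replace=False)
        rows = []
        gidx = np.searchsorted(cum, flat, side="right") - 1
        for f, gi in zip(flat, gidx):
            gene_id, chrom, l1, h1, l2, h2, _c = gene_rows[gi]
            off = int(f - cum[gi])
            pos_sorted, vids = vid_by_chrom[chrom]
            vi = l1 + off if off < (h1 - l1) else l2 + (off - (h1 - l1))
            rows.append((gene_id, vids[vi]))
        pairs = pd.DataFrame(rows, columns=["gene_id", "variant_id"])
        res = scan(adjusted_expr, dosage, variants, sample_table, pairs, cut)
        lambdas[rep] = lambda_from_pvalues(res["p"].to_numpy())
    return LambdaResult(cut=cut, lambdas=lambdas, median=float(np.median(lambdas)))
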