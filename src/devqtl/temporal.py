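"""Temporal-predominance classification of eQTLs and eGenes.

For each eGene the top FDR-significant variant (smallest significant p
across the complete/prenatal/postnatal scans) is compared between
stages with a Z-test on the prenatal and postnatal regression
coefficients,

    Z = (beta_pre - beta_post) / sqrt(se_pre^2 + se_post^2),

and the pair is assigned to one of five mutually exclusive categories:
constant, prenatal-predominant, postnatal-predominant, and the two
trending fall-throughs. All of a gene's significant pairs inherit the
top pair's category. Alternative assignment schemes (majority vote,
second variant, individual pairs) quantify how stable the labels are.

Also here: the prenatal-vs-postnatal differential expression variance
F-test.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .eqtl import bh_fdr, cut_mask

__all__ = [
    "CATEGORIES",
    "merge_cuts",
    "select_top",
    "z_test",
    "classify",
    "classify_table",
    "propagate",
    "alternative_assignments",
    "variance_f_test",
]

CATEGORIES = (
    "constant",
    "prenatal_predominant",
    "postnatal_predominant",
    "prenatal_trending",
    "postnatal_trending",
)

# tie order for the majority-vote alternative assignment
MAJORITY_TIE_ORDER = CATEGORIES


def merge_cuts(complete: pd.DataFrame, prenatal: pd.DataFrame, postnatal: pd.DataFrame) -> pd.DataFrame:
    """Join the three per-cut scan tables on (gene_id, variant_id) into one
    wide record table with suffixed columns."""
    keys = ["gene_id", "variant_id"]
    out = complete[keys + ["beta", "se", "p", "fdr", "n"]].rename(
        columns=lambda c: c if c in keys else f"{c}_complete"
    )
    for name, df in (("pre", prenatal), ("post", postnatal)):
        out = out.merge(
            df[keys + ["beta", "se", "p", "fdr", "n"]].rename(
                columns=lambda c: c if c in keys else f"{c}_{name}"
            ),
            on=keys,
            how="outer",
        )
    return out


def _min_significant(rec: pd.DataFrame, alpha: float) -> pd.Series:
    """Smallest FDR-significant p across the three cuts (NaN if none)."""
    ps = np.full(len(rec), np.nan)
    for cut in ("complete", "pre", "post"):
        p = rec[f"p_{cut}"].to_numpy(float)
        f = rec[f"fdr_{cut}"].to_numpy(float)
        sig = np.isfinite(f) & (f <= alpha)
        ps = np.where(sig & (~np.isfinite(ps) | (p < ps)), p, ps)
    return pd.Series(ps, index=rec.index, name="min_sig_p")


def select_top(records: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """One pair per eGene: the FDR-significant pair with the smallest
    significant p from any cut.

    ``records`` must carry a ``tss_dist`` column for the tie-break:
    exact p ties go to the smaller |TSS distance|, then lexicographic
    variant_id. Genes with no significant pair are absent from the
    output.
    """
    rec = records.copy()
    rec["min_sig_p"] = _min_significant(rec, alpha)
    rec = rec[np.isfinite(rec["min_sig_p"])]
    if len(rec) == 0:
        return rec
    rec["_absd"] = rec["tss_dist"].abs() if "tss_dist" in rec else 0
    rec = rec.sort_values(["gene_id", "min_sig_p", "_absd", "variant_id"],
                          kind="mergesort")
    top = rec.groupby("gene_id", as_index=False).head(1).drop(columns="_absd")
    return top.reset_index(drop=True)


def z_test(beta_pre, se_pre, beta_post, se_post) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided Z-test comparing prenatal and postnatal coefficients."""
    se_pre = np.asarray(se_pre, dtype=float)
    se_post = np.asarray(se_post, dtype=float)
    if np.any(se_pre <= 0) or np.any(se_post <= 0):
        raise ValueError("standard errors must be positive")
    z = (np.asarray(beta_pre, float) - np.asarray(beta_post, float)) / np.sqrt(
        se_pre**2 + se_post**2
    )
    return z, 2.0 * stats.norm.sf(np.abs(z))


def classify(
    fdr_complete: float,
    p_pre: float,
    fdr_pre: float,
    beta_pre: float,
    p_post: float,
    fdr_post: float,
    beta_post: float,
    z_fdr: float,
    alpha: float = 0.05,
) -> str:
    """Assign one pair to a temporal category; rules evaluated in order.

    constant: complete-cut FDR <= alpha, same-signed point estimates and
    unadjusted p <= alpha in both subset cuts. prenatal_predominant:
    prenatal FDR <= alpha, postnatal p > alpha, Z-test FDR <= alpha
    (postnatal_predominant mirrored). Anything else trends toward the
    stage with the larger coefficient; exact ties go postnatal.
    """
    for v in (fdr_complete, p_pre, p_post, beta_pre, beta_post):
        if v is None or not np.isfinite(v):
            raise ValueError("classification requires statistics from all three cuts")
    same_sign = np.sign(beta_pre) == np.sign(beta_post)
    if fdr_complete <= alpha and same_sign and p_pre <= alpha and p_post <= alpha:
        return "constant"
    if np.isfinite(fdr_pre) and fdr_pre <= alpha and p_post > alpha \
            and np.isfinite(z_fdr) and z_fdr <= alpha:
        return "prenatal_predominant"
    if np.isfinite(fdr_post) and fdr_post <= alpha and p_pre > alpha \
            and np.isfinite(z_fdr) and z_fdr <= alpha:
        return "postnatal_predominant"
    return "prenatal_trending" if beta_pre > beta_post else "postnatal_trending"


def classify_table(top: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Classify a table of top pairs (adds z, z_p, z_fdr, category).

    The Z-test BH family is the set of top pairs being classified.
    """
    out = top.copy()
    z, zp = z_test(out["beta_pre"], out["se_pre"], out["beta_post"], out["se_post"])
    out["z"] = z
    out["z_p"] = zp
    out["z_fdr"] = bh_fdr(zp)
    out["category"] = [
        classify(
            r["fdr_complete"], r["p_pre"], r["fdr_pre"], r["beta_pre"],
            r["p_post"], r["fdr_post"], r["beta_post"], r["z_fdr"], alpha,
        )
        for _, r in out.iterrows()
    ]
    return out


def propagate(gene_categories: pd.DataFrame, records: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Label every FDR-significant pair with its gene's category.

    Pairs of genes absent from ``gene_categories`` (no significant top
    pair) are left out.
    """
    rec = records.copy()
    rec["min_sig_p"] = _min_significant(rec, alpha)
    sig = rec[np.isfinite(rec["min_sig_p"])]
    cat = gene_categories.set_index("gene_id")["category"]
    out = sig[sig["gene_id"].isin(cat.index)].copy()
    out["category"] = out["gene_id"].map(cat).to_numpy()
    return out.reset_index(drop=True)


def _classify_individual(sig: pd.DataFrame, alpha: float) -> pd.Series:
    """Classify each significant pair on its own statistics (Z-test BH
    family = all pairs being classified)."""
    z, zp = z_test(sig["beta_pre"], sig["se_pre"], sig["beta_post"], sig["se_post"])
    zf = bh_fdr(zp)
    cats = [
        classify(r["fdr_complete"], r["p_pre"], r["fdr_pre"], r["beta_pre"],
                 r["p_post"], r["fdr_post"], r["beta_post"], zfi, alpha)
        for (_, r), zfi in zip(sig.iterrows(), zf)
    ]
    return pd.Series(cats, index=sig.index, name="category")


def alternative_assignments(
    records: pd.DataFrame,
    gene_categories: pd.DataFrame,
    alpha: float = 0.05,
) -> dict[str, pd.DataFrame]:
    """Three alternative eGene labelings and their concordance with the
    top-variant labels.

    majority: each gene takes the modal category of its individually
    classified significant pairs, ties broken in the order constant,
    prenatal_predominant, postnatal_predominant, prenatal_trending,
    postnatal_trending. second: label of the gene's second most
    significant pair (genes with a single pair reported separately).
    individual: the per-pair labels themselves. Each concordance table
    cross-tabulates top-variant category (rows, as percentages) against
    the alternative.
    """
    rec = records.copy()
    rec["min_sig_p"] = _min_significant(rec, alpha)
    sig = rec[np.isfinite(rec["min_sig_p"])].copy()
    sig = sig[sig["gene_id"].isin(gene_categories["gene_id"])]
    sig["category"] = _classify_individual(sig, alpha)
    top_cat = gene_categories.set_index("gene_id")["category"]

    order = {c: i for i, c in enumerate(MAJORITY_TIE_ORDER)}

    def _majority(group: pd.Series) -> str:
        counts = group.value_counts()
        best = counts.max()
        tied = [c for c in counts.index if counts[c] == best]
        return min(tied, key=lambda c: order[c])

    majority = sig.groupby("gene_id")["category"].apply(_majority).rename("majority")

    sig_sorted = sig.sort_values(["gene_id", "min_sig_p", "variant_id"], kind="mergesort")
    second_rows = sig_sorted.groupby("gene_id").nth(1)
    second = second_rows.set_index("gene_id")["category"].rename("second") \
        if len(second_rows) else pd.Series(dtype=object, name="second")
    singletons = sorted(set(sig["gene_id"]) - set(second.index))

    def _concordance(alt: pd.Series) -> pd.DataFrame:
        df = pd.DataFrame({"top": top_cat.reindex(alt.index), "alt": alt})
        tab = pd.crosstab(df["top"], df["alt"])
        return tab.div(tab.sum(axis=1), axis=0) * 100.0

    individual = sig.set_index("gene_id")["category"]
    top_per_pair = sig["gene_id"].map(top_cat)
    pair_tab = pd.crosstab(top_per_pair, sig["category"])
    pair_tab = pair_tab.div(pair_tab.sum(axis=1), axis=0) * 100.0

    return {
        "majority": majority.to_frame(),
        "second": second.to_frame(),
        "second_skipped": pd.DataFrame({"gene_id": singletons}),
        "individual": individual.to_frame(),
        "concordance_majority": _concordance(majority),
        "concordance_second": _concordance(second) if len(second) else pd.DataFrame(),
        "concordance_individual": pair_tab,
    }


def variance_f_test(
    log2cpm: pd.DataFrame,
    sample_table: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-gene F-test comparing prenatal and postnatal residual variance.

    Within each stage, expression is residualized on period
    (categorical), sex, and five ancestry PCs; F = var_pre / var_post
    with the stages' residual degrees of freedom, two-sided p by
    doubling the smaller tail, BH across genes. ``direction`` marks
    which variance is larger for genes at FDR <= alpha.
    """
    res = {}
    dfs = {}
    for cutname, stage in (("prenatal", "pre"), ("postnatal", "post")):
        mask = cut_mask(sample_table, cutname)
        st = sample_table.loc[mask]
        period = pd.get_dummies(st["period"].astype("category"), drop_first=True)
        X = np.column_stack([
            np.ones(mask.sum()), period.to_numpy(float),
            (st["sex"] == "male").to_numpy(float),
            st[[f"pc{i}" for i in range(1, 6)]].to_numpy(float),
        ])
        rank = np.linalg.matrix_rank(X)
        df = int(mask.sum() - rank)
        if df <= 0:
            raise ValueError(f"{cutname} stage has no residual degrees of freedom")
        ids = sample_table["sample_id"].to_numpy()[mask]
        Y = log2cpm[ids].to_numpy(float)
        q, _ = np.linalg.qr(X)
        R = Y - (Y @ q) @ q.T
        res[stage] = np.einsum("gs,gs->g", R, R) / df
        dfs[stage] = df
    F = res["pre"] / res["post"]
    cdf = stats.f.cdf(F, dfs["pre"], dfs["post"])
    p = 2.0 * np.minimum(cdf, 1.0 - cdf)
    p = np.minimum(p, 1.0)
    fdr = bh_fdr(p)
    sig = fdr <= alpha
    direction = np.where(~sig, "ns", np.where(F > 1, "greater_prenatal", "greater_postnatal"))
    return pd.DataFrame(
        {
            "gene_id": log2cpm.index,
            "var_pre": res["pre"],
            "var_post": res["post"],
            "F": F,
            "p": p,
            "fdr": fdr,
            "direction": direction,
        }
    )
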