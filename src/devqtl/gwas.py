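"""GWAS integration: enrichment, colocalization, and gene-set tests.

The enrichment test asks whether genome-wide-significant GWAS SNPs are
eQTLs more often than chance allows, against a null that respects LD
(supervised pruning), minor-allele frequency, and local gene density:
each GWAS SNP is repeatedly swapped for a random SNP from the same
(MAF decile, gene-density decile) bin and the fold enrichment is
compared with the permuted distribution.

Colocalization evaluates, per locus, five hypotheses about a GWAS
trait and an eQTL sharing a causal variant, combining per-SNP Wakefield
approximate Bayes factors into posterior probabilities PP0-PP4.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

from .eqtl import bh_fdr

__all__ = [
    "ld_r2_from_dosage",
    "match_to_tested",
    "supervised_prune",
    "bin_variants",
    "permutation_enrichment",
    "EnrichmentResult",
    "coloc",
    "ColocResult",
    "gene_set_fet",
]


def ld_r2_from_dosage(dosage: np.ndarray, variants: pd.DataFrame,
                      max_dist: int = 1_000_000) -> pd.DataFrame:
    """Pairwise genotype r^2 table for variants within ``max_dist`` on the
    same chromosome (columns a, b, r2; a < b by position)."""
    rows = []
    for chrom, grp in variants.reset_index(drop=True).groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        pos = grp["pos"].to_numpy()
        order = np.argsort(pos)
        idx, pos = idx[order], pos[order]
        G = dosage[idx].astype(float)
        sd = G.std(axis=1)
        for i in range(len(idx)):
            j = i + 1
            while j < len(idx) and pos[j] - pos[i] <= max_dist:
                if sd[i] > 0 and sd[j] > 0:
                    r = np.corrcoef(G[i], G[j])[0, 1]
                    rows.append((grp["variant_id"].iloc[order[i]],
                                 grp["variant_id"].iloc[order[j]], float(r**2)))
                j += 1
    return pd.DataFrame(rows, columns=["a", "b", "r2"])


class _LdLookup:
    """Symmetric r^2 lookup from a pair table."""

    def __init__(self, pairs: pd.DataFrame):
        self._map: dict[str, dict[str, float]] = {}
        for a, b, r2 in pairs[["a", "b", "r2"]].itertuples(index=False):
            self._map.setdefault(a, {})[b] = r2
            self._map.setdefault(b, {})[a] = r2

    def partners(self, snp: str) -> dict[str, float]:
        return self._map.get(snp, {})

    def r2(self, a: str, b: str) -> float:
        return self._map.get(a, {}).get(b, 0.0)


def match_to_tested(
    gwas_snps,
    tested_variants,
    ld_pairs: pd.DataFrame,
    r2_min: float = 0.8,
) -> pd.DataFrame:
    """Map GWAS SNPs onto the eQTL-tested variant universe.

    A SNP tested directly is kept as itself; otherwise its best proxy
    with r^2 > r2_min among tested variants substitutes. SNPs with no
    direct or proxy match are dropped (counted in the ``provenance``
    column values: direct / proxy; dropped SNPs are absent).
    """
    tested = set(tested_variants)
    ld = _LdLookup(ld_pairs) if len(ld_pairs) else _LdLookup(pd.DataFrame(columns=["a", "b", "r2"]))
    rows = []
    for snp in gwas_snps:
        if snp in tested:
            rows.append({"gwas_snp": snp, "matched": snp, "provenance": "direct", "r2": 1.0})
            continue
        best, best_r2 = None, r2_min
        for partner, r2 in ld.partners(snp).items():
            if partner in tested and r2 > best_r2:
                best, best_r2 = partner, r2
        if best is not None:
            rows.append({"gwas_snp": snp, "matched": best, "provenance": "proxy", "r2": best_r2})
    return pd.DataFrame(rows, columns=["gwas_snp", "matched", "provenance", "r2"])


def supervised_prune(
    snps: pd.DataFrame,
    ld_pairs: pd.DataFrame,
    r2_max: float = 0.7,
    window: int = 500_000,
) -> list[str]:
    """Greedy LD pruning supervised by GWAS p-value.

    SNPs are processed in ascending p (position, then id, as the
    deterministic tie-break); a SNP is kept unless it has r^2 > r2_max
    with an already-kept SNP within ``window`` bp on the same
    chromosome. This preferentially retains the most strongly
    phenotype-associated SNP of each LD clump.

    ``snps`` needs columns variant_id, chrom, pos, p.
    """
    if snps["p"].isna().any():
        missing = snps.loc[snps["p"].isna(), "variant_id"].tolist()
        raise ValueError(f"missing GWAS p for SNP(s): {missing[:5]}")
    ld = _LdLookup(ld_pairs)
    ordered = snps.sort_values(["p", "pos", "variant_id"], kind="mergesort")
    kept: list[str] = []
    kept_pos: dict[str, list[tuple[int, str]]] = {}
    for vid, chrom, pos in ordered[["variant_id", "chrom", "pos"]].itertuples(index=False):
        clash = False
        for kpos, kid in kept_pos.get(chrom, []):
            if abs(kpos - pos) <= window and ld.r2(vid, kid) > r2_max:
                clash = True
                break
        if not clash:
            kept.append(vid)
            kept_pos.setdefault(chrom, []).append((int(pos), vid))
    return kept


def bin_variants(
    variants: pd.DataFrame,
    gene_annotation: pd.DataFrame,
    window: int = 1_000_000,
    n_bins: int = 10,
    exclude_regions: list[tuple[str, int, int]] | None = None,
) -> pd.DataFrame:
    """(MAF decile, gene-density decile) per variant.

    Gene density is the number of genes whose cis window (gene
    boundaries +- ``window``) contains the variant. Deciles are
    empirical quantile bins over the whole tested-variant universe
    after removing configured excluded regions (e.g. an HLA analogue);
    when fewer than ``n_bins`` distinct values exist the bins are
    coarser (duplicate edges merged).
    """
    v = variants.copy()
    if exclude_regions:
        drop = np.zeros(len(v), dtype=bool)
        for chrom, lo, hi in exclude_regions:
            drop |= ((v["chrom"] == chrom) & (v["pos"] >= lo) & (v["pos"] < hi)).to_numpy()
        v = v.loc[~drop]

    density = np.zeros(len(v), dtype=int)
    for chrom, grp in v.groupby("chrom", sort=False):
        genes = gene_annotation[gene_annotation["chrom"] == chrom]
        if len(genes) == 0:
            continue
        starts = np.sort(genes["start"].to_numpy() - window)
        ends = np.sort(genes["end"].to_numpy() + window)
        pos = grp["pos"].to_numpy()
        # windows containing pos = (#starts <= pos) - (#ends <= pos)
        density[v.index.get_indexer(grp.index)] = (
            np.searchsorted(starts, pos, side="right")
            - np.searchsorted(ends, pos, side="right")
        )

    def _decile(x: np.ndarray) -> np.ndarray:
        ranked = pd.Series(x)
        try:
            return pd.qcut(ranked, n_bins, labels=False, duplicates="drop").to_numpy()
        except ValueError:
            return np.zeros(len(x), dtype=int)

    out = v[["variant_id"]].copy()
    out["maf_bin"] = _decile(v["maf"].to_numpy(float))
    out["density"] = density
    out["density_bin"] = _decile(density.astype(float))
    return out.reset_index(drop=True)


@dataclass
class EnrichmentResult:
    """Matched-permutation enrichment of an eQTL list in GWAS SNPs."""

    eqtl_list: str
    n_gwas_snps: int
    observed: float
    null_mean: float
    fold: float
    p: float
    n_perm: int


def permutation_enrichment(
    gwas_set,
    eqtl_set,
    bins: pd.DataFrame,
    n_perm: int = 10_000,
    seed: int = 0,
    name: str = "eqtls",
) -> EnrichmentResult:
    """Fold enrichment of eQTLs among GWAS SNPs against bin-matched nulls.

    Per permutation each GWAS SNP is replaced by a uniform draw from its
    (MAF, gene-density) bin, excluding the SNP itself, independently
    across SNPs (with replacement). Fold = observed eQTL proportion /
    mean null proportion; the empirical p uses the add-one rule
    (r + 1)/(n_perm + 1) with r the number of null proportions >= the
    observed.
    """
    gwas_set = list(gwas_set)
    eqtl_set = set(eqtl_set)
    b = bins.set_index("variant_id")
    is_eqtl = bins["variant_id"].isin(eqtl_set).to_numpy()
    by_bin = {
        key: grp.index.to_numpy()
        for key, grp in bins.set_index("variant_id").groupby(["maf_bin", "density_bin"])
    }
    eqtl_flag = dict(zip(bins["variant_id"], is_eqtl))

    rng = np.random.default_rng(seed)
    observed = np.mean([snp in eqtl_set for snp in gwas_set])
    null_draw_flags = []
    for snp in gwas_set:
        if snp not in b.index:
            raise KeyError(f"GWAS SNP {snp!r} not in the binned variant universe")
        key = (b.loc[snp, "maf_bin"], b.loc[snp, "density_bin"])
        cands = by_bin[key]
        cands = cands[cands != snp]
        if len(cands) == 0:
            raise ValueError(f"empty matching bin for SNP {snp!r}")
        flags = np.fromiter((eqtl_flag[c] for c in cands), dtype=bool, count=len(cands))
        draws = rng.integers(0, len(cands), size=n_perm)
        null_draw_flags.append(flags[draws])
    null_prop = np.mean(null_draw_flags, axis=0)  # per permutation
    null_mean = float(null_prop.mean())
    fold = float(observed / null_mean) if null_mean > 0 else np.inf
    r = int(np.sum(null_prop >= observed))
    p = (r + 1) / (n_perm + 1)
    return EnrichmentResult(
        eqtl_list=name,
        n_gwas_snps=len(gwas_set),
        observed=float(observed),
        null_mean=null_mean,
        fold=fold,
        p=float(p),
        n_perm=n_perm,
    )


@dataclass
class ColocResult:
    """Five-hypothesis colocalization posteriors for one locus."""

    pp0: float
    pp1: float
    pp2: float
    pp3: float
    pp4: float
    priors: tuple[float, float, float]
    labf_gwas: np.ndarray
    labf_eqtl: np.ndarray

    @property
    def posteriors(self) -> np.ndarray:
        return np.array([self.pp0, self.pp1, self.pp2, self.pp3, self.pp4])


def _log_abf(beta: np.ndarray, se: np.ndarray, W: float) -> np.ndarray:
    """Wakefield log approximate Bayes factor per SNP.

    log ABF = 0.5 log(V / (V + W)) + z^2 W / (2 (V + W)), V = se^2.
    """
    V = se**2
    z2 = (beta / se) ** 2
    return 0.5 * np.log(V / (V + W)) + z2 * W / (2.0 * (V + W))


def coloc(
    gwas_stats: pd.DataFrame,
    eqtl_stats: pd.DataFrame,
    priors: tuple[float, float, float] = (1e-4, 1e-4, 1e-5),
    W: float = 0.15**2,
) -> ColocResult:
    """Single-causal-variant colocalization of a GWAS and an eQTL signal.

    Both inputs carry beta and se for the same SNP list over one locus
    (matched on ``variant_id``). Hypotheses: H0 neither trait
    associated; H1 GWAS only; H2 eQTL only; H3 both, different causal
    variants; H4 both, shared causal variant. Priors (p1, p2, p12) are
    per-SNP; W is the prior effect variance of a true association.
    PP4 >= 0.8 is conventionally read as strong evidence of
    colocalization.
    """
    if list(gwas_stats["variant_id"]) != list(eqtl_stats["variant_id"]):
        g = gwas_stats.sort_values("variant_id").reset_index(drop=True)
        e = eqtl_stats.sort_values("variant_id").reset_index(drop=True)
        if list(g["variant_id"]) != list(e["variant_id"]):
            raise ValueError("gwas and eqtl SNP lists differ")
        gwas_stats, eqtl_stats = g, e
    for df, label in ((gwas_stats, "gwas"), (eqtl_stats, "eqtl")):
        if (df["se"] <= 0).any():
            raise ValueError(f"non-positive se in {label} stats")
    p1, p2, p12 = priors
    l1 = _log_abf(gwas_stats["beta"].to_numpy(float), gwas_stats["se"].to_numpy(float), W)
    l2 = _log_abf(eqtl_stats["beta"].to_numpy(float), eqtl_stats["se"].to_numpy(float), W)

    lsum1 = logsumexp(l1)
    lsum2 = logsumexp(l2)
    lsum4 = logsumexp(l1 + l2)
    # sum over i != j of ABF1_i * ABF2_j, in log space
    both = lsum1 + lsum2
    diff = lsum4 - both
    lsum3 = -np.inf if diff >= 0 else both + np.log1p(-np.exp(diff))

    lh = np.array([
        0.0,
        np.log(p1) + lsum1,
        np.log(p2) + lsum2,
        np.log(p1) + np.log(p2) + lsum3,
        np.log(p12) + lsum4,
    ])
    post = np.exp(lh - logsumexp(lh))
    return ColocResult(*post, priors=priors, labf_gwas=l1, labf_eqtl=l2)


@dataclass
class GeneSetTest:
    """Fisher exact test of a query set against a trait set."""

    set_name: str
    background: int
    a: int  # query & trait
    b: int  # query only
    c: int  # trait only
    d: int  # neither
    odds_ratio: float
    p: float
    p_adjusted: float
    n_comparisons: int


def gene_set_fet(
    query_set,
    trait_set,
    background,
    n_comparisons: int = 1,
    method: str = "bonferroni",
    name: str = "gene_set",
) -> GeneSetTest:
    """2x2 Fisher exact test with the expressed-gene universe as background.

    Trait genes outside the background are dropped (with only cortically
    expressed genes eligible, genes never expressed cannot overlap).
    Adjustment: bonferroni multiplies p by n_comparisons (capped at 1).
    """
    bg = set(background)
    query = set(query_set) & bg
    trait = set(trait_set)
    dropped = trait - bg
    if dropped:
        import warnings

        warnings.warn(f"{len(dropped)} trait genes outside the background were dropped")
        trait &= bg
    a = len(query & trait)
    b = len(query - trait)
    c = len(trait - query)
    d = len(bg) - a - b - c
    odds, p = stats.fisher_exact([[a, b], [c, d]])
    if method == "bonferroni":
        p_adj = min(1.0, p * n_comparisons)
    elif method == "bh":
        # BH on a family needs the whole family; see gene_set_fet_table
        p_adj = float(p)
    else:
        raise ValueError(f"unknown correction method {method!r}")
    return GeneSetTest(
        set_name=name, background=len(bg), a=a, b=b, c=c, d=d,
        odds_ratio=float(odds), p=float(p), p_adjusted=float(p_adj),
        n_comparisons=n_comparisons,
    )


def gene_set_fet_table(
    query_sets: dict,
    trait_set,
    background,
    method: str = "bonferroni",
    n_comparisons: int | None = None,
) -> pd.DataFrame:
    """Run gene_set_fet for each named query set and adjust across the
    family (bonferroni with the family size, or BH over the family)."""
    n = n_comparisons if n_comparisons is not None else len(query_sets)
    tests = [
        gene_set_fet(q, trait_set, background, n_comparisons=n, method="bonferroni", name=name)
        for name, q in query_sets.items()
    ]
    df = pd.DataFrame([t.__dict__ for t in tests])
    if method == "bh":
        df["p_adjusted"] = bh_fdr(df["p"].to_numpy())
    return df
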