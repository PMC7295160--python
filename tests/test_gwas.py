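"""GWAS integration: proxy matching, supervised pruning, bin matching,
permutation enrichment, colocalization, gene-set Fisher tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from devqtl import gwas


def ld_table(rows):
    return pd.DataFrame(rows, columns=["a", "b", "r2"])


class TestMatchToTested:
    def test_direct_kept(self):
        out = gwas.match_to_tested(["v1"], ["v1"], ld_table([]))
        assert out.iloc[0]["provenance"] == "direct"

    def test_proxy_substituted(self):
        out = gwas.match_to_tested(["v1"], ["v2"], ld_table([("v1", "v2", 0.9)]))
        assert out.iloc[0]["matched"] == "v2"
        assert out.iloc[0]["provenance"] == "proxy"

    def test_weak_proxy_dropped(self):
        out = gwas.match_to_tested(["v1"], ["v2"], ld_table([("v1", "v2", 0.7)]))
        assert len(out) == 0

    def test_best_proxy_wins(self):
        out = gwas.match_to_tested(["v1"], ["v2", "v3"],
                                   ld_table([("v1", "v2", 0.85), ("v1", "v3", 0.95)]))
        assert out.iloc[0]["matched"] == "v3"


class TestSupervisedPrune:
    def _snps(self, rows):
        return pd.DataFrame(rows, columns=["variant_id", "chrom", "pos", "p"])

    def test_smaller_p_wins_within_clump(self):
        snps = self._snps([("a", "chr1", 100_000, 1e-9), ("b", "chr1", 200_000, 1e-8)])
        kept = gwas.supervised_prune(snps, ld_table([("a", "b", 0.9)]))
        assert kept == ["a"]

    def test_low_r2_pair_both_kept(self):
        snps = self._snps([("a", "chr1", 100_000, 1e-9), ("b", "chr1", 200_000, 1e-8)])
        kept = gwas.supervised_prune(snps, ld_table([("a", "b", 0.5)]))
        assert sorted(kept) == ["a", "b"]

    def test_outside_window_both_kept(self):
        snps = self._snps([("a", "chr1", 100_000, 1e-9), ("b", "chr1", 700_000, 1e-8)])
        kept = gwas.supervised_prune(snps, ld_table([("a", "b", 0.9)]))
        assert sorted(kept) == ["a", "b"]

    def test_missing_p_rejected(self):
        snps = self._snps([("a", "chr1", 1, np.nan)])
        with pytest.raises(ValueError, match="missing GWAS p"):
            gwas.supervised_prune(snps, ld_table([]))

    def test_input_order_independence(self, rng):
        rows = []
        for i in range(30):
            rows.append((f"v{i}", "chr1", int(rng.integers(0, 2_000_000)),
                         float(rng.uniform(1e-10, 1e-4))))
        snps = self._snps(rows)
        ld_rows = []
        for i in range(0, 28, 2):
            ld_rows.append((f"v{i}", f"v{i+1}", float(rng.uniform(0, 1))))
        ld = ld_table(ld_rows)
        kept1 = gwas.supervised_prune(snps, ld)
        kept2 = gwas.supervised_prune(snps.sample(frac=1, random_state=1), ld)
        assert sorted(kept1) == sorted(kept2)


class TestBinVariants:
    def _universe(self, n=200, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame({
            "variant_id": [f"v{i}" for i in range(n)],
            "chrom": "chr1",
            "pos": np.sort(rng.choice(50_000_000, n, replace=False)),
            "maf": rng.uniform(0.05, 0.5, n),
        })

    def _genes(self):
        return pd.DataFrame({
            "gene_id": ["g1", "g2"], "chrom": "chr1",
            "start": [10_000_000, 10_200_000], "end": [10_050_000, 10_260_000],
        })

    def test_isolated_variant_lowest_density(self):
        v = self._universe()
        bins = gwas.bin_variants(v, self._genes())
        far = v["pos"] > 20_000_000
        near = (v["pos"] > 10_000_000) & (v["pos"] < 10_300_000)
        d = bins.set_index("variant_id")["density"]
        assert (d[v.loc[far, "variant_id"]] == 0).all()
        assert (d[v.loc[near, "variant_id"]] >= 1).all()

    def test_excluded_region_absent(self):
        v = self._universe()
        bins = gwas.bin_variants(v, self._genes(),
                                 exclude_regions=[("chr1", 0, 25_000_000)])
        kept = set(bins["variant_id"])
        assert all(p >= 25_000_000 for p in v.set_index("variant_id").loc[list(kept), "pos"])

    def test_maf_deciles_balanced(self):
        bins = gwas.bin_variants(self._universe(1000), self._genes(), n_bins=10)
        counts = bins["maf_bin"].value_counts()
        assert len(counts) == 10
        assert counts.max() - counts.min() <= 2


def balanced_bins(n, eqtl_rate, rng):
    """Variant universe with one bin and a planted eQTL rate."""
    bins = pd.DataFrame({
        "variant_id": [f"v{i}" for i in range(n)],
        "maf_bin": 0, "density_bin": 0,
    })
    eqtls = set(bins["variant_id"][rng.random(n) < eqtl_rate])
    return bins, eqtls


class TestPermutationEnrichment:
    def test_universal_eqtls_fold_one(self, rng):
        bins, _ = balanced_bins(100, 0.0, rng)
        all_ids = list(bins["variant_id"])
        res = gwas.permutation_enrichment(all_ids[:10], all_ids, bins,
                                          n_perm=100, seed=0)
        assert res.observed == 1.0 and res.null_mean == 1.0 and res.fold == 1.0

    def test_planted_threefold_enrichment(self):
        rng = np.random.default_rng(5)
        bins, eqtls = balanced_bins(4000, 0.2, rng)
        non_eqtls = [v for v in bins["variant_id"] if v not in eqtls]
        eqtl_list = sorted(eqtls)
        # GWAS set with 60% eQTL membership vs 20% base rate: fold 3
        gwas_set = eqtl_list[:30] + non_eqtls[:20]
        res = gwas.permutation_enrichment(gwas_set, eqtls, bins, n_perm=10_000, seed=1)
        assert res.fold == pytest.approx(3.0, abs=0.3)
        assert res.p < 0.01

    def test_empty_bin_rejected(self):
        bins = pd.DataFrame({"variant_id": ["v0"], "maf_bin": [0], "density_bin": [0]})
        with pytest.raises(ValueError, match="empty matching bin"):
            gwas.permutation_enrichment(["v0"], [], bins, n_perm=10, seed=0)

    def test_null_p_conservative_over_seeds(self):
        """Exchangeable null: the add-one empirical p is valid (slightly
        conservative at ties), so the nominal-0.05 rejection rate must
        not exceed 0.05 by more than binomial noise. Full uniformity at
        permutation scale is exercised in the acceptance suite."""
        rng = np.random.default_rng(6)
        pvals = []
        for rep in range(100):
            bins, eqtls = balanced_bins(400, 0.25, rng)
            gwas_set = list(rng.choice(bins["variant_id"], 30, replace=False))
            res = gwas.permutation_enrichment(gwas_set, eqtls, bins,
                                              n_perm=500, seed=rep)
            pvals.append(res.p)
        assert np.mean(np.asarray(pvals) <= 0.05) <= 0.10
        assert np.mean(pvals) > 0.45


class TestColoc:
    def _stats(self, z, se=0.05, ids=None):
        z = np.asarray(z, dtype=float)
        ids = ids or [f"v{i}" for i in range(len(z))]
        return pd.DataFrame({"variant_id": ids, "beta": z * se, "se": se})

    def test_all_null_pp0_dominant(self):
        g = self._stats(np.zeros(100))
        e = self._stats(np.zeros(100))
        res = gwas.coloc(g, e)
        assert res.pp0 > 0.9

    def test_shared_signal_pp4(self):
        z = np.zeros(100)
        z[0] = 8.0
        res = gwas.coloc(self._stats(z), self._stats(z))
        assert res.pp4 > 0.99

    def test_distinct_signals_pp3(self):
        zg, ze = np.zeros(100), np.zeros(100)
        zg[0] = 10.0
        ze[50] = 10.0
        res = gwas.coloc(self._stats(zg), self._stats(ze))
        assert res.pp3 > 0.9

    def test_posteriors_sum_to_one(self, rng):
        g = self._stats(rng.standard_normal(50))
        e = self._stats(rng.standard_normal(50))
        res = gwas.coloc(g, e)
        assert res.posteriors.sum() == pytest.approx(1.0, abs=1e-9)

    def test_sign_flip_invariance(self, rng):
        # the ABF depends on beta only through z^2, so negating all
        # effects leaves the posteriors untouched
        z = rng.standard_normal(30)
        z[3] = 6.0
        g = self._stats(z)
        e = self._stats(z * 0.8)
        r1 = gwas.coloc(g, e)
        r2 = gwas.coloc(g.assign(beta=-g["beta"]), e)
        np.testing.assert_allclose(r1.posteriors, r2.posteriors, atol=1e-12)

    def test_matches_naive_sum_oracle(self, rng):
        """Posteriors equal a naive (non-log) evaluation of the five
        hypothesis sums from the per-SNP Bayes factors."""
        z = rng.standard_normal(20)
        z[5] = 4.0
        g = self._stats(z, se=0.1)
        e = self._stats(z * 0.7, se=0.12)
        res = gwas.coloc(g, e)
        W = 0.15**2
        p1 = p2 = 1e-4
        p12 = 1e-5

        def abf(beta, se):
            V = se**2
            return np.sqrt(V / (V + W)) * np.exp((beta / se) ** 2 * W / (2 * (V + W)))

        b1 = abf(g["beta"].to_numpy(), g["se"].to_numpy())
        b2 = abf(e["beta"].to_numpy(), e["se"].to_numpy())
        h = np.array([
            1.0,
            p1 * b1.sum(),
            p2 * b2.sum(),
            p1 * p2 * (np.outer(b1, b2).sum() - (b1 * b2).sum()),
            p12 * (b1 * b2).sum(),
        ])
        np.testing.assert_allclose(res.posteriors, h / h.sum(), rtol=1e-9)

    def test_nonpositive_se_rejected(self):
        g = self._stats([1.0, 2.0])
        bad = g.assign(se=[0.05, 0.0])
        with pytest.raises(ValueError, match="se"):
            gwas.coloc(g, bad)

    def test_mismatched_snp_lists_rejected(self):
        g = self._stats([1.0, 2.0])
        e = self._stats([1.0, 2.0], ids=["a", "b"])
        with pytest.raises(ValueError, match="SNP lists differ"):
            gwas.coloc(g, e)


class TestGeneSetFet:
    def test_hypergeometric_oracle(self):
        # a=5 b=5 c=5 d=85: OR = (5*85)/(5*5) = 17
        background = [f"g{i}" for i in range(100)]
        query = background[:10]
        trait = background[:5] + background[10:15]
        res = gwas.gene_set_fet(query, trait, background)
        assert res.a == 5 and res.b == 5 and res.c == 5 and res.d == 85
        assert res.odds_ratio == pytest.approx(17.0)
        # oracle: two-sided exact p by hypergeometric enumeration
        M, n, N = 100, 10, 10  # universe, trait, query
        rv = stats.hypergeom(M, n, N)
        probs = rv.pmf(np.arange(0, 11))
        p_oracle = probs[probs <= rv.pmf(5) * (1 + 1e-9)].sum()
        assert res.p == pytest.approx(p_oracle, rel=1e-6)

    def test_depleted_overlap_or_below_one(self):
        background = [f"g{i}" for i in range(200)]
        query = background[:50]
        trait = background[50:100]  # disjoint though ~12 expected
        res = gwas.gene_set_fet(query, trait, background)
        assert res.odds_ratio < 1

    def test_bonferroni_thirty_comparisons(self):
        background = [f"g{i}" for i in range(100)]
        res = gwas.gene_set_fet(background[:10], background[5:15], background,
                                n_comparisons=30)
        assert res.p_adjusted == pytest.approx(min(1.0, res.p * 30))

    def test_trait_genes_outside_background_dropped(self):
        background = [f"g{i}" for i in range(50)]
        with pytest.warns(UserWarning, match="dropped"):
            res = gwas.gene_set_fet(background[:5], background[:5] + ["zzz"], background)
        assert res.a + res.c == 5
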