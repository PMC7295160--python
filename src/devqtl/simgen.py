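"""Synthetic cohorts for developmental eQTL analysis.

Generates the four inputs the pipeline consumes: a developmental sample
table (ages, periods 1-12, epochs 0-3, sex, ancestry PCs), biallelic
genotypes in Hardy-Weinberg equilibrium with optional block LD, a
gene x sample count matrix whose log2 expression follows a mixture of
polynomial age trajectories with planted cis-eQTL effects, and GWAS
summary statistics with a configurable causal overlap.

All randomness flows through a single integer seed per operation;
regeneration with the same seed is byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DEFAULT_N_PER_PERIOD",
    "DEFAULT_AGE_RANGES",
    "TrajectorySpec",
    "simulate_samples",
    "simulate_genes",
    "simulate_genotypes",
    "simulate_expression",
    "simulate_gwas",
    "plant_eqtls",
    "hwe_exact_test",
    "epoch_of_period",
    "stage_of_period",
]

# Cohort mirroring the study design: 112 prenatal samples (periods 1-6),
# a handful of transitional period-7 samples, 60 postnatal (periods 8-12).
DEFAULT_N_PER_PERIOD = (14, 24, 28, 24, 14, 8, 4, 10, 10, 12, 14, 14)

# Post-conception days per period; non-overlapping, ordered. Birth ~ day 266.
DEFAULT_AGE_RANGES = (
    (28, 56),
    (56, 70),
    (70, 91),
    (91, 112),
    (112, 133),
    (133, 167),
    (167, 447),
    (447, 632),
    (632, 897),
    (897, 2452),
    (2452, 4644),
    (4644, 7572),
)

_EPOCH_OF_PERIOD = {1: 0, 2: 0, 3: 1, 4: 1, 5: 1, 6: 2, 7: 2, 8: 2,
                    9: 3, 10: 3, 11: 3, 12: 3}

N_ANCESTRY_PCS = 5


def epoch_of_period(period: int) -> int:
    """Map a developmental period (1-12) to its epoch (0-3)."""
    return _EPOCH_OF_PERIOD[int(period)]


def stage_of_period(period: int) -> str:
    """prenatal (periods 1-6), transitional (7), or postnatal (8-12)."""
    p = int(period)
    if 1 <= p <= 6:
        return "prenatal"
    if p == 7:
        return "transitional"
    if 8 <= p <= 12:
        return "postnatal"
    raise ValueError(f"period must be in 1..12, got {period}")


def simulate_samples(
    n_per_period=DEFAULT_N_PER_PERIOD,
    age_ranges=DEFAULT_AGE_RANGES,
    seed: int = 0,
    male_fraction: float = 0.5,
) -> pd.DataFrame:
    """Draw a developmental cohort.

    Parameters
    ----------
    n_per_period : sequence of 12 non-negative ints
        Samples per developmental period 1..12.
    age_ranges : sequence of 12 (low, high) intervals in post-conception days
        Must be ordered and non-overlapping so age increases with period.
    male_fraction : probability a sample is male.

    Returns a DataFrame with columns sample_id, age_days, period, epoch,
    stage, sex, pc1..pc5.
    """
    n_per_period = list(n_per_period)
    if len(n_per_period) != 12 or len(age_ranges) != 12:
        raise ValueError("n_per_period and age_ranges must have length 12")
    if any(n < 0 for n in n_per_period):
        raise ValueError("per-period counts must be non-negative")
    if sum(n_per_period) == 0:
        raise ValueError("empty cohort: all per-period counts are zero")
    for i in range(11):
        if age_ranges[i][1] > age_ranges[i + 1][0]:
            raise ValueError("age_ranges must be ordered and non-overlapping")

    rng = np.random.default_rng(seed)
    rows = []
    idx = 0
    for period, (n, (lo, hi)) in enumerate(zip(n_per_period, age_ranges), start=1):
        ages = np.sort(rng.uniform(lo, hi, size=n))
        for a in ages:
            rows.append(
                {
                    "sample_id": f"S{idx:04d}",
                    "age_days": float(a),
                    "period": period,
                    "epoch": epoch_of_period(period),
                    "stage": stage_of_period(period),
                    "sex": "male" if rng.random() < male_fraction else "female",
                }
            )
            idx += 1
    samples = pd.DataFrame(rows)
    pcs = rng.standard_normal((len(samples), N_ANCESTRY_PCS))
    for j in range(N_ANCESTRY_PCS):
        samples[f"pc{j + 1}"] = pcs[:, j]
    return samples


def simulate_genes(
    n_genes: int,
    chrom_lengths: dict[str, int] | None = None,
    length_range=(2_000, 200_000),
    noncoding_fraction: float = 0.25,
    seed: int = 0,
) -> pd.DataFrame:
    """Scatter gene models across chromosomes (0-based half-open coordinates).

    TSS is the start for + strand genes and end-1 for - strand genes.
    pLI is drawn from a mixture concentrated near 0 and 1, as observed
    in exome-wide constraint scores.
    """
    if chrom_lengths is None:
        chrom_lengths = {"chr1": 120_000_000, "chr2": 120_000_000}
    rng = np.random.default_rng(seed)
    chroms = list(chrom_lengths)
    weights = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    rows = []
    for i in range(n_genes):
        chrom = chroms[rng.choice(len(chroms), p=weights)]
        length = int(rng.integers(length_range[0], length_range[1]))
        start = int(rng.integers(0, chrom_lengths[chrom] - length))
        end = start + length
        strand = "+" if rng.random() < 0.5 else "-"
        rows.append(
            {
                "gene_id": f"G{i:05d}",
                "chrom": chrom,
                "start": start,
                "end": end,
                "strand": strand,
                "tss": start if strand == "+" else end - 1,
                "biotype": "noncoding" if rng.random() < noncoding_fraction else "protein_coding",
                "pli": float(rng.beta(0.3, 0.3)),
            }
        )
    return pd.DataFrame(rows).sort_values(["chrom", "start"], ignore_index=True)


def hwe_exact_test(n_het: int, n_hom_rare: int, n_hom_common: int, midp: bool = True) -> float:
    """Exact Hardy-Weinberg test p-value from genotype counts.

    Enumerates the conditional distribution of heterozygote counts given
    the allele counts (the standard exact test), summing probabilities
    <= that of the observed configuration. With ``midp`` the observed
    configuration contributes half its probability, which removes the
    conservativeness of the plain exact test.
    """
    n = n_het + n_hom_rare + n_hom_common
    if n == 0:
        return 1.0
    rare = 2 * n_hom_rare + n_het
    if rare == 0 or rare == 2 * n:
        return 1.0
    # log-probabilities over all het counts with the observed parity
    hets = np.arange(rare % 2, min(rare, 2 * n - rare) + 1, 2)
    hom_r = (rare - hets) // 2
    hom_c = n - hets - hom_r
    from scipy.special import gammaln

    logp = (
        gammaln(n + 1)
        - gammaln(hets + 1.0)
        - gammaln(hom_r + 1.0)
        - gammaln(hom_c + 1.0)
        + hets * np.log(2.0)
        + gammaln(rare + 1.0)
        + gammaln(2 * n - rare + 1.0)
        - gammaln(2 * n + 1.0)
    )
    p = np.exp(logp - logp.max())
    p /= p.sum()
    obs = np.flatnonzero(hets == n_het)[0]
    mask = p <= p[obs] * (1 + 1e-12)
    total = p[mask].sum()
    if midp:
        total -= 0.5 * p[obs]
    return float(min(max(total, np.finfo(float).tiny), 1.0))


def _latent_corr_for_binary_r(r: float, f: float) -> float:
    """Latent Gaussian correlation giving binary correlation ``r`` after
    thresholding two standard normals at the same quantile ``f``.

    Solves phi(rho) = r where phi(rho) = (P11(rho) - f^2) / (f (1 - f))
    and P11 is the bivariate-normal orthant probability below the
    threshold in both margins.
    """
    from scipy.optimize import brentq
    from scipy.stats import multivariate_normal

    t = stats.norm.ppf(f)

    def phi(rho):
        p11 = multivariate_normal(cov=[[1.0, rho], [rho, 1.0]]).cdf([t, t])
        return (p11 - f * f) / (f * (1 - f)) - r

    if r >= 1.0:
        return 1.0
    return float(brentq(phi, 0.0, 1 - 1e-9, xtol=1e-6))


def _variant_positions(n_variants, chrom_lengths, rng):
    chroms = list(chrom_lengths)
    weights = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    counts = rng.multinomial(n_variants, weights)
    chrom_col, pos_col = [], []
    for c, k in zip(chroms, counts):
        pos = np.sort(rng.choice(chrom_lengths[c], size=k, replace=False))
        chrom_col.extend([c] * k)
        pos_col.extend(pos.tolist())
    return chrom_col, pos_col


def simulate_genotypes(
    n_variants: int,
    sample_table: pd.DataFrame,
    maf_range=(0.05, 0.5),
    block_size: int = 1,
    within_block_r2: float = 0.0,
    chrom_lengths: dict[str, int] | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Draw biallelic genotypes under HWE with optional block LD.

    Alleles are generated by thresholding latent Gaussians; variants in
    the same block share a compound-symmetric latent correlation equal to
    sqrt(within_block_r2), so pairwise genotype r^2 approaches (slightly
    below, because of threshold attenuation) the requested value.

    Returns ``(variants, dosage)`` where ``variants`` has columns
    variant_id, chrom, pos, ref, alt, maf, maf_pre, maf_post, hwe_p and
    ``dosage`` is an (n_variants, n_samples) int8 array of alt-allele
    counts.
    """
    n_samples = len(sample_table)
    if n_samples < 2:
        raise ValueError("need at least 2 samples to simulate genotypes")
    lo, hi = maf_range
    if not (0.01 <= lo <= hi <= 0.5):
        raise ValueError("maf_range must lie within [0.01, 0.5]")
    if block_size < 1:
        raise ValueError("block_size must be >= 1")
    if chrom_lengths is None:
        chrom_lengths = {"chr1": 120_000_000, "chr2": 120_000_000}

    rng = np.random.default_rng(seed)
    chrom_col, pos_col = _variant_positions(n_variants, chrom_lengths, rng)

    af = rng.uniform(lo, hi, size=n_variants)
    r_target = float(np.sqrt(within_block_r2))

    dosage = np.empty((n_variants, n_samples), dtype=np.int8)
    block_id = np.empty(n_variants, dtype=np.int64)
    start = 0
    b = 0
    # blocks never span chromosomes
    chrom_arr = np.asarray(chrom_col)
    while start < n_variants:
        stop = min(start + block_size, n_variants)
        stop = start + int(np.sum(chrom_arr[start:stop] == chrom_arr[start]))
        width = stop - start
        correlated = r_target > 0 and width > 1
        if correlated:
            # high-LD variants must share an allele frequency; the latent
            # correlation is solved so the binary (allele) correlation hits
            # the target r despite threshold attenuation
            af[start:stop] = af[start]
            rho = _latent_corr_for_binary_r(r_target, af[start])
        thresholds = stats.norm.ppf(af[start:stop])
        alleles = np.zeros((width, n_samples), dtype=np.int8)
        for _copy in range(2):
            if correlated:
                shared = rng.standard_normal(n_samples)
                noise = rng.standard_normal((width, n_samples))
                z = np.sqrt(rho) * shared[None, :] + np.sqrt(1 - rho) * noise
            else:
                z = rng.standard_normal((width, n_samples))
            alleles += (z < thresholds[:, None]).astype(np.int8)
        dosage[start:stop] = alleles
        block_id[start:stop] = b
        b += 1
        start = stop

    bases = np.array(list("ACGT"))
    ref = bases[rng.integers(0, 4, size=n_variants)]
    alt = bases[(rng.integers(1, 4, size=n_variants) + np.searchsorted(bases, ref)) % 4]

    pre = (sample_table["stage"] == "prenatal").to_numpy()
    post = (sample_table["stage"] == "postnatal").to_numpy()

    def _maf(mask):
        if mask.sum() == 0:
            return np.full(n_variants, np.nan)
        f = dosage[:, mask].mean(axis=1) / 2.0
        return np.minimum(f, 1 - f)

    f_all = dosage.mean(axis=1) / 2.0
    hwe_p = np.empty(n_variants)
    for i in range(n_variants):
        row = dosage[i]
        n_het = int(np.sum(row == 1))
        n_alt = int(np.sum(row == 2))
        n_ref = n_samples - n_het - n_alt
        rare_is_alt = f_all[i] <= 0.5
        hwe_p[i] = hwe_exact_test(n_het, n_alt if rare_is_alt else n_ref,
                                  n_ref if rare_is_alt else n_alt)

    variants = pd.DataFrame(
        {
            "variant_id": [f"{c}_{p}_{r}_{a}" for c, p, r, a in zip(chrom_col, pos_col, ref, alt)],
            "chrom": chrom_col,
            "pos": pos_col,
            "ref": ref,
            "alt": alt,
            "maf": np.minimum(f_all, 1 - f_all),
            "maf_pre": _maf(pre),
            "maf_post": _maf(post),
            "hwe_p": hwe_p,
            "block": block_id,
        }
    )
    return variants, dosage


@dataclass
class TrajectorySpec:
    """Mixture of polynomial log2-expression trajectories.

    ``coef`` has one row per group, increasing powers of the standardized
    log2 age u = (log2(age_days) - age_center) / age_scale. Group means
    are polyval(coef_k, u); Gaussian noise with ``noise_sd`` is added on
    the log2 scale. ``proportions`` are the mixing weights genes are
    drawn from.
    """

    coef: np.ndarray = field(
        default_factory=lambda: np.array(
            [
                [0.0, 1.2, 0.1, 0.0, 0.0],   # rising
                [0.0, -1.2, -0.1, 0.0, 0.0],  # falling
                [0.0, 0.0, 0.0, 0.0, 0.0],   # flat
            ]
        )
    )
    proportions: np.ndarray = field(default_factory=lambda: np.array([0.29, 0.22, 0.49]))
    noise_sd: float = 0.5
    age_center: float = 8.5
    age_scale: float = 2.0
    base_mean: float = 2.5
    base_sd: float = 2.0

    def __post_init__(self):
        self.coef = np.atleast_2d(np.asarray(self.coef, dtype=float))
        self.proportions = np.asarray(self.proportions, dtype=float)
        if len(self.proportions) != len(self.coef):
            raise ValueError("one mixing proportion per coefficient row required")
        if not np.isclose(self.proportions.sum(), 1.0):
            raise ValueError("mixing proportions must sum to 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    def transformed_age(self, age_days) -> np.ndarray:
        return (np.log2(np.asarray(age_days, dtype=float)) - self.age_center) / self.age_scale

    def group_mean(self, group: int, age_days) -> np.ndarray:
        u = self.transformed_age(age_days)
        return np.polynomial.polynomial.polyval(u, self.coef[group])


def plant_eqtls(
    gene_annotation: pd.DataFrame,
    variants: pd.DataFrame,
    n_eqtls: int,
    beta_pre: float,
    beta_post: float,
    window: int = 1_000_000,
    min_maf: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Pick random (gene, cis-variant) pairs and assign stage-specific betas.

    Each selected gene gets one eQTL; variants are drawn uniformly from
    those within ``window`` of the gene boundaries with MAF >= min_maf.
    """
    rng = np.random.default_rng(seed)
    rows = []
    eligible_v = variants[variants["maf"] >= min_maf]
    gene_order = gene_annotation.sample(frac=1.0, random_state=int(rng.integers(2**31)))
    for _, g in gene_order.iterrows():
        cis = eligible_v[
            (eligible_v["chrom"] == g["chrom"])
            & (eligible_v["pos"] >= g["start"] - window)
            & (eligible_v["pos"] < g["end"] + window)
        ]
        if len(cis) == 0:
            continue
        v = cis.iloc[int(rng.integers(len(cis)))]
        rows.append(
            {
                "gene_id": g["gene_id"],
                "variant_id": v["variant_id"],
                "beta_pre": beta_pre,
                "beta_post": beta_post,
            }
        )
        if len(rows) == n_eqtls:
            break
    if len(rows) < n_eqtls:
        raise ValueError(f"only {len(rows)} genes had eligible cis variants")
    return pd.DataFrame(rows)


def simulate_expression(
    sample_table: pd.DataFrame,
    gene_annotation: pd.DataFrame,
    trajectory_spec: TrajectorySpec | None = None,
    eqtl_spec: pd.DataFrame | None = None,
    genotypes: tuple[pd.DataFrame, np.ndarray] | None = None,
    library_size: float = 30_000_000,
    sex_effect: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a count matrix with trajectory structure and planted eQTLs.

    Mean log2 CPM of gene g in sample s is the gene's baseline plus its
    group polynomial at the sample's transformed age, plus
    dosage * (beta_pre | beta_post) for any planted eQTL (the stage-
    appropriate beta; transitional samples get the midpoint), plus an
    optional additive sex effect for males. Gaussian noise with the
    spec's noise_sd is added, and the log2 CPM is inverted against
    ``library_size`` (the (c + 0.5)/(L + 1) convention) and rounded to
    integer counts.

    Returns ``(counts, truth)``: counts indexed by gene_id with sample_id
    columns; truth records each gene's group and baseline.
    """
    spec = trajectory_spec if trajectory_spec is not None else TrajectorySpec()
    rng = np.random.default_rng(seed)
    genes = gene_annotation["gene_id"].to_numpy()
    n_genes, n_samples = len(genes), len(sample_table)

    groups = rng.choice(len(spec.proportions), size=n_genes, p=spec.proportions)
    base = rng.normal(spec.base_mean, spec.base_sd, size=n_genes)

    u = spec.transformed_age(sample_table["age_days"].to_numpy())
    traj = np.polynomial.polynomial.polyval(u, spec.coef.T)  # groups x samples
    mean = base[:, None] + traj[groups]

    if sex_effect != 0.0:
        mean += sex_effect * (sample_table["sex"] == "male").to_numpy()[None, :]

    if eqtl_spec is not None and len(eqtl_spec):
        if genotypes is None:
            raise ValueError("eqtl_spec requires genotypes")
        variants, dosage = genotypes
        gene_idx = pd.Index(genes)
        var_idx = pd.Index(variants["variant_id"])
        stage = sample_table["stage"].to_numpy()
        w_pre = np.where(stage == "prenatal", 1.0, np.where(stage == "transitional", 0.5, 0.0))
        w_post = 1.0 - w_pre
        for _, e in eqtl_spec.iterrows():
            gi = gene_idx.get_indexer([e["gene_id"]])[0]
            vi = var_idx.get_indexer([e["variant_id"]])[0]
            if gi < 0:
                raise ValueError(f"eqtl_spec gene {e['gene_id']} not in gene_annotation")
            if vi < 0:
                raise ValueError(f"eqtl_spec variant {e['variant_id']} not in variant set")
            d = dosage[vi].astype(float)
            mean[gi] += d * (e["beta_pre"] * w_pre + e["beta_post"] * w_post)

    log2cpm = mean + rng.normal(0.0, spec.noise_sd, size=(n_genes, n_samples))
    counts = np.rint(np.exp2(log2cpm) * (library_size + 1) / 1e6 - 0.5)
    counts = np.clip(counts, 0, None).astype(np.int64)

    counts_df = pd.DataFrame(counts, index=pd.Index(genes, name="gene_id"),
                             columns=sample_table["sample_id"].to_numpy())
    truth = pd.DataFrame({"gene_id": genes, "group": groups, "baseline": base})
    return counts_df, truth


def simulate_gwas(
    variant_set: pd.DataFrame,
    causal_set,
    effect_sd: float = 0.0,
    n_gwas: int = 100_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Emit GWAS summary statistics for the simulated variants.

    Non-causal variants draw z ~ N(0, 1); causal variants draw
    z ~ N(mu, 1) with mu = effect_sd * sqrt(n_gwas) and a random sign.
    beta and se are on the per-allele scale with se = 1/sqrt(n_gwas),
    and p is the two-sided normal tail, so p, z, beta and se are
    mutually consistent.
    """
    causal_set = set(causal_set)
    known = set(variant_set["variant_id"])
    missing = causal_set - known
    if missing:
        raise ValueError(f"causal variants not in variant set: {sorted(missing)[:5]}")
    rng = np.random.default_rng(seed)
    n = len(variant_set)
    z = rng.standard_normal(n)
    mu = effect_sd * np.sqrt(n_gwas)
    is_causal = variant_set["variant_id"].isin(causal_set).to_numpy()
    signs = rng.choice([-1.0, 1.0], size=n)
    z = z + np.where(is_causal, mu * signs, 0.0)
    se = 1.0 / np.sqrt(n_gwas)
    out = variant_set[["variant_id", "chrom", "pos"]].copy()
    out["beta"] = z * se
    out["se"] = se
    out["z"] = z
    out["p"] = 2.0 * stats.norm.sf(np.abs(z))
    out["n"] = n_gwas
    return out
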