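"""End-to-end study assembly on synthetic cohorts.

Glue that strings the generator, expression preparation, association
scans, and temporal classification together in the documented order.
Used by the command-line interface and by calibration analyses (e.g.
the genomic-control lambda on a null cohort).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import eqtl, simgen, temporal, xprep

__all__ = ["Study", "build_study", "scan_all_cuts", "classify_study"]


@dataclass
class Study:
    """All artifacts of one synthetic study."""

    samples: pd.DataFrame
    genes: pd.DataFrame
    variants: pd.DataFrame          # after the frequency/HWE filter
    dosage: np.ndarray              # aligned to ``variants`` rows
    counts: pd.DataFrame
    log2cpm: pd.DataFrame           # expressed genes only
    adjusted: pd.DataFrame
    truth: pd.DataFrame
    eqtl_spec: pd.DataFrame | None = None
    records: pd.DataFrame | None = None
    extras: dict = field(default_factory=dict)


def build_study(
    n_genes: int = 500,
    n_variants: int = 5_000,
    seed: int = 0,
    n_per_period=simgen.DEFAULT_N_PER_PERIOD,
    trajectory_spec: simgen.TrajectorySpec | None = None,
    eqtl_spec: pd.DataFrame | None = None,
    n_planted: int = 0,
    beta_pre: float = 0.0,
    beta_post: float = 0.0,
    planted_min_maf: float = 0.05,
    n_hidden: int = 5,
    maf_range=(0.05, 0.5),
    chrom_lengths: dict[str, int] | None = None,
    cis_window: int = 1_000_000,
    library_size: float = 30_000_000,
) -> Study:
    """Simulate a cohort and run it through expression preparation.

    When ``n_planted`` > 0 (and no explicit ``eqtl_spec`` is given),
    that many genes receive a cis-eQTL with the requested stage betas.
    Seeds for the internal stages are derived deterministically from
    ``seed``.
    """
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(5)]

    samples = simgen.simulate_samples(n_per_period=n_per_period, seed=seeds[0])
    genes = simgen.simulate_genes(n_genes, chrom_lengths=chrom_lengths, seed=seeds[1])
    variants, dosage = simgen.simulate_genotypes(
        n_variants, samples, maf_range=maf_range,
        chrom_lengths=chrom_lengths, seed=seeds[2],
    )
    if eqtl_spec is None and n_planted > 0:
        eqtl_spec = simgen.plant_eqtls(
            genes, variants, n_planted, beta_pre, beta_post,
            window=cis_window, min_maf=planted_min_maf, seed=seeds[3],
        )
    counts, truth = simgen.simulate_expression(
        samples, genes, trajectory_spec=trajectory_spec,
        eqtl_spec=eqtl_spec, genotypes=(variants, dosage),
        library_size=library_size, seed=seeds[4],
    )

    cpm = xprep.compute_cpm(counts)
    log2cpm = xprep.compute_log2cpm(counts)
    expressed = xprep.filter_expressed(cpm, samples)
    log2cpm = log2cpm.loc[expressed]
    adjusted = xprep.adjust_expression(log2cpm, samples, n_hidden=n_hidden)

    kept = eqtl.filter_variants(variants, dosage, samples)
    dosage_kept = dosage[kept.index.to_numpy()]
    kept = kept.reset_index(drop=True)

    return Study(
        samples=samples, genes=genes, variants=kept, dosage=dosage_kept,
        counts=counts, log2cpm=log2cpm, adjusted=adjusted, truth=truth,
        eqtl_spec=eqtl_spec,
    )


def scan_all_cuts(study: Study, pairs: pd.DataFrame | None = None,
                  cis_window: int = 1_000_000) -> pd.DataFrame:
    """Run the association scan on all three cuts and merge the records,
    attaching signed TSS distances."""
    if pairs is None:
        pairs = eqtl.cis_pairs(study.variants, study.genes, window=cis_window)
        pairs = pairs[pairs["gene_id"].isin(study.adjusted.index)].reset_index(drop=True)
    per_cut = {
        cut: eqtl.scan(study.adjusted, study.dosage, study.variants,
                       study.samples, pairs, cut)
        for cut in eqtl.CUTS
    }
    records = temporal.merge_cuts(per_cut["complete"], per_cut["prenatal"],
                                  per_cut["postnatal"])
    gene_info = study.genes.set_index("gene_id")
    vpos = study.variants.set_index("variant_id")["pos"]
    tss = gene_info["tss"].reindex(records["gene_id"]).to_numpy()
    strand = gene_info["strand"].reindex(records["gene_id"]).to_numpy()
    pos = vpos.reindex(records["variant_id"]).to_numpy()
    d = pos - tss
    records["tss_dist"] = np.where(strand == "+", d, -d).astype(int)
    study.records = records
    return records


def classify_study(study: Study, alpha: float = 0.05) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Top-pair selection, Z-test classification, and propagation to all
    significant pairs. Returns (eGene table, eQTL table)."""
    if study.records is None:
        scan_all_cuts(study)
    top = temporal.select_top(study.records, alpha=alpha)
    egenes = temporal.classify_table(top, alpha=alpha)
    eqtls = temporal.propagate(egenes[["gene_id", "category"]], study.records, alpha=alpha)
    return egenes, eqtls
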