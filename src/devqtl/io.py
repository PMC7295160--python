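"""Readers and writers for the pipeline's tabular formats.

Everything is plain TSV except genotypes, which can also round-trip
through a minimal VCF (GT field only). Genomic coordinates are 0-based
half-open internally and 1-based on VCF emission.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "write_counts",
    "read_counts",
    "write_samples",
    "read_samples",
    "write_dosage",
    "read_dosage",
    "write_vcf",
    "read_vcf",
    "write_gwas",
    "read_gwas",
]


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


def read_counts(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")


def write_samples(samples: pd.DataFrame, path) -> None:
    samples.to_csv(path, sep="\t", index=False)


def read_samples(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_dosage(variants: pd.DataFrame, dosage: np.ndarray, sample_ids, path) -> None:
    df = pd.DataFrame(dosage, columns=list(sample_ids))
    out = pd.concat([variants.reset_index(drop=True), df], axis=1)
    out.to_csv(path, sep="\t", index=False)


def read_dosage(path, n_meta_cols: int | None = None) -> tuple[pd.DataFrame, np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t")
    meta_cols = [c for c in df.columns if not c.startswith("S")] if n_meta_cols is None \
        else list(df.columns[:n_meta_cols])
    sample_cols = [c for c in df.columns if c not in meta_cols]
    return df[meta_cols], df[sample_cols].to_numpy(np.int8), sample_cols


def write_vcf(variants: pd.DataFrame, dosage: np.ndarray, sample_ids, path) -> None:
    """Minimal VCF 4.2 with GT only; positions emitted 1-based."""
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(sample_ids) + "\n")
        for i, v in enumerate(variants.itertuples(index=False)):
            gts = "\t".join(gt_map[int(d)] for d in dosage[i])
            fh.write(f"{v.chrom}\t{v.pos + 1}\t{v.variant_id}\t{v.ref}\t{v.alt}"
                     f"\t.\tPASS\t.\tGT\t{gts}\n")


def read_vcf(path) -> tuple[pd.DataFrame, np.ndarray, list[str]]:
    """Read a biallelic VCF into (variants, dosage, sample_ids); positions
    converted back to 0-based. Uses cyvcf2 when installed, otherwise a
    plain-text fallback sufficient for GT-only files."""
    try:
        from cyvcf2 import VCF
    except ImportError:
        return _read_vcf_text(path)
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, dose = [], []
    for rec in vcf:
        if len(rec.ALT) != 1:
            continue
        rows.append({"variant_id": rec.ID or f"{rec.CHROM}_{rec.POS - 1}",
                     "chrom": rec.CHROM, "pos": rec.POS - 1,
                     "ref": rec.REF, "alt": rec.ALT[0]})
        dose.append(np.clip(rec.gt_types, 0, 3))
    d = np.array(dose)
    d[d == 2] = 0  # cyvcf2 codes UNKNOWN as 2, HOM_ALT as 3
    d[d == 3] = 2
    return pd.DataFrame(rows), d.astype(np.int8), samples


def _read_vcf_text(path) -> tuple[pd.DataFrame, np.ndarray, list[str]]:
    rows, dose, samples = [], [], []
    gt_map = {"0/0": 0, "0/1": 1, "1/0": 1, "1/1": 2, "0|0": 0, "0|1": 1, "1|0": 1, "1|1": 2}
    for line in Path(path).read_text().splitlines():
        if line.startswith("##"):
            continue
        if line.startswith("#CHROM"):
            samples = line.split("\t")[9:]
            continue
        parts = line.split("\t")
        rows.append({"variant_id": parts[2], "chrom": parts[0], "pos": int(parts[1]) - 1,
                     "ref": parts[3], "alt": parts[4]})
        fmt = parts[8].split(":")
        gt_i = fmt.index("GT")
        dose.append([gt_map[p.split(":")[gt_i]] for p in parts[9:]])
    return pd.DataFrame(rows), np.array(dose, dtype=np.int8), samples


def write_gwas(gwas: pd.DataFrame, path) -> None:
    cols = [c for c in ["variant_id", "chrom", "pos", "beta", "se", "z", "p", "n"]
            if c in gwas.columns]
    gwas[cols].to_csv(path, sep="\t", index=False)


def read_gwas(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
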