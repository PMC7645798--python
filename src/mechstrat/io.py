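"""Genotype matrix container and plain-text readers/writers (TSV, VCF).

Dosages use the additive 0/1/2 minor-allele coding; missing genotypes are NaN
in memory and ``NA`` on disk. The VCF path handles unphased GT fields only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "read_genotypes_tsv",
    "write_genotypes_tsv",
    "read_genotypes_vcf",
    "write_genotypes_vcf",
]


@dataclass
class GenotypeMatrix:
    """Patients × SNPs additive dosage matrix with patient metadata.

    ``dosages`` is a DataFrame (index = patient ids, columns = SNP ids,
    values in {0, 1, 2} or NaN). ``cohort`` and ``disease`` are optional
    per-patient labels aligned to the same index.
    """

    dosages: pd.DataFrame
    cohort: pd.Series | None = field(default=None)
    disease: pd.Series | None = field(default=None)

    def __post_init__(self) -> None:
        vals = self.dosages.to_numpy(dtype=float)
        finite = vals[~np.isnan(vals)]
        if finite.size and not np.isin(finite, (0.0, 1.0, 2.0)).all():
            raise ValueError("dosages must be 0, 1, 2 or missing")
        for name in ("cohort", "disease"):
            series = getattr(self, name)
            if series is not None and not series.index.equals(self.dosages.index):
                raise ValueError(f"{name} index does not match patient index")

    @property
    def patient_ids(self) -> list[str]:
        return list(self.dosages.index)

    @property
    def snp_ids(self) -> list[str]:
        return list(self.dosages.columns)

    @property
    def n_patients(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def values(self) -> np.ndarray:
        return self.dosages.to_numpy(dtype=float)


def read_genotypes_tsv(path: str | Path) -> GenotypeMatrix:
    """Read a patients × SNPs TSV (first column = patient id, header = SNP ids).

    Optional ``study`` / ``disease`` columns are split off into metadata.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    df.index.name = None
    cohort = disease = None
    if "study" in df.columns:
        cohort = df.pop("study").astype(str)
    if "disease" in df.columns:
        disease = df.pop("disease").astype(str)
    return GenotypeMatrix(dosages=df.astype(float), cohort=cohort, disease=disease)


def write_genotypes_tsv(geno: GenotypeMatrix, path: str | Path, metadata: bool = True) -> None:
    # integers on disk, NA for missing
    out = geno.dosages.astype("Int64")
    extras = []
    if metadata and geno.disease is not None:
        extras.append(geno.disease.rename("disease"))
    if metadata and geno.cohort is not None:
        extras.append(geno.cohort.rename("study"))
    if extras:
        out = pd.concat(extras + [out], axis=1)
    out.index.name = "patient_id"
    out.to_csv(path, sep="\t", na_rep="NA")


def _dosage_from_gt(gt: tuple | None) -> float:
    if gt is None:
        return np.nan
    alleles = [a for a in gt if a is not None]
    if not alleles:
        return np.nan
    return float(sum(1 for a in alleles if a != 0))


def read_genotypes_vcf(path: str | Path) -> GenotypeMatrix:
    """Read GT fields of an (uncompressed or bgzipped) VCF into dosages.

    Dosage = count of non-reference alleles; missing GT (./.) becomes NaN.
    Sample ids become patient ids; the ID column provides SNP ids.
    """
    import pysam

    rows: dict[str, list[float]] = {}
    snp_ids: list[str] = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for sample in samples:
            rows[sample] = []
        for rec in vcf:
            snp_ids.append(rec.id or f"{rec.chrom}:{rec.pos}")
            for sample in samples:
                rows[sample].append(_dosage_from_gt(rec.samples[sample].get("GT")))
    df = pd.DataFrame.from_dict(rows, orient="index", columns=snp_ids)
    return GenotypeMatrix(dosages=df)


def write_genotypes_vcf(
    geno: GenotypeMatrix,
    path: str | Path,
    positions: dict[str, tuple[str, int]] | None = None,
) -> None:
    """Write a minimal GT-only unphased VCF (text, uncompressed).

    ``positions`` maps SNP id → (chrom, pos); SNPs without a position are
    placed consecutively on chromosome ``chrUn``. Alleles are arbitrary
    (A ref / G alt) — only the additive dosage is meaningful.
    """
    gt_codes = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        known = positions or {}
        chroms = sorted({known[s][0] for s in geno.snp_ids if s in known})
        if any(s not in known for s in geno.snp_ids):
            chroms.append("chrUn")
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(geno.patient_ids)
            + "\n"
        )
        vals = geno.values()
        for j, snp in enumerate(geno.snp_ids):
            chrom, pos = (positions or {}).get(snp, ("chrUn", j + 1))
            calls = "\t".join(
                gt_codes.get(v, "./.") if not np.isnan(v) else "./."
                for v in vals[:, j]
            )
            fh.write(f"{chrom}\t{pos}\t{snp}\tA\tG\t.\t.\t.\tGT\t{calls}\n")
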