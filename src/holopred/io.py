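"""Readers and writers for the package's plain-text file formats.

* Genotype TSV: header = SNP IDs, first column = sample ID, cells 0/1/2 or NA.
* OTU TSV: header = OTU IDs, first column = sample ID, non-negative counts
  (or relative abundances — auto-detected from row sums).
* Phenotype CSV: sample ID, trait value, then covariate columns.
* Kernel TSV: square matrix, header row + first column of sample IDs,
  12 significant digits.

An optional VCF reader (GT field -> ALT-allele dosage) is provided through
cyvcf2 for standard VCF 4.x input.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .kernels import GenotypeMatrix, Kernel, OTUTable
from .model import PhenotypeTable

__all__ = [
    "read_genotypes",
    "read_genotypes_vcf",
    "read_otu_table",
    "read_phenotypes",
    "write_kernel",
    "read_kernel",
]


def read_genotypes(path: str | Path) -> GenotypeMatrix:
    """Read a genotype dosage TSV; validates cells and duplicate IDs."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate sample ID {dup!r}")
    mat = np.empty(df.shape, dtype=float)
    allowed = {"0": 0.0, "1": 1.0, "2": 2.0}
    for j, col in enumerate(df.columns):
        for i, cell in enumerate(df[col]):
            s = "NA" if cell is None else str(cell).strip()
            if s in allowed:
                mat[i, j] = allowed[s]
            elif s in ("NA", "", "nan", "<NA>"):
                mat[i, j] = np.nan
            else:
                raise ValueError(
                    f"{path}: invalid dosage {cell!r} at sample "
                    f"{df.index[i]!r}, SNP {col!r} (expected 0, 1, 2 or NA)"
                )
    return GenotypeMatrix(mat, list(df.index), list(df.columns))


def read_genotypes_vcf(path: str | Path) -> GenotypeMatrix:
    """Read genotypes from a VCF (GT field only), as ALT-allele dosage 0/1/2."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows: list[np.ndarray] = []
    ids: list[str] = []
    for var in vcf:
        vid = var.ID or f"{var.CHROM}:{var.POS}"
        ids.append(vid)
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = var.gt_types.astype(float)
        dose = np.where(gt == 3, 2.0, np.where(gt == 2, np.nan, gt))
        rows.append(dose)
    if not rows:
        raise ValueError(f"{path}: VCF contains no variants")
    mat = np.vstack(rows).T  # samples x SNPs
    return GenotypeMatrix(mat, samples, ids)


def read_otu_table(path: str | Path) -> OTUTable:
    """Read an OTU TSV; auto-detects counts vs relative abundances.

    Rows all summing to 1 (within 1e-6) are treated as relative abundances;
    rows all clearly not summing to 1 as counts; a mixture is rejected.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    mat = df.to_numpy(dtype=float)
    if (mat < 0).any():
        i, j = np.argwhere(mat < 0)[0]
        raise ValueError(
            f"{path}: negative abundance at sample {df.index[i]!r}, "
            f"OTU {df.columns[j]!r}"
        )
    sums = mat.sum(axis=1)
    rel = np.isclose(sums, 1.0, atol=1e-6)
    if rel.all():
        return OTUTable(mat, list(df.index), list(df.columns), is_relative=True)
    if rel.any():
        raise ValueError(
            f"{path}: ambiguous table — {int(rel.sum())} of {len(sums)} rows "
            "sum to 1 but the rest do not; supply pure counts or pure "
            "relative abundances"
        )
    return OTUTable(mat, list(df.index), list(df.columns), is_relative=False)


def read_phenotypes(
    path: str | Path,
    trait: str | None = None,
    fixed_columns: list[str] | None = None,
    class_columns: list[str] | None = None,
) -> PhenotypeTable:
    """Read a phenotype CSV (sample ID first, then trait and covariates).

    ``trait`` defaults to the first non-ID column. Remaining columns are
    attached as fixed covariates unless listed in ``class_columns``.
    """
    path = Path(path)
    df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    if df.index.duplicated().any():
        raise ValueError(f"{path}: duplicate sample IDs")
    if trait is None:
        trait = df.columns[0]
    if trait not in df.columns:
        raise ValueError(f"{path}: trait column {trait!r} not found")
    class_columns = list(class_columns or [])
    for c in class_columns:
        if c not in df.columns:
            raise ValueError(f"{path}: class-effect column {c!r} not found")
    if fixed_columns is None:
        fixed_columns = [c for c in df.columns if c != trait and c not in class_columns]
    y = pd.to_numeric(df[trait], errors="coerce").to_numpy(dtype=float)
    fixed = df[fixed_columns].reset_index(drop=True) if fixed_columns else None
    classes = df[class_columns].reset_index(drop=True) if class_columns else None
    return PhenotypeTable(y, list(df.index), fixed, classes)


def write_kernel(k: Kernel, path: str | Path) -> None:
    """Write a kernel as a square TSV, full matrix, 12 significant digits."""
    df = pd.DataFrame(k.matrix, index=k.sample_ids, columns=k.sample_ids)
    df.index.name = k.kind
    df.to_csv(path, sep="\t", float_format="%.12g")


def read_kernel(path: str | Path, kind: str | None = None) -> Kernel:
    """Read a kernel TSV written by :func:`write_kernel`."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    kind = kind or str(df.index.name or "GRM")
    mat = df.to_numpy(dtype=float)
    mat = 0.5 * (mat + mat.T)  # printed precision can break exact symmetry
    return Kernel(mat, list(df.index), kind)
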