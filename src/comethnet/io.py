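"""Readers and writers for the pipeline's interchange formats.

All formats are plain text: beta / metadata / annotation / dosage /
phenotype TSVs, whitespace-delimited GWAS summary statistics, MatrixMarket
expression triplets, BED-style interval files (1-based inclusive on disk,
0-based half-open in memory) and the planted-truth JSON.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from comethnet.simulate import PlantedTruth

__all__ = [
    "read_beta_tsv",
    "read_meta_tsv",
    "read_traits_tsv",
    "read_annotation_tsv",
    "read_expression",
    "read_cell_annotation",
    "read_sumstats",
    "read_dosages",
    "read_pheno_tsv",
    "read_intervals_bed",
    "write_intervals_bed",
    "read_truth",
]


def read_beta_tsv(path: str | Path, impute: bool = False) -> pd.DataFrame:
    """Load a probes-by-samples beta matrix.

    Missing values are rejected unless ``impute`` is set, in which case
    they are filled with the per-probe median.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        raise ValueError(f"{path}: duplicate probe ids")
    if df.columns.has_duplicates:
        raise ValueError(f"{path}: duplicate sample ids")
    if df.isna().any().any():
        if not impute:
            raise ValueError(
                f"{path}: missing beta values (pass impute=True for per-probe "
                "median imputation)"
            )
        med = df.median(axis=1)
        df = df.T.fillna(med).T
    return df


def read_meta_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_traits_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_annotation_tsv(path: str | Path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t")
    required = {"probe", "chr", "pos", "genes"}
    if not required <= set(ann.columns):
        raise ValueError(f"{path}: annotation needs columns {sorted(required)}")
    return ann


def read_expression(
    matrix_path: str | Path,
    genes_path: str | Path | None = None,
    cells_path: str | Path | None = None,
) -> pd.DataFrame:
    """Genes-by-cells expression from MatrixMarket triplet or TSV."""
    matrix_path = Path(matrix_path)
    if matrix_path.suffix == ".mtx":
        from scipy.io import mmread

        m = mmread(matrix_path).toarray()
        genes = (
            pd.read_csv(genes_path, sep="\t")["gene"].tolist()
            if genes_path
            else [f"G{i:04d}" for i in range(m.shape[0])]
        )
        cells = (
            pd.read_csv(cells_path, sep="\t")["cell"].tolist()
            if cells_path
            else [f"C{i:05d}" for i in range(m.shape[1])]
        )
        return pd.DataFrame(m, index=genes, columns=cells)
    return pd.read_csv(matrix_path, sep="\t", index_col=0)


def read_cell_annotation(path: str | Path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t")
    if "cell" not in ann.columns:
        raise ValueError(f"{path}: cell annotation needs a 'cell' column")
    return ann


def read_sumstats(path: str | Path) -> pd.DataFrame:
    """Whitespace-delimited GWAS summary statistics (SNP CHR BP A1 A2 BETA SE P INFO)."""
    ss = pd.read_csv(path, sep=r"\s+")
    required = {"SNP", "CHR", "BP", "A1", "A2", "BETA", "P"}
    if not required <= set(ss.columns):
        raise ValueError(f"{path}: summary statistics need columns {sorted(required)}")
    if "INFO" not in ss.columns:
        ss["INFO"] = 1.0
    return ss


def read_dosages(path: str | Path) -> pd.DataFrame:
    """Samples-by-variants dosage matrix from TSV or VCF.

    VCF input uses the DS FORMAT field when present, else the genotype
    allele count.
    """
    path = Path(path)
    if path.suffix in (".vcf", ".gz") or path.name.endswith(".vcf.gz"):
        return _read_dosages_vcf(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    vals = df.to_numpy(float)
    bad = np.isfinite(vals) & ((vals < 0) | (vals > 2))
    if bad.any():
        raise ValueError(f"{path}: dosages outside [0, 2]")
    return df


def _read_dosages_vcf(path: Path) -> pd.DataFrame:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    ids, cols = [], []
    for var in vcf:
        ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        try:
            ds = var.format("DS")
            cols.append(np.asarray(ds, float).ravel())
        except (KeyError, TypeError, ValueError):
            gt = np.asarray(var.gt_types, float)
            gt[gt == 2] = np.nan  # UNKNOWN
            gt[gt == 3] = 2.0  # HOM_ALT
            cols.append(gt)
    return pd.DataFrame(np.column_stack(cols), index=samples, columns=ids)


def read_pheno_tsv(path: str | Path) -> pd.DataFrame:
    ph = pd.read_csv(path, sep="\t")
    required = {"sample", "visit_month", "GDS", "UPDRS3", "age", "sex"}
    if not required <= set(ph.columns):
        raise ValueError(f"{path}: phenotype needs columns {sorted(required)}")
    return ph


def read_intervals_bed(path: str | Path) -> pd.DataFrame:
    """Interval file with 1-based inclusive coordinates on disk; converts to
    the 0-based half-open convention used internally."""
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chr", "start", "end"], comment="#"
    )
    df["start"] = df["start"].astype(int) - 1
    df["end"] = df["end"].astype(int)
    return df


def write_intervals_bed(intervals: pd.DataFrame, path: str | Path) -> None:
    out = intervals.copy()
    out["start"] = out["start"].astype(int) + 1
    out["end"] = out["end"].astype(int)
    out.to_csv(path, sep="\t", header=False, index=False)


def read_truth(path: str | Path) -> PlantedTruth:
    return PlantedTruth.from_json(Path(path).read_text())
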