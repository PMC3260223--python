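"""Case-control genotype containers and plain-text I/O.

Genotypes are minor-allele dosages coded 0/1/2 and are treated downstream as
unordered categories, so the coding orientation never affects any score.
Missing genotypes are rejected at load time rather than imputed: silent
imputation would alter interaction scores in ways that cannot be verified.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["Dataset", "DatasetError", "read_dataset", "write_dataset"]

#: leading non-genotype columns of a PLINK ``--recode A`` .raw file
_RAW_META = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]


class DatasetError(ValueError):
    """Raised for malformed or invalid genotype data files."""


@dataclass
class Dataset:
    """An individuals x SNPs genotype matrix with a binary phenotype.

    Parameters
    ----------
    genotypes : ndarray of shape (n_individuals, n_snps)
        Minor-allele dosage codes, each entry in {0, 1, 2}.
    snp_ids : list of str
        Unique SNP identifiers, one per column.
    individual_ids : list of str
        Unique individual identifiers, one per row.
    phenotype : ndarray of shape (n_individuals,)
        0 = control, 1 = case.
    truth : list of tuple of str, optional
        Planted interacting SNP-id combinations (simulated data only).
    """

    genotypes: np.ndarray
    snp_ids: list[str]
    individual_ids: list[str]
    phenotype: np.ndarray
    truth: list[tuple[str, ...]] | None = None

    def __post_init__(self) -> None:
        self.genotypes = np.ascontiguousarray(self.genotypes, dtype=np.int8)
        self.phenotype = np.asarray(self.phenotype, dtype=np.int8)
        self.snp_ids = list(self.snp_ids)
        self.individual_ids = list(self.individual_ids)
        if self.truth is not None:
            self.truth = [tuple(t) for t in self.truth]
        self.validate()

    # -- validation ----------------------------------------------------
    def validate(self) -> None:
        g = self.genotypes
        if g.ndim != 2:
            raise DatasetError("genotype matrix must be 2-dimensional")
        n, m = g.shape
        if m == 0:
            raise DatasetError("dataset has 0 SNPs")
        if n == 0:
            raise DatasetError("dataset has 0 individuals")
        bad = (g < 0) | (g > 2)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise DatasetError(
                f"genotype code {int(g[i, j])} at individual {i}, SNP {j} "
                "is outside {0,1,2}; missing or invalid genotypes are not "
                "accepted (no imputation is performed)"
            )
        if len(self.snp_ids) != m:
            raise DatasetError("snp_ids length does not match column count")
        if len(set(self.snp_ids)) != m:
            raise DatasetError("snp_ids are not unique")
        if len(self.individual_ids) != n:
            raise DatasetError("individual_ids length does not match row count")
        if len(set(self.individual_ids)) != n:
            raise DatasetError("individual_ids are not unique")
        if self.phenotype.shape != (n,):
            raise DatasetError("phenotype length does not match row count")
        if not np.isin(self.phenotype, (0, 1)).all():
            raise DatasetError("phenotype labels must be 0 (control) or 1 (case)")
        if not (self.phenotype == 0).any() or not (self.phenotype == 1).any():
            raise DatasetError("dataset must contain at least one case and one control")
        if self.truth is not None:
            known = set(self.snp_ids)
            for combo in self.truth:
                missing = [s for s in combo if s not in known]
                if missing:
                    raise DatasetError(f"truth combination {combo} references unknown SNPs {missing}")

    # -- convenience ---------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    @property
    def X(self) -> np.ndarray:
        return self.genotypes

    @property
    def y(self) -> np.ndarray:
        return self.phenotype

    def truth_indices(self) -> list[tuple[int, ...]]:
        """Planted combinations as column-index tuples (sorted)."""
        if not self.truth:
            return []
        pos = {s: i for i, s in enumerate(self.snp_ids)}
        return [tuple(sorted(pos[s] for s in combo)) for combo in self.truth]

    def __eq__(self, other) -> bool:
        if not isinstance(other, Dataset):
            return NotImplemented
        return (
            np.array_equal(self.genotypes, other.genotypes)
            and self.snp_ids == other.snp_ids
            and self.individual_ids == other.individual_ids
            and np.array_equal(self.phenotype, other.phenotype)
        )


def _validated_codes(frame: pd.DataFrame, path: str) -> np.ndarray:
    """Convert a string genotype frame to int8 codes with strict checks."""
    arr = frame.to_numpy()
    ok = np.isin(arr, ("0", "1", "2"))
    if not ok.all():
        i, j = np.argwhere(~ok)[0]
        tok = arr[i, j]
        raise DatasetError(
            f"{path}: invalid genotype token {tok!r} for individual "
            f"{frame.index[i]!r}, SNP {frame.columns[j]!r}: genotypes must be "
            "0, 1 or 2 and missing values are rejected (no imputation)"
        )
    return arr.astype(np.int8)


def _read_tsv(path: str) -> Dataset:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, header=0)
    except pd.errors.ParserError as exc:  # malformed row length
        raise DatasetError(f"{path}: malformed TSV ({exc})") from exc
    if df.shape[1] < 3:
        raise DatasetError(f"{path}: expected columns id, phenotype, then at least one SNP")
    if df.isna().any().any():
        row = int(np.argwhere(df.isna().to_numpy())[0][0])
        raise DatasetError(
            f"{path}: missing token on data line {row + 2}; missing genotypes "
            "are rejected at load (no imputation is performed)"
        )
    ids = df.iloc[:, 0].tolist()
    pheno_tok = df.iloc[:, 1]
    if not pheno_tok.isin(("0", "1")).all():
        bad = pheno_tok[~pheno_tok.isin(("0", "1"))].iloc[0]
        raise DatasetError(f"{path}: phenotype token {bad!r} is not 0/1")
    geno = df.iloc[:, 2:]
    geno.index = ids
    codes = _validated_codes(geno, path)
    return Dataset(codes, list(geno.columns), ids, pheno_tok.astype(np.int8).to_numpy())


def _read_plink_raw(path: str) -> Dataset:
    try:
        df = pd.read_csv(path, sep=r"\s+", dtype=str, header=0)
    except pd.errors.ParserError as exc:
        raise DatasetError(f"{path}: malformed .raw file ({exc})") from exc
    if list(df.columns[:6]) != _RAW_META:
        raise DatasetError(
            f"{path}: expected PLINK .raw header starting with {' '.join(_RAW_META)}"
        )
    if df.shape[1] < 7:
        raise DatasetError(f"{path}: .raw file contains no SNP columns")
    if df.isna().any().any():
        row = int(np.argwhere(df.isna().to_numpy())[0][0])
        raise DatasetError(
            f"{path}: missing token on data line {row + 2}; missing genotypes "
            "are rejected at load (no imputation is performed)"
        )
    pheno_tok = df["PHENOTYPE"]
    if not pheno_tok.isin(("1", "2")).all():
        bad = pheno_tok[~pheno_tok.isin(("1", "2"))].iloc[0]
        raise DatasetError(
            f"{path}: PHENOTYPE token {bad!r} is not 1 (control) or 2 (case); "
            "missing phenotypes are rejected"
        )
    ids = (df["FID"] + "_" + df["IID"]).tolist()
    geno = df.iloc[:, 6:]
    geno.index = ids
    codes = _validated_codes(geno, path)
    # PLINK codes phenotype 1/2; remap to 0/1
    phenotype = (pheno_tok.astype(np.int8) - 1).to_numpy()
    return Dataset(codes, list(geno.columns), ids, phenotype)


def read_dataset(path, format: str | None = None) -> Dataset:
    """Read a case-control genotype dataset from ``tsv`` or ``plink_raw``.

    When ``format`` is None it is inferred from the extension (``.raw`` means
    PLINK ``--recode A`` output, anything else the native TSV dialect: columns
    ``id``, ``phenotype``, then one column per SNP).
    """
    path = str(path)
    if format is None:
        format = "plink_raw" if path.endswith(".raw") else "tsv"
    if format == "tsv":
        return _read_tsv(path)
    if format == "plink_raw":
        return _read_plink_raw(path)
    raise ValueError(f"unrecognized format {format!r} (expected 'tsv' or 'plink_raw')")


def write_dataset(dataset: Dataset, path) -> None:
    """Write a dataset as the native TSV dialect (round-trips exactly)."""
    dataset.validate()
    with open(path, "w") as fh:
        fh.write("id\tphenotype\t" + "\t".join(dataset.snp_ids) + "\n")
        geno = dataset.genotypes
        for i, ind in enumerate(dataset.individual_ids):
            row = "\t".join(map(str, geno[i]))
            fh.write(f"{ind}\t{int(dataset.phenotype[i])}\t{row}\n")
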