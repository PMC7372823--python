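"""Cohort container and delimited-text I/O.

A cohort is the cleartext input to the pipeline: a covariate matrix X
(standardized, with a leading intercept column), a binary phenotype vector
y, and a SNP genotype matrix S with values in {0, 1, 2} (minor-allele
copies).  Files are plain CSV with a header and a ``sample_id`` column:

* ``covariates.csv`` — sample_id, cov1..covd
* ``phenotype.csv``  — sample_id, y
* ``snps.csv``       — sample_id, snp1..snpk
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["CohortData", "read_cohort", "write_cohort"]


@dataclass
class CohortData:
    """Cleartext cohort: standardized design matrix, phenotype, genotypes."""

    X: np.ndarray  # n x (d+1), intercept column of ones first, covariates standardized
    y: np.ndarray  # n, values in {0, 1}
    S: np.ndarray  # n x k, values in {0, 1, 2}
    sample_ids: list = field(default_factory=list)
    covariate_names: list = field(default_factory=list)
    snp_ids: list = field(default_factory=list)
    standardized: bool = True

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def d(self) -> int:
        return self.X.shape[1] - 1

    @property
    def k(self) -> int:
        return self.S.shape[1]

    @classmethod
    def from_raw(cls, covariates, y, S, sample_ids=None, covariate_names=None, snp_ids=None):
        """Standardize covariates (mean 0, sd 1), prepend the intercept."""
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        y = np.asarray(y, dtype=float).ravel()
        S = np.asarray(S, dtype=float)
        if S.ndim == 1:
            S = S[:, None]
        n = cov.shape[0]
        if y.shape[0] != n or S.shape[0] != n:
            raise ValueError(
                f"sample counts differ: covariates {n}, phenotype {y.shape[0]}, SNPs {S.shape[0]}"
            )
        sd = cov.std(axis=0)
        if np.any(sd == 0):
            bad = int(np.flatnonzero(sd == 0)[0])
            raise ValueError(f"covariate column {bad} is constant; cannot standardize")
        Z = (cov - cov.mean(axis=0)) / sd
        X = np.column_stack([np.ones(n), Z])
        d, k = cov.shape[1], S.shape[1]
        return cls(
            X=X,
            y=y,
            S=S,
            sample_ids=list(sample_ids) if sample_ids is not None else [f"s{i}" for i in range(n)],
            covariate_names=(
                list(covariate_names) if covariate_names is not None else [f"cov{j+1}" for j in range(d)]
            ),
            snp_ids=list(snp_ids) if snp_ids is not None else [f"snp{j+1}" for j in range(k)],
        )


def _read_table(path, kind: str) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "sample_id" not in df.columns:
        raise ValueError(f"{kind} file {path} lacks a sample_id column")
    return df.set_index("sample_id")


def read_cohort(covariates_path, phenotype_path, snp_path) -> CohortData:
    """Read and validate the three cohort tables.

    Raises with row/column coordinates on non-numeric cells, genotype values
    outside {0, 1, 2}, phenotypes outside {0, 1}, or sample mismatches.
    """
    cov = _read_table(covariates_path, "covariates")
    phe = _read_table(phenotype_path, "phenotype")
    snp = _read_table(snp_path, "SNP")

    if not (cov.index.equals(phe.index) and cov.index.equals(snp.index)):
        raise ValueError(
            "sample_id mismatch between files: "
            f"{len(cov)} covariate rows, {len(phe)} phenotype rows, {len(snp)} SNP rows"
        )

    for df, kind in ((cov, "covariates"), (phe, "phenotype"), (snp, "SNP")):
        for col in df.columns:
            vals = pd.to_numeric(df[col], errors="coerce")
            if vals.isna().any():
                row = vals.index[vals.isna()][0]
                raise ValueError(f"non-numeric cell in {kind} file at row {row!r}, column {col!r}")
            df[col] = vals

    if "y" not in phe.columns:
        raise ValueError("phenotype file must have a column named 'y'")
    y = phe["y"].to_numpy(dtype=float)
    bad = ~np.isin(y, (0.0, 1.0))
    if bad.any():
        row = phe.index[bad][0]
        raise ValueError(f"phenotype value {y[bad][0]!r} at row {row!r} is not in {{0, 1}}")

    S = snp.to_numpy(dtype=float)
    offgrid = ~np.isin(S, (0.0, 1.0, 2.0))
    if offgrid.any():
        i, j = map(int, np.argwhere(offgrid)[0])
        raise ValueError(
            f"genotype {S[i, j]!r} at row {snp.index[i]!r}, column {snp.columns[j]!r} "
            "is not in {0, 1, 2}"
        )

    return CohortData.from_raw(
        cov.to_numpy(dtype=float),
        y,
        S,
        sample_ids=list(cov.index),
        covariate_names=list(cov.columns),
        snp_ids=list(snp.columns),
    )


def write_cohort(cohort: CohortData, out_dir) -> dict:
    """Write the three CSV tables; returns the paths used."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "covariates": out / "covariates.csv",
        "phenotype": out / "phenotype.csv",
        "snps": out / "snps.csv",
    }
    idx = pd.Index(cohort.sample_ids, name="sample_id")
    pd.DataFrame(cohort.X[:, 1:], index=idx, columns=cohort.covariate_names).to_csv(
        paths["covariates"]
    )
    pd.DataFrame({"y": cohort.y.astype(int)}, index=idx).to_csv(paths["phenotype"])
    pd.DataFrame(cohort.S.astype(int), index=idx, columns=cohort.snp_ids).to_csv(paths["snps"])
    return paths
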