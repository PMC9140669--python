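"""Case-control genotype datasets: container, validation, and text I/O.

Genotypes are coded as minor-allele counts in {0, 1, 2}; the phenotype is
binary (0 = control, 1 = case).  Simulated datasets carry an optional
``truth`` attribute listing the embedded functional SNP combinations
(0-based column indices) so downstream evaluation can score detections.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeDataset",
    "GenotypeFormatError",
    "read_genotype_table",
    "write_genotype_table",
    "validate_dataset",
]

PHENOTYPE_COLUMN = "Class"


class GenotypeFormatError(ValueError):
    """Raised when a genotype file violates the expected dialect."""


@dataclass
class GenotypeDataset:
    """A samples x SNPs genotype matrix with a binary phenotype.

    Parameters
    ----------
    genotypes : (n_samples, n_snps) integer array with entries in {0, 1, 2}.
    phenotype : (n_samples,) integer array, 0 = control, 1 = case.
    snp_names : unique SNP identifiers, one per column.
    truth : optional list of functional SNP combinations (0-based column
        index tuples) embedded by a simulator.
    """

    genotypes: np.ndarray
    phenotype: np.ndarray
    snp_names: list[str] = field(default_factory=list)
    truth: Optional[list[tuple[int, ...]]] = None

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes)
        self.phenotype = np.asarray(self.phenotype)
        if not self.snp_names:
            self.snp_names = [f"SNP{i + 1}" for i in range(self.genotypes.shape[1])]
        self.snp_names = list(self.snp_names)
        if self.truth is not None:
            self.truth = [tuple(int(i) for i in combo) for combo in self.truth]

    @property
    def n_samples(self) -> int:
        return int(self.genotypes.shape[0])

    @property
    def n_snps(self) -> int:
        return int(self.genotypes.shape[1])

    @property
    def n_cases(self) -> int:
        return int(np.sum(self.phenotype == 1))

    @property
    def n_controls(self) -> int:
        return int(np.sum(self.phenotype == 0))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeDataset):
            return NotImplemented
        return (
            np.array_equal(self.genotypes, other.genotypes)
            and np.array_equal(self.phenotype, other.phenotype)
            and self.snp_names == other.snp_names
            and self.truth == other.truth
        )


def validate_dataset(ds: GenotypeDataset) -> list[str]:
    """Report invariant violations; an empty list means the dataset is valid.

    Never raises, whatever the shapes or dtypes of the arrays.
    """
    problems: list[str] = []
    g = np.asarray(ds.genotypes)
    y = np.asarray(ds.phenotype)
    if g.ndim != 2:
        problems.append(f"genotype matrix must be 2-D, got ndim={g.ndim}")
        return problems
    if y.ndim != 1 or y.shape[0] != g.shape[0]:
        problems.append(
            f"phenotype length {y.shape} does not match n_samples={g.shape[0]}"
        )
    if g.size and not np.isin(g, (0, 1, 2)).all():
        bad = np.argwhere(~np.isin(g, (0, 1, 2)))[0]
        problems.append(
            f"genotype value {g[tuple(bad)]!r} at sample {bad[0]}, SNP column "
            f"{bad[1]} is not in {{0,1,2}}"
        )
    if y.size and not np.isin(y, (0, 1)).all():
        bad_i = int(np.argwhere(~np.isin(y, (0, 1)))[0][0])
        problems.append(f"phenotype value {y[bad_i]!r} at sample {bad_i} is not in {{0,1}}")
    if len(ds.snp_names) != g.shape[1]:
        problems.append(
            f"{len(ds.snp_names)} SNP names for {g.shape[1]} genotype columns"
        )
    if len(set(ds.snp_names)) != len(ds.snp_names):
        seen: set[str] = set()
        for n in ds.snp_names:
            if n in seen:
                problems.append(f"duplicated SNP name {n!r}")
                break
            seen.add(n)
    if ds.truth is not None:
        for combo in ds.truth:
            if len(set(combo)) != len(combo):
                problems.append(f"truth combination {combo} has duplicate indices")
            if any(not (0 <= i < g.shape[1]) for i in combo):
                problems.append(f"truth combination {combo} out of range [0, {g.shape[1]})")
    return problems


def _raise_if_invalid(ds: GenotypeDataset, where: str) -> None:
    problems = validate_dataset(ds)
    if problems:
        raise GenotypeFormatError(f"{where}: " + "; ".join(problems))


def read_genotype_table(path, fmt: str = "csv") -> GenotypeDataset:
    """Read a genotype matrix from delimited text.

    ``csv``/``tsv`` expect a header of SNP names plus a ``Class`` phenotype
    column (0 = control, 1 = case).  ``plink_raw`` expects PLINK's ``.raw``
    recode layout (FID IID PAT MAT SEX PHENOTYPE followed by SNP dosage
    columns) with 1/2 phenotype coding, remapped here to 0/1.
    """
    if fmt in ("csv", "tsv"):
        df = pd.read_csv(path, sep="," if fmt == "csv" else "\t")
        if PHENOTYPE_COLUMN not in df.columns:
            raise GenotypeFormatError(
                f"{path}: missing phenotype column {PHENOTYPE_COLUMN!r}"
            )
        phenotype = df[PHENOTYPE_COLUMN].to_numpy()
        snp_df = df.drop(columns=[PHENOTYPE_COLUMN])
    elif fmt == "plink_raw":
        df = pd.read_csv(path, sep=r"\s+")
        meta = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]
        missing = [c for c in meta if c not in df.columns]
        if missing:
            raise GenotypeFormatError(f"{path}: missing .raw columns {missing}")
        raw_pheno = df["PHENOTYPE"].to_numpy()
        if not np.isin(raw_pheno, (1, 2)).all():
            bad = int(np.argwhere(~np.isin(raw_pheno, (1, 2)))[0][0])
            raise GenotypeFormatError(
                f"{path}: PHENOTYPE value {raw_pheno[bad]!r} at row {bad} "
                "is not 1/2 coded"
            )
        phenotype = raw_pheno - 1
        snp_df = df.drop(columns=meta)
    else:
        raise ValueError(f"unknown format {fmt!r}")

    ds = GenotypeDataset(
        genotypes=snp_df.to_numpy(),
        phenotype=np.asarray(phenotype),
        snp_names=[str(c) for c in snp_df.columns],
    )
    _raise_if_invalid(ds, str(path))
    return ds


def write_genotype_table(ds: GenotypeDataset, path, fmt: str = "csv") -> None:
    """Write ``ds`` as delimited text: SNP-name header plus a ``Class`` column.

    Output is deterministic byte-for-byte for a fixed dataset.
    """
    if fmt not in ("csv", "tsv"):
        raise ValueError(f"unknown format {fmt!r}")
    _raise_if_invalid(ds, "write_genotype_table")
    df = pd.DataFrame(np.asarray(ds.genotypes), columns=ds.snp_names)
    df[PHENOTYPE_COLUMN] = np.asarray(ds.phenotype)
    df.to_csv(path, sep="," if fmt == "csv" else "\t", index=False, lineterminator="\n")
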