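"""Core in-memory containers shared across the pipeline.

The two blocks of the analysis are a categorical genotype matrix
(subjects x SNPs, codes 0/1/2 for wildtype / heterozygous /
homozygous-rare) and a per-subject summary of each longitudinal
phenotype (random intercept and slope with their standard errors).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: sentinel for a missing genotype call in the integer code matrix
MISSING = -1

#: required columns of a long-format phenotype table
PHENOTYPE_COLUMNS = ("subject_id", "phenotype", "time", "value")


class PnccaError(Exception):
    """Base class for errors raised by this package."""


class EmptyInputError(PnccaError):
    pass


class DegenerateDataError(PnccaError):
    pass


@dataclass
class GenotypeMatrix:
    """Subjects x SNPs categorical matrix with missing-data mask.

    ``codes`` holds int8 entries in {0, 1, 2} (genotypic order:
    wildtype, heterozygous, homozygous-rare) or :data:`MISSING`.
    """

    subject_ids: np.ndarray
    snp_ids: np.ndarray
    codes: np.ndarray

    def __post_init__(self) -> None:
        self.subject_ids = np.asarray(self.subject_ids)
        self.snp_ids = np.asarray(self.snp_ids)
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.shape != (len(self.subject_ids), len(self.snp_ids)):
            raise ValueError(
                f"codes shape {self.codes.shape} does not match "
                f"{len(self.subject_ids)} subjects x {len(self.snp_ids)} SNPs"
            )
        valid = (self.codes == MISSING) | ((self.codes >= 0) & (self.codes <= 2))
        if not valid.all():
            bad = np.unique(self.codes[~valid])
            raise ValueError(f"genotype codes outside {{0,1,2,missing}}: {bad}")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    @property
    def missing_mask(self) -> np.ndarray:
        return self.codes == MISSING

    @property
    def n_categories(self) -> np.ndarray:
        """Number of distinct observed categories per SNP."""
        return np.array(
            [len(np.unique(col[col != MISSING])) for col in self.codes.T]
        )

    def category_counts(self, j: int) -> np.ndarray:
        """Counts of codes 0,1,2 among non-missing entries of SNP ``j``."""
        col = self.codes[:, j]
        return np.bincount(col[col != MISSING], minlength=3)

    def subset(self, subjects=None, snps=None) -> "GenotypeMatrix":
        """Row/column subset by boolean mask or integer index array."""
        rows = slice(None) if subjects is None else np.asarray(subjects)
        cols = slice(None) if snps is None else np.asarray(snps)
        return GenotypeMatrix(
            self.subject_ids[rows], self.snp_ids[cols], self.codes[rows][:, cols]
        )

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.subject_ids.copy(), self.snp_ids.copy(), self.codes.copy()
        )


def validate_records(records: pd.DataFrame) -> pd.DataFrame:
    """Validate a long-format repeated-measurement table.

    Requires columns subject_id, phenotype, time, value; any further
    columns are treated as covariates. Times and values must be finite.
    """
    missing_cols = [c for c in PHENOTYPE_COLUMNS if c not in records.columns]
    if missing_cols:
        raise ValueError(f"phenotype table lacks columns {missing_cols}")
    if len(records) == 0:
        raise EmptyInputError("phenotype table is empty")
    for col in ("time", "value"):
        vals = pd.to_numeric(records[col], errors="coerce")
        if not np.isfinite(vals).all():
            raise ValueError(f"non-finite entries in phenotype column '{col}'")
    return records


@dataclass
class SummarySet:
    """Per-subject random-effect summaries of every phenotype.

    ``values`` columns are named ``<phenotype>_intercept`` /
    ``<phenotype>_slope``; ``se`` matches column for column. The
    weight matrix used by the weighted-least-squares backfit is the
    elementwise reciprocal of the squared standard errors.
    """

    values: pd.DataFrame
    se: pd.DataFrame
    dropped: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if list(self.values.columns) != list(self.se.columns) or len(
            self.values
        ) != len(self.se):
            raise ValueError("values and se must be aligned")
        if not np.isfinite(self.se.to_numpy()).all() or (self.se.to_numpy() <= 0).any():
            raise ValueError("standard errors must be finite and positive")

    @property
    def subject_ids(self) -> np.ndarray:
        return self.values.index.to_numpy()

    @property
    def weights(self) -> pd.DataFrame:
        w = 1.0 / self.se.to_numpy() ** 2
        if not np.isfinite(w).all() or (w <= 0).any():
            raise ValueError("weights must be strictly positive and finite")
        return pd.DataFrame(w, index=self.values.index, columns=self.values.columns)

    @property
    def n_columns(self) -> int:
        return self.values.shape[1]


@dataclass
class FilterReport:
    """Record of removed items (axis, identifier, reason)."""

    records: list = field(default_factory=list)

    def add(self, axis: str, identifier, reason: str) -> None:
        self.records.append({"axis": axis, "id": identifier, "reason": reason})

    def __len__(self) -> int:
        return len(self.records)

    def for_axis(self, axis: str) -> list:
        return [r for r in self.records if r["axis"] == axis]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records, columns=["axis", "id", "reason"])
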