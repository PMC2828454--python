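"""Readers and writers for the delimited text formats of the pipeline.

Genotypes: header row of SNP ids, first column the subject id, cells in
{0, 1, 2} with empty, ``NA`` or ``-9`` accepted as missing. PLINK
``.raw``-style additive files are also accepted: the FID/IID/PAT/MAT/
SEX/PHENOTYPE prefix columns are detected and skipped (IID becomes the
subject id).

Phenotypes: long format with columns subject_id, phenotype, time,
value; any further columns are carried along as covariates.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import MISSING, GenotypeMatrix, SummarySet, validate_records

_MISSING_TOKENS = {"", "NA", "NaN", "nan", "-9", "-9.0"}
_PLINK_PREFIX = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]


def _sniff_sep(path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") else ","


def read_genotypes(path, sep: str | None = None) -> GenotypeMatrix:
    """Read a subjects x SNPs genotype table from delimited text."""
    sep = sep or _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    cols = list(df.columns)
    if cols[: len(_PLINK_PREFIX)] == _PLINK_PREFIX:
        subject_ids = df["IID"].to_numpy()
        df = df.drop(columns=_PLINK_PREFIX)
    else:
        subject_ids = df.iloc[:, 0].to_numpy()
        df = df.iloc[:, 1:]
    snp_ids = np.array(df.columns)
    raw = df.to_numpy()
    codes = np.full(raw.shape, MISSING, dtype=np.int8)
    for token, value in (("0", 0), ("1", 1), ("2", 2)):
        codes[raw == token] = value
    unknown = ~np.isin(raw, list(_MISSING_TOKENS) + ["0", "1", "2"])
    if unknown.any():
        bad = np.unique(raw[unknown])[:5]
        raise ValueError(f"unrecognized genotype tokens: {bad}")
    return GenotypeMatrix(subject_ids, snp_ids, codes)


def write_genotypes(G: GenotypeMatrix, path, sep: str = ",") -> None:
    df = pd.DataFrame(G.codes.astype(object), columns=G.snp_ids)
    df = df.mask(df == MISSING, "NA")
    df.insert(0, "subject_id", G.subject_ids)
    df.to_csv(path, sep=sep, index=False)


def read_phenotypes(path, sep: str | None = None) -> pd.DataFrame:
    """Read a long-format repeated-measurement table."""
    sep = sep or _sniff_sep(path)
    df = pd.read_csv(path, sep=sep)
    return validate_records(df)


def write_phenotypes(records: pd.DataFrame, path, sep: str = ",") -> None:
    records.to_csv(path, sep=sep, index=False, float_format="%.10g")


def write_summaries(S: SummarySet, prefix) -> None:
    """Write a summary set as ``<prefix>.csv`` (values) and ``<prefix>.se.csv``."""
    for df, suffix in ((S.values, ".csv"), (S.se, ".se.csv")):
        out = df.copy()
        out.insert(0, "subject_id", df.index)
        out.to_csv(f"{prefix}{suffix}", index=False, float_format="%.12g")


def read_summaries(values_path, se_path) -> SummarySet:
    values = pd.read_csv(values_path).set_index("subject_id")
    se = pd.read_csv(se_path).set_index("subject_id")
    return SummarySet(values=values, se=se)
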