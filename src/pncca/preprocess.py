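"""Data-preparation rules applied before the canonical analysis.

The cleaning pipeline mirrors standard cohort practice for common-variant
association work: derive composite phenotypes (Friedewald LDL), drop
subjects with too few repeated measurements or too much genotype
missingness, drop monomorphic and high-missingness SNPs, collapse rare
genotype classes into their genotypic neighbour, and impute the few
remaining missing calls from each SNP's marginal distribution.
"""
from __future__ import annotations

import numbers

import numpy as np
import pandas as pd

from .containers import (
    MISSING,
    DegenerateDataError,
    EmptyInputError,
    FilterReport,
    GenotypeMatrix,
    validate_records,
)


def friedewald_ldl(total_chol, hdl, triglycerides):
    """Estimate LDL cholesterol (mg/dl) from a fasting lipid panel.

    LDL = total cholesterol - HDL - 0.2 * triglycerides. Negative
    results are physiologically implausible and are typically grounds
    for excluding the sample; flagging is left to the caller.
    """
    tc = np.asarray(total_chol, dtype=float)
    hd = np.asarray(hdl, dtype=float)
    tg = np.asarray(triglycerides, dtype=float)
    if not (np.isfinite(tc).all() and np.isfinite(hd).all() and np.isfinite(tg).all()):
        raise ValueError("friedewald_ldl requires finite inputs")
    ldl = tc - hd - 0.2 * tg
    if isinstance(total_chol, numbers.Number):
        return float(ldl)
    return ldl


def filter_snps(G: GenotypeMatrix, max_missing_fraction: float = 0.05):
    """Remove monomorphic SNPs and SNPs with excessive missingness.

    A SNP is removed when it shows a single category among its
    non-missing calls, or when its missing fraction is at or above
    ``max_missing_fraction``.
    """
    if not 0 < max_missing_fraction <= 1:
        raise ValueError("max_missing_fraction must be in (0, 1]")
    if G.n_snps == 0 or G.n_subjects == 0:
        raise EmptyInputError("empty genotype matrix")
    report = FilterReport()
    keep = np.ones(G.n_snps, dtype=bool)
    miss_frac = G.missing_mask.mean(axis=0)
    for j in range(G.n_snps):
        if miss_frac[j] >= max_missing_fraction:
            keep[j] = False
            report.add("snp", G.snp_ids[j], f"missing_fraction={miss_frac[j]:.4f}")
        else:
            col = G.codes[:, j]
            obs = col[col != MISSING]
            if obs.size == 0 or len(np.unique(obs)) == 1:
                keep[j] = False
                report.add("snp", G.snp_ids[j], "monomorphic")
    return G.subset(snps=keep), report


def impute_missing(G: GenotypeMatrix, seed: int) -> GenotypeMatrix:
    """Fill missing calls by sampling each SNP's marginal distribution.

    Draws are independent across cells, use one generator seeded with
    ``seed`` and consume it column by column, so results are
    reproducible for a fixed matrix and seed.
    """
    rng = np.random.default_rng(seed)
    codes = G.codes.copy()
    for j in range(G.n_snps):
        col = codes[:, j]
        miss = col == MISSING
        if not miss.any():
            continue
        obs = col[~miss]
        if obs.size == 0:
            raise DegenerateDataError(
                f"SNP {G.snp_ids[j]} is entirely missing and cannot be imputed"
            )
        cats, counts = np.unique(obs, return_counts=True)
        col[miss] = rng.choice(cats, size=miss.sum(), p=counts / counts.sum())
    return GenotypeMatrix(G.subject_ids.copy(), G.snp_ids.copy(), codes)


def collapse_rare_categories(G: GenotypeMatrix, min_fraction: float = 0.01):
    """Merge genotype classes rarer than ``min_fraction`` into a neighbour.

    The homozygous-rare class merges into the heterozygous class (the
    common-variant convention); a rare heterozygous class merges toward
    the rare homozygote, a rare wildtype class toward the heterozygote.
    Merging repeats until every retained class meets the threshold or
    only one class remains; single-class SNPs are reported as
    monomorphic (removal is left to :func:`filter_snps`).

    Returns ``(collapsed matrix, monomorphic flags per SNP)``.
    """
    codes = G.codes.copy()
    monomorphic = np.zeros(G.n_snps, dtype=bool)
    for j in range(G.n_snps):
        col = codes[:, j]
        obs_mask = col != MISSING
        n_obs = int(obs_mask.sum())
        if n_obs == 0:
            monomorphic[j] = True
            continue
        while True:
            obs = col[obs_mask]
            cats, counts = np.unique(obs, return_counts=True)
            if len(cats) <= 1:
                monomorphic[j] = True
                break
            frac = counts / n_obs
            rare = np.where(frac < min_fraction)[0]
            if rare.size == 0:
                break
            # merge the rarest class first, into its genotypic neighbour
            k = rare[np.argmin(frac[rare])]
            cat = cats[k]
            if cat == 2:
                target = 1 if 1 in cats else 0
            elif cat == 0:
                target = 1 if 1 in cats else 2
            else:  # rare heterozygote joins the rare homozygote side
                target = 2 if 2 in cats else 0
            col[obs_mask & (col == cat)] = target
        codes[:, j] = col
    return GenotypeMatrix(G.subject_ids.copy(), G.snp_ids.copy(), codes), monomorphic


def filter_subjects(
    records: pd.DataFrame,
    G: GenotypeMatrix,
    min_obs_per_phenotype: int = 2,
    max_subject_snp_missing: float = 0.05,
):
    """Keep subjects present in both blocks with adequate data.

    A subject is excluded when any phenotype has fewer than
    ``min_obs_per_phenotype`` measurements or when more than
    ``max_subject_snp_missing`` of its genotype calls are missing.
    """
    validate_records(records)
    pheno_subjects = set(records["subject_id"].unique())
    geno_subjects = set(G.subject_ids.tolist())
    common = pheno_subjects & geno_subjects
    if not common:
        raise EmptyInputError("no subjects shared between phenotype and genotype data")

    report = FilterReport()
    phenotypes = records["phenotype"].unique()
    counts = records.groupby(["subject_id", "phenotype"]).size().unstack(fill_value=0)
    miss_frac = pd.Series(G.missing_mask.mean(axis=1), index=G.subject_ids)

    keep = []
    for sid in G.subject_ids:
        if sid not in common:
            report.add("subject", sid, "absent_from_phenotype_data")
            continue
        row = counts.loc[sid] if sid in counts.index else None
        if row is None or any(row.get(p, 0) < min_obs_per_phenotype for p in phenotypes):
            report.add("subject", sid, f"fewer_than_{min_obs_per_phenotype}_observations")
            continue
        if miss_frac[sid] > max_subject_snp_missing:
            report.add("subject", sid, f"snp_missing_fraction={miss_frac[sid]:.4f}")
            continue
        keep.append(sid)
    for sid in sorted(pheno_subjects - geno_subjects, key=str):
        report.add("subject", sid, "absent_from_genotype_data")
    if not keep:
        raise EmptyInputError("no subjects retained after filtering")

    keep_set = set(keep)
    G_out = G.subset(subjects=np.isin(G.subject_ids, keep))
    rec_out = records[records["subject_id"].isin(keep_set)].reset_index(drop=True)
    return rec_out, G_out, report


def preprocess(
    records: pd.DataFrame,
    G: GenotypeMatrix,
    snp_missing: float = 0.05,
    subject_missing: float = 0.05,
    rare_fraction: float = 0.01,
    min_obs_per_phenotype: int = 2,
    seed: int = 0,
):
    """Full cleaning pipeline: subjects, SNPs, rare classes, imputation.

    Subject filters run first, then SNP missingness/monomorphism
    filters, then rare-category collapsing (with removal of SNPs that
    collapse to one class), then marginal imputation.
    """
    records, G, report = filter_subjects(
        records, G, min_obs_per_phenotype, subject_missing
    )
    G, snp_report = filter_snps(G, snp_missing)
    report.records.extend(snp_report.records)
    G, mono = collapse_rare_categories(G, rare_fraction)
    if mono.any():
        for sid in G.snp_ids[mono]:
            report.add("snp", sid, "monomorphic_after_collapse")
        G = G.subset(snps=~mono)
    G = impute_missing(G, seed)
    return records, G, report
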