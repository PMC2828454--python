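"""Synthetic cohorts with known genetic ground truth.

The generator emulates the structure of longitudinal cardiovascular
cohort studies: several risk factors measured repeatedly per subject at
unbalanced, jittered visit times; subject-specific linear trends
(random intercept and slope); binary covariates (treatment, sex); and
a genotype panel in Hardy-Weinberg proportions with a small set of
causal SNPs acting additively, dominantly or recessively on the latent
intercepts and/or slopes. Because causal effects are placed on the
latent summary scale, the two-step method's working assumption (SNPs
shift a subject's level or trend, not individual measurements) holds
exactly under the alternative; a per-visit effect mode is available
for misspecification checks.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import MISSING, GenotypeMatrix
from . import io as pio

_EFFECT_CODES = {
    "additive": np.array([-1.0, 0.0, 1.0]),
    "dominant": np.array([-1.0, 1.0, 1.0]),
    "recessive": np.array([-1.0, -1.0, 1.0]),
}


@dataclass
class CausalEffect:
    """One causal SNP: which summary it shifts and how strongly.

    ``beta`` is the effect in SD units of the targeted random effect;
    the induced univariate correlation between the (standardized)
    encoded genotype and the summary is beta / sqrt(1 + beta^2).
    """

    snp: int
    effect_type: str = "additive"
    phenotype: int = 0
    component: str = "intercept"
    beta: float = 0.31


@dataclass
class SimulationDesign:
    n_subjects: int = 500
    q_snps: int = 500
    maf_range: tuple = (0.1, 0.45)
    n_phenotypes: int = 7
    causal: list = field(default_factory=list)
    # visit structure: scheduled times, per-subject count range, jitter
    schedule: tuple = (0.0, 8.0, 16.0, 24.0)
    visit_range: tuple = (2, 4)
    time_jitter: float = 2.0
    # variance components (shared across phenotypes unless degenerate)
    intercept_sd: float = 1.0
    slope_sd: float = 0.05
    re_correlation: float = 0.2
    residual_sd: float = 0.5
    #: phenotype indices whose slope is a deterministic multiple of the
    #: intercept (no independent time-trend information)
    degenerate_phenotypes: list = field(default_factory=list)
    trt_effect: float = -0.3
    sex_effect: float = 0.2
    genotype_missing: float = 0.0
    per_visit_effects: bool = False
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie in (0, 0.5]")
        if min(self.intercept_sd, self.slope_sd, self.residual_sd) < 0:
            raise ValueError("standard deviations must be >= 0")
        if abs(self.re_correlation) > 1:
            raise ValueError("|re_correlation| must be <= 1")


def simulate_genotypes(design: SimulationDesign, rng=None) -> GenotypeMatrix:
    """Independent SNPs in Hardy-Weinberg proportions, MAF ~ U(maf_range)."""
    rng = rng or np.random.default_rng(design.seed)
    n, q = design.n_subjects, design.q_snps
    maf = rng.uniform(*design.maf_range, size=q)
    u = rng.random((n, q))
    p_aa = (1 - maf) ** 2
    p_ab = 2 * maf * (1 - maf)
    codes = (u >= p_aa).astype(np.int8) + (u >= p_aa + p_ab).astype(np.int8)
    if design.genotype_missing > 0:
        mask = rng.random((n, q)) < design.genotype_missing
        codes[mask] = MISSING
    subject_ids = np.array([f"S{i:05d}" for i in range(n)])
    snp_ids = np.array([f"snp{j:05d}" for j in range(q)])
    G = GenotypeMatrix(subject_ids, snp_ids, codes)
    G.maf = maf  # ground truth, used by tests
    return G


def _standardized_encoding(codes_col: np.ndarray, effect_type: str) -> np.ndarray:
    enc = _EFFECT_CODES[effect_type][np.where(codes_col == MISSING, 1, codes_col)]
    sd = enc.std()
    if sd == 0:
        return np.zeros_like(enc)
    return (enc - enc.mean()) / sd


def simulate_longitudinal(design: SimulationDesign, G: GenotypeMatrix, rng=None):
    """Repeated measurements plus the true per-subject random effects.

    Returns ``(records, truth)`` where ``truth`` holds the true b0/b1
    matrices (subjects x phenotypes), the causal specification and the
    covariates.
    """
    rng = rng or np.random.default_rng(design.seed + 1)
    n, p = design.n_subjects, design.n_phenotypes

    # latent random effects per phenotype
    b0 = np.empty((n, p))
    b1 = np.empty((n, p))
    for ph in range(p):
        if ph in design.degenerate_phenotypes:
            z0 = rng.standard_normal(n)
            z1 = z0  # perfectly correlated: slope carries no new information
        else:
            r = design.re_correlation
            z0 = rng.standard_normal(n)
            z1 = r * z0 + np.sqrt(1 - r**2) * rng.standard_normal(n)
        b0[:, ph] = design.intercept_sd * z0
        b1[:, ph] = design.slope_sd * z1

    if not design.per_visit_effects:
        for eff in design.causal:
            s = _standardized_encoding(G.codes[:, eff.snp], eff.effect_type)
            sd = design.intercept_sd if eff.component == "intercept" else design.slope_sd
            target = b0 if eff.component == "intercept" else b1
            target[:, eff.phenotype] += eff.beta * sd * s

    trt = rng.integers(0, 2, size=n)
    sex = rng.integers(0, 2, size=n)

    lo, hi = design.visit_range
    n_visits = rng.integers(lo, hi + 1, size=n)
    schedule = np.asarray(design.schedule, dtype=float)

    visit_enc = [
        _standardized_encoding(G.codes[:, eff.snp], eff.effect_type)
        for eff in design.causal
    ]

    rows = []
    for i in range(n):
        times = schedule[: n_visits[i]] + rng.uniform(
            -design.time_jitter, design.time_jitter, size=n_visits[i]
        )
        times = np.maximum(times, 0.0)
        for ph in range(p):
            mu = (
                b0[i, ph]
                + b1[i, ph] * times
                + design.trt_effect * trt[i]
                + design.sex_effect * sex[i]
            )
            if design.per_visit_effects:
                for eff, enc in zip(design.causal, visit_enc):
                    if eff.phenotype == ph:
                        mu = mu + eff.beta * design.residual_sd * enc[i]
            vals = mu + rng.normal(0, design.residual_sd, size=len(times))
            for t, v in zip(times, vals):
                rows.append(
                    (G.subject_ids[i], f"pheno{ph}", float(t), float(v), int(trt[i]), int(sex[i]))
                )
    records = pd.DataFrame(
        rows, columns=["subject_id", "phenotype", "time", "value", "trt", "sex"]
    )
    truth = {
        "b0": b0,
        "b1": b1,
        "causal": list(design.causal),
        "trt": trt,
        "sex": sex,
    }
    return records, truth


# ---------------------------------------------------------------------------
# named study designs


def framingham_like_design(
    n_subjects: int = 600,
    q_snps: int = 2000,
    n_causal: int = 5,
    beta: float = 0.45,
    seed: int = 103,
) -> SimulationDesign:
    """Population-cohort style: 7 phenotypes, <=4 jittered visits.

    One phenotype (index 3, the blood-glucose analogue) is degenerate:
    its slope is a deterministic multiple of its intercept. The causal
    SNPs all act additively on phenotype 1's intercept (an HDL-like
    cluster of associated variants). The default effect size gives a
    latent univariate correlation of beta / sqrt(1 + beta^2) ~ 0.41,
    which BLUP estimation error attenuates to ~0.25-0.3 against the
    fitted intercept summaries under this visit schedule and noise
    level — the regime of a moderately strong common-variant signal.
    """
    positions = np.unique(
        np.linspace(3, max(q_snps - 5, 3), max(n_causal, 1)).round().astype(int)
    )[:n_causal]
    causal = [
        CausalEffect(snp=int(j), effect_type="additive", phenotype=1,
                     component="intercept", beta=beta)
        for j in positions
    ]
    return SimulationDesign(
        n_subjects=n_subjects,
        q_snps=q_snps,
        n_phenotypes=7,
        causal=causal,
        schedule=(0.0, 8.0, 16.0, 24.0),
        visit_range=(2, 4),
        time_jitter=2.0,
        degenerate_phenotypes=[3],
        genotype_missing=0.02,
        seed=seed,
    )


def regress_like_design(
    n_subjects: int = 300, q_snps: int = 99, seed: int = 104
) -> SimulationDesign:
    """Trial style: 3 phenotypes, scheduled post-baseline visits (months).

    Two strongly associated SNPs act on phenotype 0's intercept,
    mimicking a candidate-gene cluster.
    """
    causal = [
        CausalEffect(snp=j, effect_type="additive", phenotype=0,
                     component="intercept", beta=0.45)
        for j in (10, 11)
    ]
    return SimulationDesign(
        n_subjects=n_subjects,
        q_snps=q_snps,
        n_phenotypes=3,
        causal=causal,
        schedule=(2.0, 4.0, 6.0, 12.0, 18.0, 24.0),
        visit_range=(3, 6),
        time_jitter=0.25,
        slope_sd=0.02,
        genotype_missing=0.01,
        seed=seed,
    )


def tiny_design(signal: bool, n_subjects: int = 60, q_snps: int = 30, seed: int = 101):
    causal = (
        [CausalEffect(snp=4, beta=1.0, phenotype=0),
         CausalEffect(snp=9, beta=1.0, phenotype=1)]
        if signal
        else []
    )
    return SimulationDesign(
        n_subjects=n_subjects,
        q_snps=q_snps,
        n_phenotypes=3,
        causal=causal,
        schedule=(0.0, 8.0, 16.0, 24.0),
        visit_range=(3, 4),
        genotype_missing=0.02,
        seed=seed,
    )


_FIXTURES = {
    "tiny_null": lambda: tiny_design(signal=False, seed=101),
    "tiny_signal": lambda: tiny_design(signal=True, seed=102),
    "framingham_like": lambda: framingham_like_design(),
    "regress_like": lambda: regress_like_design(),
}


def make_fixture(name: str, out_dir, seed: int | None = None) -> dict:
    """Write a named deterministic dataset; returns the file paths.

    Files: ``genotypes.csv``, ``phenotypes.csv`` and ``truth.json``
    (causal SNP ids and design parameters, for recovery checks).
    """
    if name not in _FIXTURES:
        raise ValueError(f"unknown fixture {name!r}; choose from {sorted(_FIXTURES)}")
    design = _FIXTURES[name]()
    if seed is not None:
        design.seed = seed
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    G = simulate_genotypes(design)
    records, truth = simulate_longitudinal(design, G)
    paths = {
        "genotypes": out_dir / "genotypes.csv",
        "phenotypes": out_dir / "phenotypes.csv",
        "truth": out_dir / "truth.json",
    }
    pio.write_genotypes(G, paths["genotypes"])
    pio.write_phenotypes(records, paths["phenotypes"])
    meta = {
        "name": name,
        "design": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(design).items()
            if k != "causal"
        },
        "causal": [asdict(c) for c in design.causal],
        "causal_snp_ids": [str(G.snp_ids[c.snp]) for c in design.causal],
    }
    with open(paths["truth"], "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
    return paths
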