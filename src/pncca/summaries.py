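"""Mixed-model summarization of repeated phenotype measurements.

Each phenotype is fitted separately with a linear mixed-effects model
(random intercept and random slope on time, REML) and every subject is
summarized by the empirical BLUPs of their intercept and slope
deviation from the population average, together with the conditional
prediction standard errors. The summaries form the phenotype block of
the canonical analysis; the reciprocal squared standard errors form
the weight matrix, so poorly-followed subjects count less.

A phenotype whose intercept and slope BLUPs are (near-)perfectly
correlated carries no separate time-trend information; its slope column
is removed before the canonical analysis.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.regression.mixed_linear_model import MixedLMParams

from .containers import DegenerateDataError, PnccaError, SummarySet, validate_records

#: |corr(intercept BLUP, slope BLUP)| at or above which the slope is dropped.
#: A truly rank-1 random-effects distribution yields BLUP correlations of
#: ~0.98-1.0 rather than exactly 1, because REML estimates approach the
#: boundary of the covariance parameter space without reaching it; the
#: threshold absorbs that estimation error while staying far above the
#: correlations regular intercept/slope pairs produce.
DEGENERATE_SLOPE_THRESHOLD = 0.95


class MixedModelFitError(PnccaError):
    pass


@dataclass
class MixedModelSpec:
    """Fixed/random structure of one phenotype's mixed model.

    ``covariates`` are additional fixed-effect columns of the record
    table (e.g. treatment, sex); ``baseline`` optionally names a
    covariate holding the pre-treatment measurement (trial-style
    models where follow-up values are adjusted for the baseline
    value). Random effects are always intercept + slope on time.
    """

    phenotype: str
    covariates: list = field(default_factory=list)
    baseline: str | None = None
    interactions: list = field(default_factory=list)  # covariates crossed with time


@dataclass
class PhenotypeFit:
    phenotype: str
    subject_ids: np.ndarray
    b0: np.ndarray
    b1: np.ndarray
    se_b0: np.ndarray
    se_b1: np.ndarray
    fixed_effects: pd.Series
    cov_re: np.ndarray
    converged: bool
    singular: bool


@dataclass
class StandardizationParams:
    time_mean: float
    time_scale: float
    value_means: dict
    value_scales: dict


def standardize_inputs(
    records: pd.DataFrame, scale_time: bool = True, scale_values: bool = False
):
    """Center time (pooled) and each phenotype's values to mean zero.

    Time is by default also scaled to unit variance: random slopes are
    reported per standardized time unit, and a well-scaled time axis
    keeps the REML variance components of the same order of magnitude
    (slope variances per raw year can be thousands of times smaller
    than intercept variances, which stalls the optimizer). Returns the
    transformed table and the parameters needed to map further data
    identically.
    """
    validate_records(records)
    out = records.copy()
    t = out["time"].to_numpy(dtype=float)
    if len(np.unique(t)) < 2:
        raise DegenerateDataError("time column is constant; cannot standardize")
    t_mean = float(t.mean())
    t_scale = float(t.std()) if scale_time else 1.0
    out["time"] = (t - t_mean) / t_scale
    v_means, v_scales = {}, {}
    for ph, grp in records.groupby("phenotype"):
        vals = grp["value"].to_numpy(dtype=float)
        if len(np.unique(vals)) < 2:
            raise DegenerateDataError(f"phenotype {ph!r} has constant values")
        mu = float(vals.mean())
        sc = float(vals.std()) if scale_values else 1.0
        v_means[ph], v_scales[ph] = mu, sc
        idx = out["phenotype"] == ph
        out.loc[idx, "value"] = (out.loc[idx, "value"] - mu) / sc
    params = StandardizationParams(t_mean, t_scale, v_means, v_scales)
    return out, params


def apply_standardization(records: pd.DataFrame, params: StandardizationParams):
    """Standardize further records with previously fitted parameters."""
    out = records.copy()
    out["time"] = (out["time"] - params.time_mean) / params.time_scale
    for ph, mu in params.value_means.items():
        idx = out["phenotype"] == ph
        out.loc[idx, "value"] = (out.loc[idx, "value"] - mu) / params.value_scales[ph]
    return out


def _design(sub: pd.DataFrame, spec: MixedModelSpec):
    names = ["intercept", "time"]
    cols = [np.ones(len(sub)), sub["time"].to_numpy(dtype=float)]
    extra = list(spec.covariates)
    if spec.baseline is not None:
        extra.append(spec.baseline)
    for c in extra:
        if c not in sub.columns:
            raise MixedModelFitError(f"covariate {c!r} missing from records")
        names.append(c)
        cols.append(sub[c].to_numpy(dtype=float))
    for c in spec.interactions:
        names.append(f"{c}:time")
        cols.append(sub[c].to_numpy(dtype=float) * sub["time"].to_numpy(dtype=float))
    return names, np.column_stack(cols)


def fit_phenotype_model(records: pd.DataFrame, spec: MixedModelSpec) -> PhenotypeFit:
    """REML mixed model for one phenotype; BLUPs with conditional SEs.

    The random-effects covariance is unstructured (2x2). If the
    optimizer fails, the model is refitted with a diagonal covariance
    and the result flagged; an estimated covariance that is merely
    singular (perfectly correlated intercept and slope) is kept as-is,
    since that is exactly what the degenerate-slope screen looks for.
    """
    sub = records[records["phenotype"] == spec.phenotype]
    if len(sub) == 0:
        raise MixedModelFitError(f"no records for phenotype {spec.phenotype!r}")
    counts = sub.groupby("subject_id").size()
    if (counts < 2).any():
        bad = counts[counts < 2].index.tolist()[:5]
        raise MixedModelFitError(
            f"subjects with <2 observations of {spec.phenotype!r}: {bad}"
        )
    names, exog = _design(sub, spec)
    endog = sub["value"].to_numpy(dtype=float)
    groups = sub["subject_id"].to_numpy()
    exog_re = np.column_stack(
        [np.ones(len(sub)), sub["time"].to_numpy(dtype=float)]
    )
    md = sm.MixedLM(endog, exog, groups=groups, exog_re=exog_re)
    diagonal_fallback = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = md.fit(reml=True, method="lbfgs", maxiter=200)
            # a fit that stops at the optimizer's iteration limit near
            # the boundary of the covariance space (singular D) is kept:
            # the near-singular estimate *is* the degeneracy signal
            if not np.isfinite(res.params).all():
                raise MixedModelFitError("non-finite parameter estimates")
        except Exception:
            # diagonal random-effects covariance as a constrained retry
            free = MixedLMParams.from_components(
                fe_params=np.ones(exog.shape[1]), cov_re=np.eye(2)
            )
            diagonal_fallback = True
            try:
                res = md.fit(reml=True, free=free, method="lbfgs", maxiter=200)
            except Exception as err:  # pragma: no cover - diagnostic path
                raise MixedModelFitError(
                    f"mixed model for {spec.phenotype!r} failed: {err}"
                ) from err

    eig = np.linalg.eigvalsh(res.cov_re)
    singular = diagonal_fallback or bool(
        eig.min() < 1e-6 * max(eig.max(), 1e-300)
    )

    re = res.random_effects
    re_cov = res.random_effects_cov
    subject_ids = np.array(sorted(counts.index.tolist()))
    b = np.array([np.asarray(re[g])[:2] for g in subject_ids])
    se = np.array(
        [np.sqrt(np.clip(np.diag(np.asarray(re_cov[g]))[:2], 1e-300, None)) for g in subject_ids]
    )
    return PhenotypeFit(
        phenotype=spec.phenotype,
        subject_ids=subject_ids,
        b0=b[:, 0],
        b1=b[:, 1],
        se_b0=se[:, 0],
        se_b1=se[:, 1],
        fixed_effects=pd.Series(res.fe_params, index=names),
        cov_re=np.asarray(res.cov_re),
        converged=bool(res.converged),
        singular=singular,
    )


def build_summary_set(fits: list) -> SummarySet:
    """Assemble fits into the phenotype block (stable column order)."""
    if not fits:
        raise ValueError("no phenotype fits supplied")
    ref = fits[0].subject_ids
    for f in fits[1:]:
        if not np.array_equal(f.subject_ids, ref):
            raise ValueError(
                f"subject sets differ between phenotype fits ({f.phenotype})"
            )
    values = {}
    se = {}
    for f in fits:
        values[f"{f.phenotype}_intercept"] = f.b0
        values[f"{f.phenotype}_slope"] = f.b1
        se[f"{f.phenotype}_intercept"] = f.se_b0
        se[f"{f.phenotype}_slope"] = f.se_b1
    idx = pd.Index(ref, name="subject_id")
    return SummarySet(
        values=pd.DataFrame(values, index=idx), se=pd.DataFrame(se, index=idx)
    )


def drop_degenerate_slopes(
    S: SummarySet, correlation_threshold: float = DEGENERATE_SLOPE_THRESHOLD
) -> SummarySet:
    """Remove slope columns (near-)perfectly correlated with their intercept."""
    drop = []
    for col in S.values.columns:
        if not col.endswith("_slope"):
            continue
        icol = col[: -len("_slope")] + "_intercept"
        if icol not in S.values.columns:
            continue
        b0 = S.values[icol].to_numpy()
        b1 = S.values[col].to_numpy()
        if b1.std() == 0 or b0.std() == 0:
            drop.append(col)
            continue
        if abs(np.corrcoef(b0, b1)[0, 1]) >= correlation_threshold:
            drop.append(col)
    return SummarySet(
        values=S.values.drop(columns=drop),
        se=S.se.drop(columns=drop),
        dropped=S.dropped + drop,
    )


def summarize(
    records: pd.DataFrame,
    phenotypes: list | None = None,
    covariates: dict | None = None,
    baseline: str | None = None,
    drop_threshold: float = DEGENERATE_SLOPE_THRESHOLD,
    standardize: bool = True,
) -> SummarySet:
    """End-to-end step one: records -> summary block with weights.

    ``covariates`` maps phenotype name -> list of covariate columns
    (missing entries get no covariates).
    """
    if standardize:
        records, _ = standardize_inputs(records)
    if phenotypes is None:
        phenotypes = sorted(records["phenotype"].unique().tolist())
    covariates = covariates or {}
    fits = [
        fit_phenotype_model(
            records,
            MixedModelSpec(
                phenotype=ph, covariates=covariates.get(ph, []), baseline=baseline
            ),
        )
        for ph in phenotypes
    ]
    return drop_degenerate_slopes(build_summary_set(fits), drop_threshold)
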