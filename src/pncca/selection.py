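"""Support-size selection by cross-validation with a permutation null.

The estimation subjects are split into folds; for every candidate
support size the model is fitted on the training folds and its weights
and transformations are applied unchanged to the held-out fold. The
selection criterion is the mean over folds of the absolute difference
between training and validation canonical correlations — it grows when
the model overfits. The reference distribution comes from permuting
the SNP variate within each validation fold while keeping the
phenotype variate fixed: a candidate size is only believed when its
validation criterion is clearly below the permuted criterion.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.model_selection import KFold

from .containers import PnccaError
from .core import (
    ColumnStandardizer,
    PnccaConfig,
    apply_model,
    fit_canonical_pair,
)

#: quantile of the permuted criterion below which a support size counts
#: as separated from the null
SEPARATION_QUANTILE = 0.05


@dataclass
class CvResult:
    k_grid: list
    mean_abs_diff: np.ndarray            # per k
    mean_abs_diff_permuted: np.ndarray   # per k, mean of permuted criterion
    rho_train: np.ndarray                # k x folds
    rho_val: np.ndarray                  # k x folds
    perm_abs_diff: np.ndarray | None     # k x (folds * n_perm) pooled
    n_folds: int
    n_permutations: int
    fold_failures: list = field(default_factory=list)
    chosen_k: int | None = None


def split_estimation_test(subject_ids, n_test: int, seed: int):
    """Seeded random split of subjects into estimation and test sets."""
    subject_ids = np.asarray(subject_ids)
    n = len(subject_ids)
    if not 0 < n_test < n:
        raise ValueError("n_test must be in (0, n)")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return subject_ids[np.sort(perm[n_test:])], subject_ids[np.sort(perm[:n_test])]


def cross_validate(
    codes: np.ndarray,
    Y_raw: np.ndarray,
    W: np.ndarray,
    k_grid,
    n_folds: int = 10,
    config: PnccaConfig | None = None,
    seed: int = 0,
    n_perm: int = 0,
) -> CvResult:
    """Fold-wise fit/apply over a grid of candidate support sizes.

    ``Y_raw`` is standardized within each training fold and the fold's
    parameters are applied to its validation subjects, mirroring how
    the final model is applied to a test set. With ``n_perm > 0`` the
    validation SNP variate is additionally permuted ``n_perm`` times
    per fold to build the null reference.
    """
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    k_grid = list(k_grid)
    if not k_grid:
        raise ValueError("k_grid must be non-empty")
    config = config or PnccaConfig()
    codes = np.asarray(codes)
    Y_raw = np.asarray(Y_raw, dtype=float)
    W = np.asarray(W, dtype=float)
    n = len(Y_raw)

    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = list(kf.split(np.arange(n)))
    rng = np.random.default_rng(seed + 1)

    rho_train = np.full((len(k_grid), n_folds), np.nan)
    rho_val = np.full((len(k_grid), n_folds), np.nan)
    perm_diff = (
        np.full((len(k_grid), n_folds * n_perm), np.nan) if n_perm > 0 else None
    )
    failures = []
    for f, (tr, va) in enumerate(folds):
        scaler = ColumnStandardizer.fit(Y_raw[tr])
        Y_tr = scaler.transform(Y_raw[tr])
        Y_va = scaler.transform(Y_raw[va])
        for ki, k in enumerate(k_grid):
            cfg = PnccaConfig(**{**asdict(config), "n_snps": int(k)})
            try:
                pair = fit_canonical_pair(codes[tr], Y_tr, W[tr], cfg)
            except PnccaError as err:
                failures.append({"fold": f, "k": int(k), "error": str(err)})
                continue
            rho_train[ki, f] = pair.rho
            rho_val[ki, f] = apply_model(pair, codes[va], Y_va)
            if n_perm > 0:
                from .core import transform_with_quants, _corr

                X_va = transform_with_quants(codes[va], pair.std_quants)
                omega_va = Y_va @ pair.u
                xi_va = X_va @ pair.v
                for b in range(n_perm):
                    perm = rng.permutation(len(va))
                    perm_diff[ki, f * n_perm + b] = abs(
                        pair.rho - _corr(omega_va, xi_va[perm])
                    )

    abs_diff = np.abs(rho_train - rho_val)
    mean_abs_diff = np.nanmean(abs_diff, axis=1)
    mean_perm = (
        np.nanmean(perm_diff, axis=1) if perm_diff is not None else np.full(len(k_grid), np.nan)
    )
    return CvResult(
        k_grid=[int(k) for k in k_grid],
        mean_abs_diff=mean_abs_diff,
        mean_abs_diff_permuted=mean_perm,
        rho_train=rho_train,
        rho_val=rho_val,
        perm_abs_diff=perm_diff,
        n_folds=n_folds,
        n_permutations=n_perm,
        fold_failures=failures,
    )


def permutation_reference(
    codes, Y_raw, W, k_grid, n_folds=10, n_perm=20, config=None, seed=0
) -> np.ndarray:
    """Pooled permuted |rho_train - rho_perm_val| values per candidate k."""
    cv = cross_validate(
        codes, Y_raw, W, k_grid, n_folds=n_folds, config=config, seed=seed, n_perm=n_perm
    )
    return cv.perm_abs_diff


def select_support_size(
    cv: CvResult,
    inflation: int = 1,
    separation_quantile: float = SEPARATION_QUANTILE,
):
    """Choose the support size, or return ``None`` (no-signal verdict).

    A size is eligible when its validation criterion lies below the
    ``separation_quantile`` of the pooled permuted criterion at that
    size; among eligible sizes the criterion minimizer is chosen,
    optionally inflated by a safety multiplier (to avoid missing
    borderline SNPs). ``None`` means no size separates from the
    permutation null and the data show no usable association.
    """
    if cv.perm_abs_diff is None:
        raise ValueError("cross-validation was run without permutations")
    thresh = np.nanquantile(cv.perm_abs_diff, separation_quantile, axis=1)
    separated = cv.mean_abs_diff < thresh
    if not separated.any():
        cv.chosen_k = None
        return None
    idx = np.where(separated)[0]
    best = idx[np.argmin(cv.mean_abs_diff[idx])]
    chosen = int(cv.k_grid[best]) * int(inflation)
    cv.chosen_k = chosen
    return chosen
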