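"""Optimal scaling of SNP genotypes under genetic-effect orderings.

Each SNP is a 3-category variable (wildtype, heterozygous,
homozygous-rare). To use it in a correlation analysis it is replaced by
one continuous column whose category quantifications are restricted to
the genetically meaningful monotone patterns: additive (all three
distinct), dominant (het = homozygous-rare), recessive (wildtype =
het) or constant — in either direction. The heterozygote therefore
always lies weakly between the two homozygotes.

Fitting is the categorical-regression (CATREG) update: the
unrestricted quantification of each category is the mean of the target
over that category; the restriction is the count-weighted least-squares
projection onto the monotone cone, computed by pooled-adjacent-violators
in both directions with the better-fitting direction retained. Pooling
produces the dominant/recessive/constant patterns automatically, so
this single projection is the least-squares-optimal member of the union
of the allowed patterns.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.isotonic import isotonic_regression

from .containers import MISSING, DegenerateDataError

#: relative tolerance (fraction of the quantification range) below which
#: two adjacent quantifications are treated as tied when naming the
#: effect type of a fitted transformation
EFFECT_TIE_TOL = 0.1

#: absolute tolerance for an all-equal (constant) quantification
CONSTANT_TOL = 1e-8


@dataclass
class ScalingSolution:
    """Fitted transformation of one SNP.

    ``quantifications`` are the restricted category scores on the scale
    of the target; ``std_quantifications`` are the same scores after the
    transformed column was standardized (the values actually entering
    the analysis), with unobserved categories filled from their nearest
    observed genotypic neighbour so new data can always be mapped.
    """

    snp_id: object
    quantifications: np.ndarray
    std_quantifications: np.ndarray
    effect_type: str
    direction: str
    transformed_column: np.ndarray | None = None


def unrestricted_quantification(codes_j: np.ndarray, target: np.ndarray) -> dict:
    """Least-squares category scores: the mean of ``target`` per category."""
    codes_j = np.asarray(codes_j)
    target = np.asarray(target, dtype=float)
    out = {}
    for cat in np.unique(codes_j[codes_j != MISSING]):
        mask = codes_j == cat
        if not mask.any():
            raise DegenerateDataError(f"category {cat} has no observations")
        out[int(cat)] = float(target[mask].mean())
    if not out:
        raise DegenerateDataError("SNP column has no observed categories")
    return out


def _weighted_sse(raw, fit, counts):
    return float(np.sum(counts * (np.asarray(raw) - np.asarray(fit)) ** 2))


def restrict_quantification(raw, counts):
    """Project raw category scores onto the monotone cone.

    Runs weighted pooled-adjacent-violators in ascending and descending
    genotypic order and keeps the direction with the smaller weighted
    sum of squares (ascending on a tie). Returns
    ``(restricted scores, effect_type, direction)``.
    """
    raw = np.asarray(raw, dtype=float)
    counts = np.asarray(counts, dtype=float)
    if raw.shape != counts.shape:
        raise ValueError("raw and counts must align")
    # unobserved categories get a vanishing weight: they do not affect
    # the projection but keep the solver's strictly-positive contract
    w = np.where(counts > 0, counts, 1e-12)
    asc = isotonic_regression(raw, sample_weight=w, increasing=True)
    desc = isotonic_regression(raw, sample_weight=w, increasing=False)
    sse_asc = _weighted_sse(raw, asc, counts)
    sse_desc = _weighted_sse(raw, desc, counts)
    if sse_desc < sse_asc:
        restricted, direction = desc, "descending"
    else:
        restricted, direction = asc, "ascending"
    return restricted, classify_effect(restricted), direction


def classify_effect(quants, rel_tol: float = EFFECT_TIE_TOL) -> str:
    """Name the genetic-effect pattern of monotone quantifications.

    Adjacent categories are considered tied when their gap is below
    ``rel_tol`` times the total quantification range — fitted scores
    from noisy data are never exactly equal unless the monotone
    projection pooled them, so a practical band is needed to recognise
    dominant/recessive shapes. For a two-category quantification the
    pattern of the merged classes is reported (a collapsed
    homozygous-rare class yields a dominant-type coding).
    """
    q = np.asarray(quants, dtype=float)
    diffs = np.diff(q)
    if not ((diffs >= 0).all() or (diffs <= 0).all()):
        raise ValueError("quantifications must be monotone")
    rng = float(q.max() - q.min())
    if rng <= CONSTANT_TOL:
        return "constant"
    if len(q) == 2:
        return "dominant"
    gaps = np.abs(diffs)
    lo_tied = gaps[0] <= rel_tol * rng
    hi_tied = gaps[1] <= rel_tol * rng
    if lo_tied and hi_tied:
        # both gaps small: call the tighter tie
        return "recessive" if gaps[0] <= gaps[1] else "dominant"
    if lo_tied:
        return "recessive"
    if hi_tied:
        return "dominant"
    return "additive"


def transform_variable(codes_j, quantifications):
    """Map codes through category scores and standardize the column.

    Constant quantifications give an all-zero column (the variable
    carries no information at any monotone scoring).
    """
    codes_j = np.asarray(codes_j)
    q = np.asarray(quantifications, dtype=float)
    x = q[codes_j]
    sd = x.std()
    if sd <= CONSTANT_TOL:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def _fill_unobserved(quants, observed):
    """Fill scores of unobserved categories from the nearest observed one."""
    q = np.array(quants, dtype=float)
    obs_idx = np.where(observed)[0]
    for k in range(len(q)):
        if not observed[k]:
            q[k] = q[obs_idx[np.argmin(np.abs(obs_idx - k))]]
    return q


def scale_snp(codes_j, target, snp_id=None) -> ScalingSolution:
    """Full optimal-scaling pipeline for one SNP against a target."""
    codes_j = np.asarray(codes_j)
    target = np.asarray(target, dtype=float)
    raw_map = unrestricted_quantification(codes_j, target)
    observed = np.array([k in raw_map for k in range(3)])
    counts = np.array([(codes_j == k).sum() for k in range(3)], dtype=float)
    raw = _fill_unobserved(
        [raw_map.get(k, np.nan) for k in range(3)], observed
    )
    # interpolate a missing middle category so it cannot create violations
    if not observed[1] and observed[0] and observed[2]:
        raw[1] = 0.5 * (raw[0] + raw[2])
    restricted, _, direction = restrict_quantification(raw, counts)
    effect = classify_effect(restricted)
    col = transform_variable(codes_j, restricted)
    if col.std() <= CONSTANT_TOL:
        effect = "constant"
        std_q = np.zeros(3)
    else:
        x = restricted[codes_j]
        std_q = (restricted - x.mean()) / x.std()
    return ScalingSolution(
        snp_id=snp_id,
        quantifications=np.asarray(restricted, dtype=float),
        std_quantifications=std_q,
        effect_type=effect,
        direction=direction,
        transformed_column=col,
    )


def solutions_to_table(solutions, path=None):
    """Tabulate fitted transformations (snp_id, c0, c1, c2, effect, direction).

    Written as delimited text when ``path`` is given; the table is the
    exchange format for freezing transformations across model fits.
    """
    import pandas as pd

    rows = [
        {
            "snp_id": s.snp_id,
            "c0": s.std_quantifications[0],
            "c1": s.std_quantifications[1],
            "c2": s.std_quantifications[2],
            "effect_type": s.effect_type,
            "direction": s.direction,
        }
        for s in solutions
    ]
    df = pd.DataFrame(rows, columns=["snp_id", "c0", "c1", "c2", "effect_type", "direction"])
    if path is not None:
        df.to_csv(path, index=False, float_format="%.12g")
    return df


def table_to_solutions(df) -> list:
    """Rebuild :class:`ScalingSolution` records from a table or CSV path."""
    import pandas as pd

    if not hasattr(df, "columns"):
        df = pd.read_csv(df)
    out = []
    for _, row in df.iterrows():
        q = np.array([row["c0"], row["c1"], row["c2"]], dtype=float)
        out.append(
            ScalingSolution(
                snp_id=row["snp_id"],
                quantifications=q,
                std_quantifications=q.copy(),
                effect_type=row["effect_type"],
                direction=row["direction"],
            )
        )
    return out


def scale_matrix(codes: np.ndarray, target: np.ndarray):
    """Optimally scale every SNP column of ``codes`` against ``target``.

    Vectorized three-point weighted pooled-adjacent-violators over all
    SNPs at once; equivalent to calling :func:`scale_snp` per column
    but orders of magnitude faster inside the alternating algorithm.

    Returns ``(X_star, std_quants)`` where ``X_star`` is the n x q
    matrix of standardized transformed columns (all-zero for SNPs that
    scale to a constant) and ``std_quants`` is q x 3 giving the
    standardized score of each category (rows of constant SNPs are 0).
    """
    codes = np.asarray(codes)
    target = np.asarray(target, dtype=float)
    n, q = codes.shape
    masks = [codes == k for k in range(3)]
    w = np.stack([m.sum(axis=0) for m in masks]).astype(float)  # 3 x q
    s = np.stack([target @ m for m in masks])  # 3 x q category sums
    with np.errstate(invalid="ignore", divide="ignore"):
        m = s / w
    # unobserved categories: weight 0; give them a neutral value
    m0, m1, m2 = m
    w0, w1, w2 = w
    m0 = np.where(w0 > 0, m0, np.where(w1 > 0, m1, m2))
    m2 = np.where(w2 > 0, m2, np.where(w1 > 0, m1, m0))
    m1 = np.where(w1 > 0, m1, 0.5 * (m0 + m2))

    asc = _pava3(m0, m1, m2, w0, w1, w2)
    desc = [-c for c in _pava3(-m0, -m1, -m2, w0, w1, w2)]
    sse_asc = sum(wk * (mk - ck) ** 2 for wk, mk, ck in zip(w, (m0, m1, m2), asc))
    sse_desc = sum(wk * (mk - ck) ** 2 for wk, mk, ck in zip(w, (m0, m1, m2), desc))
    use_desc = sse_desc < sse_asc
    quants = np.where(use_desc, np.stack(desc), np.stack(asc))  # 3 x q

    # standardize with the category-count weights
    mean = (w * quants).sum(axis=0) / n
    var = (w * (quants - mean) ** 2).sum(axis=0) / n
    sd = np.sqrt(var)
    constant = sd <= CONSTANT_TOL
    safe_sd = np.where(constant, 1.0, sd)
    std_q = (quants - mean) / safe_sd
    std_q[:, constant] = 0.0
    X_star = std_q[codes, np.arange(q)[None, :]]
    return X_star, std_q.T


def _pava3(c0, c1, c2, w0, w1, w2):
    """Closed-form ascending weighted PAVA for three points, vectorized."""
    with np.errstate(invalid="ignore", divide="ignore"):
        p01 = np.where(w0 + w1 > 0, (w0 * c0 + w1 * c1) / np.maximum(w0 + w1, 1e-300), c0)
        p12 = np.where(w1 + w2 > 0, (w1 * c1 + w2 * c2) / np.maximum(w1 + w2, 1e-300), c2)
        tot = np.maximum(w0 + w1 + w2, 1e-300)
        pall = (w0 * c0 + w1 * c1 + w2 * c2) / tot
    v01 = c0 > c1
    # branch A: no initial violation
    a_v12 = c1 > c2
    a_pool_all = a_v12 & (c0 > p12)
    r0_a = np.where(a_pool_all, pall, c0)
    r1_a = np.where(a_pool_all, pall, np.where(a_v12, p12, c1))
    r2_a = np.where(a_pool_all, pall, np.where(a_v12, p12, c2))
    # branch B: 0,1 pooled first
    b_pool_all = p01 > c2
    r0_b = np.where(b_pool_all, pall, p01)
    r1_b = np.where(b_pool_all, pall, p01)
    r2_b = np.where(b_pool_all, pall, c2)
    r0 = np.where(v01, r0_b, r0_a)
    r1 = np.where(v01, r1_b, r1_a)
    r2 = np.where(v01, r2_b, r2_a)
    return r0, r1, r2
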