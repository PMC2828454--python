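"""Penalized nonlinear canonical correlation analysis.

The two-block alternating algorithm (Wold's Mode B regression framing):

* phenotype side — the weights ``u`` of the summary matrix ``Y`` are
  estimated by weighted-least-squares backfitting against the current
  SNP variate, with per-cell weights equal to the reciprocal squared
  standard errors of the random-effect summaries;
* SNP side — every SNP is optimally scaled against the current
  phenotype variate, and the weights ``v`` are the univariately
  soft-thresholded correlations, with the threshold chosen each
  iteration so a preset number of SNPs survives. With selection
  disabled the SNP side is an ordinary least-squares regression, which
  makes the procedure classical CCA on fixed columns.

Successive canonical pairs are obtained by deflating ``Y`` on the
previous phenotype variate; previously selected SNPs can optionally be
frozen at their first fitted transformation.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np

from .containers import DegenerateDataError, PnccaError
from .scaling import CONSTANT_TOL, ScalingSolution, classify_effect, scale_matrix

logger = logging.getLogger(__name__)


class EmptyModelError(PnccaError):
    """All SNP weights were shrunk to zero at the requested penalty."""


class InfeasibleSupportError(PnccaError):
    pass


@dataclass
class PnccaConfig:
    """Tuning parameters of the alternating fit.

    n_snps
        target SNP support size; ``None`` disables selection and uses
        ordinary least squares on the SNP side (dense weights).
    scaling
        ``"optimal"`` rescales every SNP against the current phenotype
        variate each iteration; ``"additive"`` fixes the standardized
        0/1/2 coding (used for oracle comparisons and quick screens).
    ridge_y
        ridge added (scaled by the mean weight) to each univariate
        backfitting denominator; used from the second pair onward to
        tame the multicollinearity deflation introduces.
    """

    n_snps: int | None = 5
    max_iter: int = 200
    tol: float = 1e-6
    backfit_tol: float = 1e-8
    backfit_max_iter: int = 1000
    ridge_y: float = 1e-3
    fix_transformations: bool = False
    scaling: str = "optimal"
    init: str = "rowmean"
    n_starts: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.n_snps is not None and self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.ridge_y < 0:
            raise ValueError("ridge_y must be >= 0")


@dataclass
class CanonicalPair:
    """One fitted canonical variate pair."""

    u: np.ndarray
    v: np.ndarray
    omega: np.ndarray
    xi: np.ndarray
    rho: float
    support: np.ndarray
    scaling: dict            # snp index -> ScalingSolution
    std_quants: np.ndarray   # q x 3 standardized category scores
    y_loadings: np.ndarray
    y_cross_loadings: np.ndarray
    x_loadings: dict
    x_cross_loadings: dict
    iterations: int
    converged: bool


def ust(scores: np.ndarray, lam: float) -> np.ndarray:
    """Univariate soft-thresholding of per-SNP coefficients.

    ``v_j = sign(s_j) (|s_j| - lam)_+``. Raises :class:`EmptyModelError`
    when every weight is shrunk to zero; the caller should lower the
    penalty. Scaling of the result is left to the caller (weights are
    renormalized against the variate they produce).
    """
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    scores = np.asarray(scores, dtype=float)
    v = np.sign(scores) * np.maximum(np.abs(scores) - lam, 0.0)
    if not np.any(v):
        raise EmptyModelError(f"no SNP survives the penalty lambda={lam}")
    return v


def penalty_for_support(scores: np.ndarray, k: int) -> float:
    """Penalty at which soft-thresholding keeps exactly ``k`` SNPs.

    Returns the midpoint between the k-th and (k+1)-th largest
    absolute score; with exact ties at the boundary a value just below
    the k-th largest is returned and more than ``k`` SNPs survive.
    """
    a = np.sort(np.abs(np.asarray(scores, dtype=float)))[::-1]
    q = len(a)
    if not 1 <= k <= q:
        raise InfeasibleSupportError(f"k={k} outside [1, {q}]")
    if k > np.count_nonzero(a):
        raise InfeasibleSupportError(
            f"k={k} exceeds the {np.count_nonzero(a)} nonzero scores"
        )
    if k == q:
        return float(a[-1] / 2)
    if a[k - 1] > a[k]:
        return float((a[k - 1] + a[k]) / 2)
    logger.info("tied scores at the support boundary; keeping all tied SNPs")
    return float(a[k - 1] * (1 - 1e-12))


def wls_backfit(
    Y: np.ndarray,
    xi: np.ndarray,
    W: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 1000,
    ridge: float = 0.0,
    u0: np.ndarray | None = None,
):
    """Estimate phenotype weights by cyclic univariate weighted LS.

    Each coordinate ``u_j`` is refitted against the partial residual
    ``z = xi - Y_{-j} u_{-j}`` with per-subject weights ``W[:, j]``,
    so subjects whose summary j has a large standard error contribute
    little to ``u_j``. With equal weights the procedure converges to
    the multiple-OLS coefficients of ``xi`` on ``Y``.

    Returns ``(u, converged, n_iter)``.
    """
    Y = np.asarray(Y, dtype=float)
    xi = np.asarray(xi, dtype=float)
    W = np.asarray(W, dtype=float)
    n, m = Y.shape
    if (W < 0).any():
        raise ValueError("weights must be >= 0")
    u = np.ones(m) if u0 is None else np.asarray(u0, dtype=float).copy()

    # The cyclic update u_j <- (W_j Y_j)'(xi - Y_{-j} u_{-j}) / (W_j Y_j)'Y_j
    # only touches the data through the m x m cross-products
    # M[j, l] = (W_j * Y_j)' Y_l and b[j] = (W_j * Y_j)' xi, so the sweeps
    # are run in coefficient space (identical iterates, O(m^2) per sweep).
    A = W * Y
    M = A.T @ Y
    b = A.T @ xi
    den = np.diag(M).copy() + ridge * W.mean(axis=0) * n
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        max_delta = 0.0
        for j in range(m):
            new = (b[j] - M[j] @ u + M[j, j] * u[j]) / den[j]
            max_delta = max(max_delta, abs(new - u[j]))
            u[j] = new
        if max_delta < tol:
            converged = True
            break
    if not converged:
        # the sweeps' fixed point solves (M + ridge diag) u = b; on a
        # stall (strong collinearity) solve it directly
        Mr = M.copy()
        Mr[np.arange(m), np.arange(m)] = den
        try:
            u_direct = np.linalg.solve(Mr, b)
            if np.isfinite(u_direct).all():
                u = u_direct
                converged = True
        except np.linalg.LinAlgError:
            logger.warning("backfitting did not converge in %d sweeps", max_iter)
    return u, converged, it


def _standardize_codes(codes: np.ndarray) -> np.ndarray:
    """Additive 0/1/2 coding, columns standardized (constant -> zero)."""
    X = codes.astype(float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd_safe = np.where(sd <= CONSTANT_TOL, 1.0, sd)
    X = (X - mu) / sd_safe
    X[:, sd <= CONSTANT_TOL] = 0.0
    return X


def _initial_xi(codes: np.ndarray, config: PnccaConfig, start: int = 0) -> np.ndarray:
    """Starting SNP variate for restart ``start``.

    Restart 0 uses the standardized row mean of the additive-coded
    matrix (deterministic); later restarts use seeded random vectors.
    The alternating objective is multimodal, so the fit is repeated
    from ``config.n_starts`` starting points and the best-correlating
    solution kept.
    """
    n = codes.shape[0]
    if start > 0 or config.init == "random":
        rng = np.random.default_rng(config.seed % (2**31) + 7919 * start)
        xi = rng.standard_normal(n)
    else:
        xi = _standardize_codes(codes).mean(axis=1)
    sd = xi.std()
    if sd <= CONSTANT_TOL:
        rng = np.random.default_rng(config.seed % (2**31) + 7919 * start + 1)
        xi = rng.standard_normal(n)
        sd = xi.std()
    return (xi - xi.mean()) / sd


def _corr(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    den = np.sqrt((a @ a) * (b @ b))
    if den == 0:
        return 0.0
    return float(a @ b / den)


def fit_canonical_pair(
    codes: np.ndarray,
    Y: np.ndarray,
    W: np.ndarray,
    config: PnccaConfig,
    frozen_quants: dict | None = None,
    snp_ids=None,
) -> CanonicalPair:
    """Alternate the two block updates until ``u`` and ``v`` converge.

    ``Y`` must arrive standardized (mean-zero, unit-variance columns).
    ``frozen_quants`` maps SNP column index -> standardized category
    scores fixed from an earlier pair (the SNP is then not re-scaled).
    The fit is restarted from ``config.n_starts`` initial variates and
    the solution with the largest canonical correlation is returned.
    """
    best = None
    for start in range(max(1, config.n_starts)):
        pair = _fit_single(codes, Y, W, config, frozen_quants, snp_ids, start)
        if best is None or pair.rho > best.rho:
            best = pair
    return best


def _fit_single(
    codes: np.ndarray,
    Y: np.ndarray,
    W: np.ndarray,
    config: PnccaConfig,
    frozen_quants: dict | None,
    snp_ids,
    start: int,
) -> CanonicalPair:
    codes = np.asarray(codes)
    Y = np.asarray(Y, dtype=float)
    W = np.asarray(W, dtype=float)
    n, m = Y.shape
    q = codes.shape[1]
    frozen_quants = frozen_quants or {}

    if config.scaling == "additive":
        X_star = _standardize_codes(codes)
        std_quants = None
    elif config.scaling != "optimal":
        raise ValueError(f"unknown scaling mode {config.scaling!r}")

    xi = _initial_xi(codes, config, start)
    u_prev = None
    v_prev = None
    u = np.ones(m)
    v = np.zeros(q)
    converged = False
    it = 0
    frozen_idx = np.array(sorted(frozen_quants), dtype=int)
    for it in range(1, config.max_iter + 1):
        u, _, _ = wls_backfit(
            Y, xi, W,
            tol=config.backfit_tol,
            max_iter=config.backfit_max_iter,
            ridge=config.ridge_y,
        )
        omega = Y @ u
        sd = omega.std()
        if sd <= CONSTANT_TOL:
            raise DegenerateDataError("phenotype variate collapsed to a constant")
        u = u / sd
        omega = omega / sd

        if config.scaling == "optimal":
            X_star, std_quants = scale_matrix(codes, omega)
            if len(frozen_idx):
                for j in frozen_idx:
                    fq = frozen_quants[j]
                    std_quants[j] = fq
                    X_star[:, j] = fq[codes[:, j]]
        scores = X_star.T @ omega / n
        if config.n_snps is None:
            v, *_ = np.linalg.lstsq(X_star, omega, rcond=None)
        else:
            lam = penalty_for_support(scores, config.n_snps)
            v = ust(scores, lam)
        xi = X_star @ v
        sd = xi.std()
        if sd <= CONSTANT_TOL:
            raise DegenerateDataError("SNP variate collapsed to a constant")
        v = v / sd
        xi = xi / sd

        if u_prev is not None:
            sign = -1.0 if u @ u_prev + v @ v_prev < 0 else 1.0
            if (
                np.max(np.abs(u - sign * u_prev)) < config.tol
                and np.max(np.abs(v - sign * v_prev)) < config.tol
            ):
                converged = True
                break
        u_prev, v_prev = u.copy(), v.copy()
    if not converged:
        logger.warning("alternating fit did not converge in %d iterations", it)

    # sign convention: largest-|weight| SNP gets a positive weight
    pivot = int(np.argmax(np.abs(v)))
    if v[pivot] < 0:
        u, v, omega, xi = -u, -v, -omega, -xi

    support = np.flatnonzero(v)
    if config.scaling == "additive":
        # category scores implied by the fixed standardized 0/1/2 coding
        std_quants = np.zeros((q, 3))
        for j in range(q):
            col = codes[:, j].astype(float)
            sd_j = col.std()
            if sd_j > CONSTANT_TOL:
                std_quants[j] = (np.arange(3) - col.mean()) / sd_j

    scaling_solutions = {}
    for j in support:
        quants = std_quants[j]
        scaling_solutions[int(j)] = ScalingSolution(
            snp_id=None if snp_ids is None else snp_ids[j],
            quantifications=quants.copy(),
            std_quantifications=quants.copy(),
            effect_type=classify_effect(quants),
            direction="ascending" if quants[0] <= quants[2] else "descending",
        )

    y_loadings = np.array([_corr(Y[:, j], omega) for j in range(m)])
    y_cross = np.array([_corr(Y[:, j], xi) for j in range(m)])
    x_loadings = {int(j): _corr(X_star[:, j], xi) for j in support}
    x_cross = {int(j): _corr(X_star[:, j], omega) for j in support}

    return CanonicalPair(
        u=u, v=v, omega=omega, xi=xi,
        rho=_corr(omega, xi),
        support=support,
        scaling=scaling_solutions,
        std_quants=std_quants,
        y_loadings=y_loadings,
        y_cross_loadings=y_cross,
        x_loadings=x_loadings,
        x_cross_loadings=x_cross,
        iterations=it,
        converged=converged,
    )


def deflate_y(Y: np.ndarray, omega: np.ndarray) -> np.ndarray:
    """Residualize every column of ``Y`` on the phenotype variate."""
    Y = np.asarray(Y, dtype=float)
    omega = np.asarray(omega, dtype=float)
    om = omega - omega.mean()
    theta = Y.T @ om / (om @ om)
    return Y - np.outer(om, theta)


def transform_with_quants(codes: np.ndarray, std_quants: np.ndarray) -> np.ndarray:
    """Map new genotype codes through fitted standardized category scores.

    Categories unseen in training were filled from their merged/nearest
    class during fitting, so every code in {0,1,2} maps to a value.
    """
    codes = np.asarray(codes)
    q = codes.shape[1]
    return std_quants.T[codes, np.arange(q)[None, :]]


def apply_model(pair: CanonicalPair, codes_new: np.ndarray, Y_new: np.ndarray) -> float:
    """Out-of-sample canonical correlation.

    ``Y_new`` must be standardized with the training parameters; the
    SNP block is transformed with the training quantifications and the
    training weight vectors are applied without refitting.
    """
    X_star = transform_with_quants(codes_new, pair.std_quants)
    omega = np.asarray(Y_new, dtype=float) @ pair.u
    xi = X_star @ pair.v
    return _corr(omega, xi)


@dataclass
class ColumnStandardizer:
    """Mean/SD column scaler whose parameters persist in the model bundle."""

    mean: np.ndarray
    sd: np.ndarray

    @classmethod
    def fit(cls, M: np.ndarray) -> "ColumnStandardizer":
        M = np.asarray(M, dtype=float)
        sd = M.std(axis=0)
        if (sd <= CONSTANT_TOL).any():
            raise DegenerateDataError("constant column cannot be standardized")
        return cls(mean=M.mean(axis=0), sd=sd)

    def transform(self, M: np.ndarray) -> np.ndarray:
        return (np.asarray(M, dtype=float) - self.mean) / self.sd


@dataclass
class PnccaModel:
    """Sequence of canonical pairs plus everything needed to apply them."""

    config: PnccaConfig
    y_columns: list
    snp_ids: list
    y_scaler: ColumnStandardizer = None
    pairs: list = field(default_factory=list)
    deflation: list = field(default_factory=list)  # per pair: (theta, post scaler)

    def fit(self, codes: np.ndarray, Y_raw: np.ndarray, W: np.ndarray, n_pairs: int = 1):
        """Fit ``n_pairs`` successive canonical pairs.

        The first pair uses no ridge on the phenotype side; later pairs
        use ``config.ridge_y`` against deflation-induced collinearity.
        After each pair ``Y`` is residualized on the fitted phenotype
        variate and re-standardized.
        """
        self.y_scaler = ColumnStandardizer.fit(Y_raw)
        Ys = self.y_scaler.transform(Y_raw)
        frozen: dict = {}
        for r in range(n_pairs):
            cfg = PnccaConfig(**{**asdict(self.config), "ridge_y": 0.0 if r == 0 else self.config.ridge_y})
            pair = fit_canonical_pair(
                codes, Ys, W, cfg,
                frozen_quants=frozen if self.config.fix_transformations else None,
                snp_ids=self.snp_ids,
            )
            self.pairs.append(pair)
            if self.config.fix_transformations:
                for j in pair.support:
                    frozen.setdefault(int(j), pair.std_quants[int(j)].copy())
            if r < n_pairs - 1:
                om = pair.omega - pair.omega.mean()
                theta = Ys.T @ om / (om @ om)
                Y_res = Ys - np.outer(om, theta)
                post = ColumnStandardizer.fit(Y_res)
                self.deflation.append((theta, post))
                Ys = post.transform(Y_res)
        return self

    def apply(self, codes_new: np.ndarray, Y_new_raw: np.ndarray) -> list:
        """Per-pair out-of-sample canonical correlations."""
        Ys = self.y_scaler.transform(Y_new_raw)
        rhos = []
        for r, pair in enumerate(self.pairs):
            rhos.append(apply_model(pair, codes_new, Ys))
            if r < len(self.deflation):
                theta, post = self.deflation[r]
                om = Ys @ pair.u
                om = om - om.mean()
                Ys = post.transform(Ys - np.outer(om, theta))
        return rhos

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "config": asdict(self.config),
            "y_columns": list(map(str, self.y_columns)),
            "snp_ids": list(map(str, self.snp_ids)),
            "y_scaler": {"mean": self.y_scaler.mean.tolist(), "sd": self.y_scaler.sd.tolist()},
            "deflation": [
                {"theta": t.tolist(), "mean": p.mean.tolist(), "sd": p.sd.tolist()}
                for t, p in self.deflation
            ],
            "pairs": [
                {
                    "u": p.u.tolist(),
                    "v": {str(int(j)): float(p.v[j]) for j in p.support},
                    "rho": p.rho,
                    "support": p.support.tolist(),
                    "std_quants": p.std_quants.tolist(),
                    "y_loadings": p.y_loadings.tolist(),
                    "y_cross_loadings": p.y_cross_loadings.tolist(),
                    "x_loadings": {str(k): v for k, v in p.x_loadings.items()},
                    "x_cross_loadings": {str(k): v for k, v in p.x_cross_loadings.items()},
                    "scaling": {
                        str(k): {
                            "snp_id": None if s.snp_id is None else str(s.snp_id),
                            "quantifications": s.quantifications.tolist(),
                            "effect_type": s.effect_type,
                            "direction": s.direction,
                        }
                        for k, s in p.scaling.items()
                    },
                    "iterations": p.iterations,
                    "converged": p.converged,
                }
                for p in self.pairs
            ],
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "PnccaModel":
        model = cls(
            config=PnccaConfig(**d["config"]),
            y_columns=d["y_columns"],
            snp_ids=d["snp_ids"],
            y_scaler=ColumnStandardizer(
                mean=np.array(d["y_scaler"]["mean"]), sd=np.array(d["y_scaler"]["sd"])
            ),
        )
        for rec in d["deflation"]:
            model.deflation.append(
                (
                    np.array(rec["theta"]),
                    ColumnStandardizer(mean=np.array(rec["mean"]), sd=np.array(rec["sd"])),
                )
            )
        for prec in d["pairs"]:
            q = len(d["snp_ids"])
            v = np.zeros(q)
            for k, val in prec["v"].items():
                v[int(k)] = val
            std_quants = np.array(prec["std_quants"])
            scaling = {
                int(k): ScalingSolution(
                    snp_id=s["snp_id"],
                    quantifications=np.array(s["quantifications"]),
                    std_quantifications=np.array(s["quantifications"]),
                    effect_type=s["effect_type"],
                    direction=s["direction"],
                )
                for k, s in prec["scaling"].items()
            }
            model.pairs.append(
                CanonicalPair(
                    u=np.array(prec["u"]),
                    v=v,
                    omega=None,
                    xi=None,
                    rho=prec["rho"],
                    support=np.array(prec["support"], dtype=int),
                    scaling=scaling,
                    std_quants=std_quants,
                    y_loadings=np.array(prec["y_loadings"]),
                    y_cross_loadings=np.array(prec["y_cross_loadings"]),
                    x_loadings={int(k): v for k, v in prec["x_loadings"].items()},
                    x_cross_loadings={int(k): v for k, v in prec["x_cross_loadings"].items()},
                    iterations=prec["iterations"],
                    converged=prec["converged"],
                )
            )
        return model

    @classmethod
    def from_json(cls, path) -> "PnccaModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))
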