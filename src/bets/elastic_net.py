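"""Penalized VAR fitting, hyperparameter selection and permutation edge FDR.

The per-gene objective is

    min_b  || y - X b ||_2^2  +  lambda * ( a ||b||_1 + (1 - a) ||b||_2^2 )

with mixing weight ``a`` in [0, 1] (a=1 lasso, a=0 ridge) and no intercept
(profiles are centred).  scikit-learn's coordinate descent minimises

    (1/2n) || y - X b ||_2^2  +  alpha ( l1 ||b||_1 + (1-l1)/2 ||b||_2^2 )

so parameters are remapped as ``alpha = lambda (2 - a) / (2 n)`` and
``l1_ratio = a / (2 - a)``; the pure-ridge case (a = 0) is solved by the
closed-form normal equations instead.

The permutation null refits each gene's regression with every *other*
gene's lagged profile independently shuffled over time; comparing real and
null coefficient magnitudes yields a per-(effect gene, lag) threshold that
controls the estimated edge false-discovery proportion.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.linear_model import ElasticNet, enet_path

from .design import LaggedDesign, build_null_design
from .timeseries import ExpressionTimeSeries

__all__ = [
    "PenaltyConfig",
    "EdgeFDRResult",
    "elastic_net_fit",
    "loocv_select",
    "permute_profiles",
    "fit_null_coefficients",
    "edge_fdr_threshold",
    "export_coefficients",
    "fdr_threshold",
]

logger = logging.getLogger(__name__)

DEFAULT_SEED = 42

_ENET_TOL = 1e-8
_ENET_MAX_ITER = 100_000


def _default_lambda_grid() -> tuple[float, ...]:
    return tuple(10.0 ** np.arange(-4, 1))


def _default_a_grid() -> tuple[float, ...]:
    return (0.1, 0.3, 0.5, 0.7, 0.9)


@dataclass(frozen=True)
class PenaltyConfig:
    """Hyperparameter grids for the penalised VAR.

    Defaults are the elastic-net grids lambda in {1e-4, ..., 1} and
    a in {0.1, 0.3, ..., 0.9}.  ``lasso`` pins a = 1, ``ridge`` a = 0.
    """

    lambda_grid: tuple[float, ...] = field(default_factory=_default_lambda_grid)
    a_grid: tuple[float, ...] = field(default_factory=_default_a_grid)
    penalty_kind: str = "elastic_net"

    def __post_init__(self) -> None:
        lam = tuple(float(x) for x in self.lambda_grid)
        object.__setattr__(self, "lambda_grid", lam)
        if self.penalty_kind == "lasso":
            a = (1.0,)
        elif self.penalty_kind == "ridge":
            a = (0.0,)
        elif self.penalty_kind == "elastic_net":
            a = tuple(float(x) for x in self.a_grid)
        else:
            raise ValueError(f"unknown penalty_kind {self.penalty_kind!r}")
        object.__setattr__(self, "a_grid", a)
        if not lam or not a:
            raise ValueError("hyperparameter grids must be non-empty")
        if any(x <= 0 for x in lam):
            raise ValueError("lambda values must be positive")
        if any(not 0.0 <= x <= 1.0 for x in a):
            raise ValueError("a values must lie in [0, 1]")

    @classmethod
    def lasso(cls, lambda_grid=None) -> "PenaltyConfig":
        grid = tuple(10.0 ** np.arange(-5, 1)) if lambda_grid is None else tuple(lambda_grid)
        return cls(grid, (1.0,), "lasso")

    @classmethod
    def ridge(cls, lambda_grid=None) -> "PenaltyConfig":
        grid = tuple(10.0 ** np.arange(-5, 7)) if lambda_grid is None else tuple(lambda_grid)
        return cls(grid, (0.0,), "ridge")


def _sklearn_params(lam: float, a: float, n_samples: int) -> tuple[float, float]:
    """Map the (lambda, a) penalty onto sklearn's (alpha, l1_ratio)."""
    alpha = lam * (2.0 - a) / (2.0 * n_samples)
    l1_ratio = a / (2.0 - a)
    return alpha, l1_ratio


def _solve(X: np.ndarray, y: np.ndarray, lam: float, a: float) -> np.ndarray:
    """Minimise the penalised least-squares objective for one gene."""
    n = X.shape[0]
    if a == 0.0:
        G = X.T @ X + lam * np.eye(X.shape[1])
        return np.linalg.solve(G, X.T @ y)
    alpha, l1_ratio = _sklearn_params(lam, a, n)
    model = ElasticNet(
        alpha=alpha,
        l1_ratio=l1_ratio,
        fit_intercept=False,
        tol=_ENET_TOL,
        max_iter=_ENET_MAX_ITER,
    )
    model.fit(X, y)
    return np.asarray(model.coef_, dtype=float)


def elastic_net_fit(design: LaggedDesign, lam: float, a: float) -> np.ndarray:
    """Fit one effect gene's penalised regression; returns the flat (L*p,) vector."""
    X, y = design.predictors, design.response
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("design contains non-finite entries")
    if not 0.0 <= a <= 1.0:
        raise ValueError("a must lie in [0, 1]")
    if lam <= 0:
        raise ValueError("lambda must be positive")
    return _solve(X, y, lam, a)


def objective(design: LaggedDesign, coef: np.ndarray, lam: float, a: float) -> float:
    """Value of the penalised objective at a coefficient vector."""
    resid = design.response - design.predictors @ coef
    return float(
        resid @ resid + lam * (a * np.abs(coef).sum() + (1.0 - a) * coef @ coef)
    )


def _loocv_errors_one_gene(
    X: np.ndarray, y: np.ndarray, lambda_grid: np.ndarray, a: float
) -> np.ndarray:
    """Sum over leave-one-out folds of held-out squared error, per lambda.

    Returns an array aligned with ``lambda_grid``.
    """
    n = X.shape[0]
    errs = np.zeros(lambda_grid.size)
    if a == 0.0:
        XtX = X.T @ X
        Xty = X.T @ y
        eye = np.eye(X.shape[1])
        for i in range(n):
            xi, yi = X[i], y[i]
            G = XtX - np.outer(xi, xi)
            c = Xty - xi * yi
            for k, lam in enumerate(lambda_grid):
                beta = np.linalg.solve(G + lam * eye, c)
                errs[k] += (yi - xi @ beta) ** 2
        return errs

    # sklearn's path solver wants decreasing alphas; remap per training size
    order = np.argsort(lambda_grid)[::-1]
    _, l1_ratio = _sklearn_params(1.0, a, 1)
    alphas = np.array([_sklearn_params(lambda_grid[k], a, n - 1)[0] for k in order])
    for i in range(n):
        # Fortran order + check_input=False skips sklearn's per-call validation,
        # which dominates at this problem size
        Xtr = np.asfortranarray(np.delete(X, i, axis=0))
        ytr = np.ascontiguousarray(np.delete(y, i))
        _, coefs, _ = enet_path(
            Xtr,
            ytr,
            l1_ratio=l1_ratio,
            alphas=alphas,
            tol=_ENET_TOL,
            max_iter=_ENET_MAX_ITER,
            precompute=False,
            check_input=False,
        )
        preds = X[i] @ coefs  # (n_alphas,)
        errs[order] += (y[i] - preds) ** 2
    return errs


def loocv_select(
    designs: list[LaggedDesign], config: PenaltyConfig
) -> tuple[float, float, np.ndarray]:
    """Select one global (lambda*, a*) by leave-one-row-out cross-validation.

    For every grid point, every gene and every row index i, the model is fit
    on the remaining rows and scored on row i; per-gene errors are divided
    by that gene's row count and summed over genes.  Ties are broken toward
    the sparser model: larger lambda, then larger a.

    Returns ``(lambda*, a*, mse_table)`` where ``mse_table[i_lam, i_a]``
    holds the summed cross-validation error.
    """
    if not designs:
        raise ValueError("no designs supplied")
    lam_grid = np.asarray(config.lambda_grid, dtype=float)
    a_grid = np.asarray(config.a_grid, dtype=float)
    mse = np.zeros((lam_grid.size, a_grid.size))
    for design in designs:
        if design.N < 2:
            raise ValueError(
                f"gene {design.effect_gene!r} has N={design.N} < 2 rows; cannot cross-validate"
            )
        for j, a in enumerate(a_grid):
            errs = _loocv_errors_one_gene(design.predictors, design.response, lam_grid, a)
            mse[:, j] += errs / design.N

    if not np.isfinite(mse).any():
        raise ValueError("cross-validation error is non-finite for every grid point")
    best = np.nanmin(np.where(np.isfinite(mse), mse, np.inf))
    # tie-break toward sparsity: largest lambda, then largest a
    candidates = [
        (lam_grid[i], a_grid[j])
        for i, j in itertools.product(range(lam_grid.size), range(a_grid.size))
        if np.isfinite(mse[i, j]) and mse[i, j] <= best * (1 + 1e-12)
    ]
    lam_star, a_star = max(candidates, key=lambda t: (t[0], t[1]))
    logger.info(
        "LOOCV selected lambda=%.4g, a=%.2g (CV error %.6g over %d grid points)",
        lam_star,
        a_star,
        best,
        mse.size,
    )
    return float(lam_star), float(a_star), mse


def permute_profiles(ts: ExpressionTimeSeries, seed: int) -> ExpressionTimeSeries:
    """Shuffle each (gene, replicate) temporal profile independently over time.

    This destroys all temporal coupling between genes while preserving each
    profile's marginal value distribution.  Reproducible given ``seed``.
    """
    if ts.has_missing:
        raise ValueError("permute_profiles requires complete data")
    rng = np.random.default_rng(seed)
    values = ts.values.copy()
    T = ts.n_times
    for g in range(ts.n_genes):
        for r in range(ts.n_replicates):
            values[g, :, r] = values[g, rng.permutation(T), r]
    return replace(ts, values=values)


def fit_null_coefficients(
    ts: ExpressionTimeSeries,
    permuted: ExpressionTimeSeries,
    effect_gene: str,
    lam: float,
    a: float,
    L: int = 2,
) -> np.ndarray:
    """Fit one gene's regression against the permutation-null design.

    The effect gene's own lagged columns and the response are unpermuted;
    all other genes' lagged columns come from the permuted data.  Uses the
    same hyperparameters as the real fit.
    """
    null_design = build_null_design(ts, permuted, effect_gene, L)
    return elastic_net_fit(null_design, lam, a)


@dataclass(frozen=True)
class EdgeFDRResult:
    """Per-(effect gene, lag) coefficient thresholds and surviving edges."""

    thresholds: dict  # (effect_gene, lag) -> float
    surviving: frozenset  # (cause, effect, lag)
    target_fdr: float

    def surviving_pairs(self) -> frozenset:
        """Edges collapsed over lags: survive if they pass at any lag."""
        return frozenset((c, e) for c, e, _ in self.surviving)


def fdr_threshold(real: np.ndarray, null: np.ndarray, target: float) -> float:
    """Smallest observed-magnitude cutoff controlling the estimated FDR.

    Scans the distinct values of ``|real| union |null|`` in increasing
    order and returns the first T for which

        #{null > T} / (#{null > T} + #{real > T})  <=  target

    with the 0/0 ratio defined as 0 (both comparisons strict).  Such a T
    always exists: at the largest observed value both counts are zero.
    """
    real = np.abs(np.asarray(real, dtype=float).ravel())
    null = np.abs(np.asarray(null, dtype=float).ravel())
    candidates = np.unique(np.concatenate([real, null]))
    real_sorted = np.sort(real)
    null_sorted = np.sort(null)
    n_real = real.size - np.searchsorted(real_sorted, candidates, side="right")
    n_null = null.size - np.searchsorted(null_sorted, candidates, side="right")
    total = n_real + n_null
    ratio = np.divide(n_null, total, out=np.zeros_like(n_null, dtype=float), where=total > 0)
    ok = np.flatnonzero(ratio <= target)
    return float(candidates[ok[0]])


def export_coefficients(real_betas: dict, result: "EdgeFDRResult", path) -> None:
    """Write fitted cross coefficients with their null thresholds as TSV.

    Columns: ``cause  effect  lag  coefficient  null_threshold  survives``.
    ``real_betas`` is the same ``(effect, lag) -> {cause: beta}`` mapping
    passed to :func:`edge_fdr_threshold`.
    """
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("cause\teffect\tlag\tcoefficient\tnull_threshold\tsurvives\n")
        for (effect, lag) in sorted(real_betas):
            T = result.thresholds[(effect, lag)]
            for cause in sorted(real_betas[(effect, lag)]):
                beta = real_betas[(effect, lag)][cause]
                survives = int((cause, effect, lag) in result.surviving)
                fh.write(f"{cause}\t{effect}\t{lag}\t{beta!r}\t{T!r}\t{survives}\n")


def edge_fdr_threshold(
    real_betas: dict, null_betas: dict, target_fdr: float = 0.05
) -> EdgeFDRResult:
    """Threshold real coefficients against the permutation null, per (gene, lag).

    ``real_betas`` and ``null_betas`` map ``(effect_gene, lag)`` to a mapping
    ``cause -> coefficient`` over the p-1 candidate causes.  An edge
    ``(cause, effect)`` survives at lag ``l`` iff ``|beta| > T_l^g``; the
    estimated FDR inequality holds at every returned threshold by
    construction.
    """
    if not 0.0 < target_fdr < 1.0:
        raise ValueError("target_fdr must lie in (0, 1)")
    if set(real_betas) != set(null_betas):
        raise ValueError("real and null coefficient keys do not match")
    thresholds: dict = {}
    surviving = set()
    for key in real_betas:
        real = real_betas[key]
        null = null_betas[key]
        if set(real) != set(null):
            raise ValueError(f"cause sets differ for {key}")
        causes = sorted(real)
        rv = np.array([real[c] for c in causes], dtype=float)
        nv = np.array([null[c] for c in causes], dtype=float)
        T = fdr_threshold(rv, nv, target_fdr)
        thresholds[key] = T
        effect, lag = key
        for c, v in zip(causes, rv):
            if abs(v) > T:
                surviving.add((c, effect, lag))
    return EdgeFDRResult(thresholds, frozenset(surviving), target_fdr)
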