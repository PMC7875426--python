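"""Lagged regression design construction for the vector autoregression.

For an effect gene ``g`` with maximum lag ``L``, the response stacks
``X_t^g`` over ``t = L+1..T`` and all replicates (time-major, replicates in
declared order), giving ``N = R (T - L)`` rows.  The predictor matrix has
``L * p`` columns in lag-major order: all genes at lag 1 (in ``gene_ids``
order), then all genes at lag 2, and so on.  The effect gene's own lagged
columns are included; they carry the autoregressive self coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .timeseries import ExpressionTimeSeries

__all__ = ["LaggedDesign", "CoefficientTensor", "build_design", "build_null_design"]


@dataclass(frozen=True)
class LaggedDesign:
    """Per-effect-gene regression problem.

    ``column_index[c]`` gives the ``(gene, lag)`` pair behind predictor
    column ``c``; columns run lag-major (lag 1 for all genes first).
    """

    effect_gene: str
    response: np.ndarray  # (N,)
    predictors: np.ndarray  # (N, L*p)
    column_index: tuple[tuple[str, int], ...]
    N: int
    L: int

    def self_columns(self, gene_ids: tuple[str, ...]) -> np.ndarray:
        """Column positions of the effect gene's own lags."""
        g = gene_ids.index(self.effect_gene)
        p = len(gene_ids)
        return np.array([ell * p + g for ell in range(self.L)])


def _lagged_predictors(values: np.ndarray, L: int) -> np.ndarray:
    """Stack lagged values into an (N, L*p) matrix, lag-major columns.

    ``values`` has shape (p, T, R); rows of the result run over
    t = L+1..T (time-major) then replicates.
    """
    p, T, R = values.shape
    blocks = []
    for ell in range(1, L + 1):
        # values at t - ell for t = L+1..T  ->  indices L-ell .. T-ell-1
        lagged = values[:, L - ell : T - ell, :]  # (p, T-L, R)
        blocks.append(np.transpose(lagged, (1, 2, 0)).reshape((T - L) * R, p))
    return np.concatenate(blocks, axis=1)


def build_design(ts: ExpressionTimeSeries, effect_gene: str, L: int) -> LaggedDesign:
    """Build the lagged design for one effect gene.

    Requires complete (no missing) data and ``T >= L + 1``.
    """
    if L < 1:
        raise ValueError("lag L must be a positive integer")
    if ts.n_times < L + 1:
        raise ValueError(f"need T >= L + 1 time points; got T={ts.n_times}, L={L}")
    if ts.has_missing:
        raise ValueError("time series has missing entries; interpolate first")
    g = ts.gene_index(effect_gene)

    p, T, R = ts.values.shape
    # C-order reshape of the (T-L, R) block gives time-major rows
    response = ts.values[g, L:, :].reshape((T - L) * R)
    predictors = _lagged_predictors(ts.values, L)
    column_index = tuple(
        (gene, ell) for ell in range(1, L + 1) for gene in ts.gene_ids
    )
    return LaggedDesign(
        effect_gene=effect_gene,
        response=response,
        predictors=predictors,
        column_index=column_index,
        N=(T - L) * R,
        L=L,
    )


def build_null_design(
    ts: ExpressionTimeSeries, permuted: ExpressionTimeSeries, effect_gene: str, L: int
) -> LaggedDesign:
    """Design for the permutation null fit of one effect gene.

    Cross-gene predictor columns come from the permuted data while the
    effect gene's own lagged columns and the response stay unpermuted, so
    the null retains the gene's autoregressive structure but severs its
    temporal coupling to every candidate cause.
    """
    if ts.gene_ids != permuted.gene_ids:
        raise ValueError("gene sets of original and permuted data do not match")
    if (
        ts.replicate_ids != permuted.replicate_ids
        or ts.n_times != permuted.n_times
    ):
        raise ValueError("original and permuted data shapes do not match")
    real = build_design(ts, effect_gene, L)
    null = build_design(permuted, effect_gene, L)
    predictors = null.predictors.copy()
    own = real.self_columns(ts.gene_ids)
    predictors[:, own] = real.predictors[:, own]
    return LaggedDesign(
        effect_gene=effect_gene,
        response=real.response,
        predictors=predictors,
        column_index=real.column_index,
        N=real.N,
        L=L,
    )


@dataclass
class CoefficientTensor:
    """Fitted VAR coefficients for all effect genes.

    ``alpha[g, l]`` is the self coefficient of effect gene ``g`` at lag
    ``l+1``; ``beta[l, c, g]`` the cross coefficient cause ``c`` -> effect
    ``g`` at lag ``l+1``.  The diagonal of each ``beta[l]`` is structurally
    zero (self-effects live only in ``alpha``).
    """

    gene_ids: tuple[str, ...]
    alpha: np.ndarray  # (p, L)
    beta: np.ndarray  # (L, p, p) with zero diagonals

    @classmethod
    def zeros(cls, gene_ids: tuple[str, ...], L: int) -> "CoefficientTensor":
        p = len(gene_ids)
        return cls(tuple(gene_ids), np.zeros((p, L)), np.zeros((L, p, p)))

    @property
    def L(self) -> int:
        return self.alpha.shape[1]

    def set_flat(self, effect_gene: str, flat: np.ndarray) -> None:
        """Unpack one effect gene's flat coefficient vector (lag-major)."""
        p = len(self.gene_ids)
        g = self.gene_ids.index(effect_gene)
        if flat.shape != (self.L * p,):
            raise ValueError(f"expected flat vector of length {self.L * p}")
        for ell in range(self.L):
            block = flat[ell * p : (ell + 1) * p]
            self.alpha[g, ell] = block[g]
            self.beta[ell, :, g] = block
            self.beta[ell, g, g] = 0.0

    def flat(self, effect_gene: str) -> np.ndarray:
        """Flat lag-major coefficient vector for one effect gene."""
        p = len(self.gene_ids)
        g = self.gene_ids.index(effect_gene)
        out = np.empty(self.L * p)
        for ell in range(self.L):
            block = self.beta[ell, :, g].copy()
            block[g] = self.alpha[g, ell]
            out[ell * p : (ell + 1) * p] = block
        return out

    def predict(self, design: LaggedDesign) -> np.ndarray:
        """Model prediction for every row of a design."""
        return design.predictors @ self.flat(design.effect_gene)
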