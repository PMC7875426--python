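"""Scoring inferred edges on held-out overexpression (perturbation) series.

Overexpression series are short and coarsely sampled, so each candidate
edge cause -> effect is scored with an unpenalised pairwise lag-1 VAR

    X_t^g = c X_{t-1}^g + d X_{t-1}^{g'} + eps_t

fit by ordinary least squares over all replicates.  Concordance between the
network's edge signs and the overexpression ``d`` coefficients is then
summarised per overexpressed cause gene by regressing a sign encoding of
the network edge (one-hot positive, one-hot negative, or signed +1/0/-1)
against the ``d`` values, with two-sided t-test p-values and
Benjamini-Hochberg adjustment across cause genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .stability import DirectedNetwork

__all__ = ["PairwiseVarFit", "pairwise_var", "sign_concordance"]

MIN_EDGES_FOR_TEST = 3


@dataclass(frozen=True)
class PairwiseVarFit:
    """OLS fit of a pairwise lag-1 autoregression for one candidate edge."""

    c: float  # self coefficient
    d: float  # cross (cause) coefficient
    residual_variance: float


def pairwise_var(
    cause_series: np.ndarray,
    effect_series: np.ndarray,
    times: np.ndarray,
    replicates: int | None = None,
) -> PairwiseVarFit:
    """Fit the pairwise lag-1 VAR by ordinary least squares.

    ``cause_series`` and ``effect_series`` are (T,) for a single replicate
    or (T, R) arrays aligned on the same time grid; the first time point of
    each replicate is dropped (its lagged value does not exist).  Lag 1 is
    used regardless of any global lag choice.  No regularisation.
    """
    cause = np.atleast_2d(np.asarray(cause_series, dtype=float).T).T
    effect = np.atleast_2d(np.asarray(effect_series, dtype=float).T).T
    if cause.shape != effect.shape:
        raise ValueError("cause and effect series must share the same shape")
    if cause.shape[0] != np.asarray(times).size:
        raise ValueError("series length does not match the time grid")

    y = effect[1:, :].ravel(order="F")
    self_lag = effect[:-1, :].ravel(order="F")
    cross_lag = cause[:-1, :].ravel(order="F")
    if y.size < MIN_EDGES_FOR_TEST:
        raise ValueError(f"need at least {MIN_EDGES_FOR_TEST} usable rows, got {y.size}")
    if np.allclose(cross_lag, 0.0):
        # degenerate but well-defined: the cross term is identically zero,
        # so d = 0 and c reduces to the AR(1) coefficient
        c = float(self_lag @ y / (self_lag @ self_lag))
        resid = y - c * self_lag
        return PairwiseVarFit(c, 0.0, float(resid @ resid / max(y.size - 2, 1)))
    X = np.column_stack([self_lag, cross_lag])
    if np.linalg.matrix_rank(X) < 2:
        raise ValueError(
            "cause and effect lagged series are collinear; pairwise VAR is degenerate"
        )
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    dof = max(y.size - 2, 1)
    return PairwiseVarFit(float(coef[0]), float(coef[1]), float(resid @ resid / dof))


def _sign_regression(encoding: np.ndarray, d_values: np.ndarray) -> tuple[float, float]:
    """Slope and two-sided t-test p-value of d ~ encoding."""
    res = stats.linregress(encoding, d_values)
    return float(res.slope), float(res.pvalue)


def sign_concordance(
    network: DirectedNetwork,
    fits: dict,
    cause_of_fit: dict | None = None,
) -> pd.DataFrame:
    """Concordance of network edge signs with overexpression VAR coefficients.

    ``fits`` maps ``(cause, effect)`` to a :class:`PairwiseVarFit` measured
    on the overexpression series; ``cause_of_fit`` optionally maps each
    scored pair to the overexpressed gene of its data set (defaults to the
    pair's cause).  Rows with fewer than three scored edges are flagged
    underpowered and carry no p-value.

    Returns one row per (overexpressed gene, encoding) with columns
    ``slope``, ``p_value``, ``p_adjusted``, ``n_edges`` and ``underpowered``.
    Encodings: ``positive_onehot`` (1 for network-positive edges),
    ``negative_onehot`` (1 for network-negative edges) and ``signed``
    (+1 / 0 / -1 by network sign, 0 for non-network pairs).
    """
    sign_by_pair = {(e.cause, e.effect): e.sign for e in network}
    groups: dict[str, list] = {}
    for pair, fit in fits.items():
        oe_gene = (cause_of_fit or {}).get(pair, pair[0])
        groups.setdefault(oe_gene, []).append((pair, fit))

    rows = []
    for oe_gene in sorted(groups):
        pairs = groups[oe_gene]
        d = np.array([fit.d for _, fit in pairs])
        net_sign = np.array([sign_by_pair.get(pair, 0) for pair, _ in pairs])
        encodings = {
            "positive_onehot": (net_sign == 1).astype(float),
            "negative_onehot": (net_sign == -1).astype(float),
            "signed": net_sign.astype(float),
        }
        for name, enc in encodings.items():
            underpowered = d.size < MIN_EDGES_FOR_TEST or np.all(enc == enc[0])
            if underpowered:
                slope, p = float("nan"), float("nan")
            else:
                slope, p = _sign_regression(enc, d)
            rows.append(
                {
                    "overexpressed_gene": oe_gene,
                    "encoding": name,
                    "slope": slope,
                    "p_value": p,
                    "n_edges": int(d.size),
                    "underpowered": bool(underpowered),
                }
            )
    df = pd.DataFrame(rows)
    if len(df):
        df["p_adjusted"] = np.nan
        for name in df["encoding"].unique():
            mask = (df["encoding"] == name) & df["p_value"].notna()
            if mask.any():
                _, p_adj, _, _ = multipletests(df.loc[mask, "p_value"], method="fdr_bh")
                df.loc[mask, "p_adjusted"] = p_adj
    return df
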