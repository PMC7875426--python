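"""Bootstrap stability selection and the permutation-calibrated stability FDR.

The edge-FDR network inference is repeated over ``B`` bootstrap resamples of
the design rows; each candidate edge's *selection frequency* pi is the
fraction of bootstrap networks containing it.  A parallel run in which a
second, independent permutation of the data plays the role of the real data
(with the first permutation still providing the coefficient null) yields
null frequencies pi-hat, and a single network-wide frequency cutoff T_b is
chosen so that the estimated stability FDR

    #{pi-hat > T_b} / (#{pi-hat > T_b} + #{pi > T_b})

stays at or below the target level (default 0.2).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from joblib import Parallel, delayed

from .design import build_design, build_null_design
from .elastic_net import _solve, fdr_threshold
from .timeseries import ExpressionTimeSeries

__all__ = [
    "BootstrapEnsemble",
    "DirectedNetwork",
    "Edge",
    "draw_bootstrap_indices",
    "selection_frequencies",
    "null_selection_frequencies",
    "stability_fdr_threshold",
    "choose_lag",
    "assemble_network",
]

logger = logging.getLogger(__name__)

DEFAULT_B = 1000
FAST_B = 100  # documented fast mode with near-equivalent edge recovery


def draw_bootstrap_indices(N: int, B: int, seed: int) -> np.ndarray:
    """Draw B multisets of N row indices, i.i.d. uniform with replacement."""
    if N < 1 or B < 1:
        raise ValueError("N and B must be >= 1")
    rng = np.random.default_rng(seed)
    return rng.integers(0, N, size=(B, N))


def _gene_problems(
    data_ts: ExpressionTimeSeries, null_ts: ExpressionTimeSeries, L: int
):
    """Per-gene (X, y, X_null, own_columns) tuples for the bootstrap loop."""
    problems = []
    for g, gene in enumerate(data_ts.gene_ids):
        real = build_design(data_ts, gene, L)
        null = build_null_design(data_ts, null_ts, gene, L)
        problems.append((real.predictors, real.response, null.predictors, g))
    return problems


def _bootstrap_block(
    problems, index_block: np.ndarray, lam: float, a: float, edge_fdr: float, L: int, p: int
) -> tuple[np.ndarray, np.ndarray]:
    """Survival counts and coefficient sums for a block of bootstrap samples.

    Returns ``(counts, coef_sum)`` each of shape (L, p, p) indexed
    [lag, cause, effect]; diagonals stay zero.  Summation over samples makes
    the reduction order-insensitive, so splitting into blocks across
    workers cannot change the result.
    """
    counts = np.zeros((L, p, p))
    coef_sum = np.zeros((L, p, p))
    off_diag = ~np.eye(p, dtype=bool)
    for rows in index_block:
        for X, y, Xn, g in problems:
            coef = _solve(X[rows], y[rows], lam, a).reshape(L, p)
            coef_null = _solve(Xn[rows], y[rows], lam, a).reshape(L, p)
            mask = off_diag[:, g]
            for ell in range(L):
                cross = coef[ell][mask]
                cross_null = coef_null[ell][mask]
                T = fdr_threshold(cross, cross_null, edge_fdr)
                survived = np.abs(cross) > T
                counts[ell, mask, g] += survived
                coef_sum[ell, mask, g] += cross
    return counts, coef_sum


def _run_bootstrap(
    data_ts: ExpressionTimeSeries,
    null_ts: ExpressionTimeSeries,
    index_sets: np.ndarray,
    lam: float,
    a: float,
    edge_fdr: float,
    L: int,
    n_jobs: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """Selection frequencies and mean coefficients over all bootstrap samples."""
    p = data_ts.n_genes
    B = index_sets.shape[0]
    problems = _gene_problems(data_ts, null_ts, L)
    if n_jobs == 1:
        counts, coef_sum = _bootstrap_block(problems, index_sets, lam, a, edge_fdr, L, p)
    else:
        blocks = np.array_split(index_sets, max(n_jobs, 1))
        results = Parallel(n_jobs=n_jobs)(
            delayed(_bootstrap_block)(problems, blk, lam, a, edge_fdr, L, p)
            for blk in blocks
            if len(blk)
        )
        counts = sum(r[0] for r in results)
        coef_sum = sum(r[1] for r in results)
    return counts / B, coef_sum / B


def selection_frequencies(
    ts: ExpressionTimeSeries,
    permuted_ts: ExpressionTimeSeries,
    index_sets: np.ndarray,
    lam: float,
    a: float,
    edge_fdr: float = 0.05,
    L: int = 2,
    n_jobs: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """Real selection frequencies pi and mean bootstrap coefficients.

    Each bootstrap sample applies the same row multiset to both the real
    design (for coefficients) and the permuted-data null design (for the
    edge-FDR threshold).  ``frequencies[l, c, g]`` is the fraction of
    bootstrap networks containing cause c -> effect g at lag l+1;
    ``mean_coefficients`` averages the fitted cross coefficients across all
    B fits, counting penalty zeros.
    """
    return _run_bootstrap(ts, permuted_ts, index_sets, lam, a, edge_fdr, L, n_jobs)


def null_selection_frequencies(
    second_permuted_ts: ExpressionTimeSeries,
    first_permuted_ts: ExpressionTimeSeries,
    index_sets: np.ndarray,
    lam: float,
    a: float,
    edge_fdr: float = 0.05,
    L: int = 2,
    n_jobs: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """Null selection frequencies pi-hat (and null mean coefficients).

    A second, independent permutation of the data plays the role of the real
    data while the first permutation still provides the coefficient null;
    the same bootstrap row indices are reused.
    """
    if np.array_equal(second_permuted_ts.values, first_permuted_ts.values):
        raise ValueError(
            "the two permuted data sets are identical; they must come from "
            "independent permutation seeds"
        )
    return _run_bootstrap(
        second_permuted_ts, first_permuted_ts, index_sets, lam, a, edge_fdr, L, n_jobs
    )


def choose_lag(mean_coefficients: np.ndarray) -> np.ndarray:
    """Per-edge lag with the larger |mean bootstrap coefficient|.

    Returns an integer (p, p) array of 0-based lag indices; exact ties go to
    the smaller lag.
    """
    return np.argmax(np.abs(mean_coefficients), axis=0)


def frequencies_at_lag(frequencies: np.ndarray, lag_star: np.ndarray) -> np.ndarray:
    """Select each edge's frequency at its chosen lag; (p, p) result."""
    return np.take_along_axis(frequencies, lag_star[None, :, :], axis=0)[0]


def stability_fdr_threshold(
    real_frequencies: np.ndarray, null_frequencies: np.ndarray, target: float = 0.2
) -> float:
    """Network-wide frequency cutoff T_b controlling the stability FDR.

    Frequencies must already be reduced to each edge's chosen lag (see
    :func:`choose_lag`), real and null sides independently.  Pooled over
    all ordered gene pairs; smallest observed candidate satisfying the
    estimated-FDR inequality (0/0 defined as 0).
    """
    if not 0.0 < target < 1.0:
        raise ValueError("target stability FDR must lie in (0, 1)")
    return fdr_threshold(real_frequencies, null_frequencies, target)


@dataclass(frozen=True)
class BootstrapEnsemble:
    """Everything the stability-FDR calibration needs, per candidate edge."""

    gene_ids: tuple[str, ...]
    B: int
    index_sets: np.ndarray  # (B, N)
    real_frequencies: np.ndarray  # (L, p, p) [lag, cause, effect]
    null_frequencies: np.ndarray
    mean_coefficients: np.ndarray
    null_mean_coefficients: np.ndarray

    def __post_init__(self) -> None:
        for arr in (self.real_frequencies, self.null_frequencies):
            if arr.min() < 0 or arr.max() > 1:
                raise ValueError("selection frequencies must lie in [0, 1]")

    @property
    def L(self) -> int:
        return self.real_frequencies.shape[0]

    def real_at_chosen_lag(self) -> tuple[np.ndarray, np.ndarray]:
        lag_star = choose_lag(self.mean_coefficients)
        return lag_star, frequencies_at_lag(self.real_frequencies, lag_star)

    def null_at_chosen_lag(self) -> tuple[np.ndarray, np.ndarray]:
        lag_star = choose_lag(self.null_mean_coefficients)
        return lag_star, frequencies_at_lag(self.null_frequencies, lag_star)


@dataclass(frozen=True)
class Edge:
    cause: str
    effect: str
    lag: int  # 1-based
    sign: int
    effect_size: float
    selection_frequency: float


@dataclass(frozen=True)
class DirectedNetwork:
    """Final signed directed network at a stability-FDR cutoff."""

    edges: tuple[Edge, ...]
    stability_threshold: float
    target_stability_fdr: float

    def __iter__(self):
        return iter(self.edges)

    def __len__(self) -> int:
        return len(self.edges)

    def edge_pairs(self) -> frozenset:
        return frozenset((e.cause, e.effect) for e in self.edges)

    def to_tsv(self, path) -> None:
        """One edge per line, sorted by descending frequency then labels."""
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("cause\teffect\tlag\tsign\teffect_size\tselection_frequency\n")
            for e in self.edges:
                fh.write(
                    f"{e.cause}\t{e.effect}\t{e.lag}\t{e.sign:+d}\t"
                    f"{e.effect_size!r}\t{e.selection_frequency!r}\n"
                )

    @classmethod
    def from_tsv(cls, path, stability_threshold=float("nan"), target=0.2):
        import pandas as pd

        df = pd.read_csv(path, sep="\t", dtype={"cause": str, "effect": str})
        edges = tuple(
            Edge(r.cause, r.effect, int(r.lag), int(r.sign), float(r.effect_size),
                 float(r.selection_frequency))
            for r in df.itertuples()
        )
        return cls(edges, stability_threshold, target)


def assemble_network(
    ensemble: BootstrapEnsemble, T_b: float, target_stability_fdr: float = 0.2
) -> DirectedNetwork:
    """Edges with selection frequency strictly above T_b, signed by mean coefficient.

    Each edge carries its chosen lag, the mean bootstrap coefficient there
    (effect size), and its selection frequency.  Self-edges are excluded
    structurally; edges whose mean coefficient is exactly zero cannot carry
    a sign and are dropped.
    """
    lag_star, freq = ensemble.real_at_chosen_lag()
    p = len(ensemble.gene_ids)
    edges = []
    for c in range(p):
        for g in range(p):
            if c == g or freq[c, g] <= T_b:
                continue
            ell = int(lag_star[c, g])
            size = float(ensemble.mean_coefficients[ell, c, g])
            if size == 0.0:
                continue
            edges.append(
                Edge(
                    cause=ensemble.gene_ids[c],
                    effect=ensemble.gene_ids[g],
                    lag=ell + 1,
                    sign=1 if size > 0 else -1,
                    effect_size=size,
                    selection_frequency=float(freq[c, g]),
                )
            )
    edges.sort(key=lambda e: (-e.selection_frequency, e.cause, e.effect))
    return DirectedNetwork(tuple(edges), float(T_b), target_stability_fdr)
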