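"""End-to-end network inference: preprocessing through stability FDR.

Stages: preprocess (drop constant genes, interpolate, centre) -> one global
leave-one-out hyperparameter search -> full-data elastic-net fit with a
permutation null (the Enet baseline network, edge FDR <= 0.05) -> bootstrap
ensemble over the same rows of real and permuted designs -> null ensemble
from a second, independent permutation -> stability FDR cutoff -> final
signed network.  Hyperparameters are tuned once on the original data and
reused for every permutation and bootstrap fit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import stability
from .design import CoefficientTensor, build_design, build_null_design
from .elastic_net import (
    PenaltyConfig,
    DEFAULT_SEED,
    edge_fdr_threshold,
    elastic_net_fit,
    loocv_select,
    permute_profiles,
)
from .stability import (
    BootstrapEnsemble,
    DirectedNetwork,
    assemble_network,
    draw_bootstrap_indices,
    stability_fdr_threshold,
)
from .timeseries import ExpressionTimeSeries, center_profiles, drop_zero_variance, interpolate_missing

__all__ = ["RunConfig", "InferenceResult", "preprocess", "run_inference"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """All knobs of one inference run; defaults are the method's published settings."""

    lag: int = 2
    penalty: PenaltyConfig = field(default_factory=PenaltyConfig)
    edge_fdr: float = 0.05
    stability_fdr: float = 0.2
    B: int = stability.DEFAULT_B
    seed_bootstrap: int = DEFAULT_SEED
    seed_permutation1: int = DEFAULT_SEED + 1
    seed_permutation2: int = DEFAULT_SEED + 2
    n_jobs: int = 1

    def __post_init__(self) -> None:
        if self.seed_permutation1 == self.seed_permutation2:
            raise ValueError("the two permutation seeds must differ (independent nulls)")
        if not 0 < self.edge_fdr < 1 or not 0 < self.stability_fdr < 1:
            raise ValueError("FDR levels must lie in (0, 1)")
        if self.lag < 1 or self.B < 1:
            raise ValueError("lag and B must be positive")


@dataclass(frozen=True)
class InferenceResult:
    """Everything a run produces, for audit and downstream scoring."""

    network: DirectedNetwork
    ensemble: BootstrapEnsemble
    enet_coefficients: CoefficientTensor  # full-data fit (baseline ranking)
    enet_network_pairs: frozenset  # Enet baseline edges at edge FDR
    lambda_star: float
    a_star: float
    stability_threshold: float
    config: RunConfig
    gene_ids: tuple[str, ...]

    def rank_by_frequency(self) -> list:
        """All candidate edges, most-selected first (the stability ranking)."""
        lag_star, freq = self.ensemble.real_at_chosen_lag()
        return self._ranked(freq)

    def rank_by_coefficient(self) -> list:
        """All candidate edges by |full-data coefficient| (the Enet ranking)."""
        score = np.max(np.abs(self.enet_coefficients.beta), axis=0)
        return self._ranked(score)

    def _ranked(self, score: np.ndarray) -> list:
        genes = self.gene_ids
        pairs = [
            (score[c, g], genes[c], genes[g])
            for c in range(len(genes))
            for g in range(len(genes))
            if c != g
        ]
        pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
        return [(c, g) for _, c, g in pairs]


def preprocess(ts: ExpressionTimeSeries) -> ExpressionTimeSeries:
    """Drop constant genes, fill missing points, centre every profile."""
    ts = drop_zero_variance(ts)
    if ts.has_missing:
        ts = interpolate_missing(ts)
    return center_profiles(ts)


def _full_fit(
    data_ts: ExpressionTimeSeries,
    null_ts: ExpressionTimeSeries,
    lam: float,
    a: float,
    L: int,
) -> tuple[CoefficientTensor, CoefficientTensor]:
    """Fit every gene on the full data and on the permutation-null design."""
    real = CoefficientTensor.zeros(data_ts.gene_ids, L)
    null = CoefficientTensor.zeros(data_ts.gene_ids, L)
    for gene in data_ts.gene_ids:
        design = build_design(data_ts, gene, L)
        real.set_flat(gene, elastic_net_fit(design, lam, a))
        null_design = build_null_design(data_ts, null_ts, gene, L)
        null.set_flat(gene, elastic_net_fit(null_design, lam, a))
    return real, null


def _betas_by_gene_lag(tensor: CoefficientTensor) -> dict:
    """(effect, lag) -> {cause: beta} mapping for the edge-FDR interface."""
    genes = tensor.gene_ids
    out = {}
    for g, effect in enumerate(genes):
        for ell in range(tensor.L):
            out[(effect, ell + 1)] = {
                cause: float(tensor.beta[ell, c, g])
                for c, cause in enumerate(genes)
                if c != g
            }
    return out


def run_inference(ts: ExpressionTimeSeries, config: RunConfig | None = None) -> InferenceResult:
    """Run the full inference pipeline on a (possibly raw) time series."""
    config = config or RunConfig()
    L = config.lag
    ts = preprocess(ts)
    p = ts.n_genes
    if p < 2:
        raise ValueError("need at least two genes with non-constant profiles")

    designs = [build_design(ts, gene, L) for gene in ts.gene_ids]
    N = designs[0].N
    lam, a, _ = loocv_select(designs, config.penalty)

    permuted1 = permute_profiles(ts, config.seed_permutation1)
    permuted2 = permute_profiles(ts, config.seed_permutation2)

    enet_real, enet_null = _full_fit(ts, permuted1, lam, a, L)
    enet_fdr = edge_fdr_threshold(
        _betas_by_gene_lag(enet_real), _betas_by_gene_lag(enet_null), config.edge_fdr
    )
    logger.info(
        "full-data fit: %d Enet edges at edge FDR <= %.2g",
        len(enet_fdr.surviving_pairs()),
        config.edge_fdr,
    )

    index_sets = draw_bootstrap_indices(N, config.B, config.seed_bootstrap)
    real_freq, mean_coef = stability.selection_frequencies(
        ts, permuted1, index_sets, lam, a, config.edge_fdr, L, config.n_jobs
    )
    null_freq, null_mean_coef = stability.null_selection_frequencies(
        permuted2, permuted1, index_sets, lam, a, config.edge_fdr, L, config.n_jobs
    )
    ensemble = BootstrapEnsemble(
        gene_ids=ts.gene_ids,
        B=config.B,
        index_sets=index_sets,
        real_frequencies=real_freq,
        null_frequencies=null_freq,
        mean_coefficients=mean_coef,
        null_mean_coefficients=null_mean_coef,
    )

    _, real_pi = ensemble.real_at_chosen_lag()
    _, null_pi = ensemble.null_at_chosen_lag()
    off = ~np.eye(p, dtype=bool)
    T_b = stability_fdr_threshold(real_pi[off], null_pi[off], config.stability_fdr)
    network = assemble_network(ensemble, T_b, config.stability_fdr)
    logger.info(
        "stability threshold T_b=%.4g -> %d edges at stability FDR <= %.2g",
        T_b,
        len(network),
        config.stability_fdr,
    )
    return InferenceResult(
        network=network,
        ensemble=ensemble,
        enet_coefficients=enet_real,
        enet_network_pairs=enet_fdr.surviving_pairs(),
        lambda_star=lam,
        a_star=a,
        stability_threshold=T_b,
        config=config,
        gene_ids=ts.gene_ids,
    )
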