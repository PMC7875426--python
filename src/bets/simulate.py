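"""Synthetic sparse-VAR data with planted, signed, lagged edges.

The generator draws a sparse coefficient tensor (self-decay on each gene's
lag-1 term, cross edges at random lags with random signs), rescales it so
the companion-form spectral radius stays below a stationarity bound, and
iterates the autoregression with Gaussian innovations from a long burn-in
so recorded series start near the stationary distribution.  Defaults mirror
the DREAM-style benchmark shape: 21 time points and 10 replicate series.

An optional perturbation phase adds a constant exogenous shift to a random
subset of genes for the first half of the series and removes it afterward,
emulating a drug-on / relax-back experiment.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .design import CoefficientTensor
from .evaluation import GoldStandard
from .timeseries import ExpressionTimeSeries

__all__ = ["PlantedNetworkSpec", "simulate_var", "add_perturbation_phase"]

SPECTRAL_RADIUS_BOUND = 0.95
BURN_IN = 200


@dataclass(frozen=True)
class PlantedNetworkSpec:
    """Ground-truth network and series dimensions for the simulator.

    ``density`` is the per-ordered-pair edge probability; each planted edge
    gets magnitude uniform in ``coefficient_range``, a negative sign with
    probability ``sign_mix``, and a uniformly random lag in 1..L.  Self
    terms decay with a lag-1 coefficient drawn from ``self_decay``.
    """

    p: int = 15
    density: float = 0.05
    L: int = 2
    coefficient_range: tuple[float, float] = (0.3, 0.8)
    sign_mix: float = 0.3
    self_decay: tuple[float, float] = (0.2, 0.5)
    noise_sd: float = 0.2
    T: int = 21
    R: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.density <= 1.0:
            raise ValueError("density must lie in [0, 1]")
        if self.p < 1 or self.T < self.L + 1 or self.R < 1 or self.L < 1:
            raise ValueError("invalid series dimensions")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def _companion_radius(beta_full: np.ndarray) -> float:
    """Spectral radius of the VAR companion matrix; beta_full is (L, p, p)
    with entry [l, c, g] the effect of cause c at lag l+1 on g."""
    L, p, _ = beta_full.shape
    comp = np.zeros((L * p, L * p))
    for ell in range(L):
        # row block 0 holds the transition from lag ell+1 values
        comp[:p, ell * p : (ell + 1) * p] = beta_full[ell].T
    if L > 1:
        comp[p:, : (L - 1) * p] = np.eye((L - 1) * p)
    return float(np.max(np.abs(np.linalg.eigvals(comp))))


def _draw_coefficients(spec: PlantedNetworkSpec, rng: np.random.Generator) -> CoefficientTensor:
    p, L = spec.p, spec.L
    tensor = CoefficientTensor.zeros(tuple(f"G{i + 1}" for i in range(p)), L)
    tensor.alpha[:, 0] = rng.uniform(*spec.self_decay, size=p)
    lo, hi = spec.coefficient_range
    for c in range(p):
        for g in range(p):
            if c == g or rng.random() >= spec.density:
                continue
            mag = rng.uniform(lo, hi)
            sign = -1.0 if rng.random() < spec.sign_mix else 1.0
            ell = int(rng.integers(0, L))
            tensor.beta[ell, c, g] = sign * mag

    full = tensor.beta.copy()
    for ell in range(L):
        full[ell] += np.diag([tensor.alpha[g, ell] for g in range(p)])
    radius = _companion_radius(full)
    for _ in range(50):
        if radius <= SPECTRAL_RADIUS_BOUND:
            break
        scale = SPECTRAL_RADIUS_BOUND / radius
        tensor.alpha *= scale
        tensor.beta *= scale
        full *= scale
        radius = _companion_radius(full)
    else:
        raise ValueError("could not rescale planted coefficients to stationarity")
    return tensor


def simulate_var(
    spec: PlantedNetworkSpec,
) -> tuple[ExpressionTimeSeries, GoldStandard, CoefficientTensor]:
    """Generate replicated series from a planted sparse VAR.

    Returns the time series (times 0..T-1, unit spacing), the gold standard
    of planted cross edges, and the coefficient tensor that generated the
    data.
    """
    rng = np.random.default_rng(spec.seed)
    tensor = _draw_coefficients(spec, rng)
    p, L, T, R = spec.p, spec.L, spec.T, spec.R

    # transition[l, c, g]: total effect (self + cross) of c at lag l+1 on g
    transition = tensor.beta.copy()
    for ell in range(L):
        transition[ell] += np.diag(tensor.alpha[:, ell])

    values = np.zeros((p, T, R))
    for r in range(R):
        hist = np.zeros((L, p))  # hist[0] = most recent
        total = BURN_IN + T
        for step in range(total):
            x = rng.normal(0.0, spec.noise_sd, size=p) if spec.noise_sd > 0 else np.zeros(p)
            for ell in range(L):
                x = x + transition[ell].T @ hist[ell]
            if L > 1:
                hist[1:] = hist[:-1]
            hist[0] = x
            if step >= BURN_IN:
                values[:, step - BURN_IN, r] = x

    ts = ExpressionTimeSeries(
        tensor.gene_ids,
        np.arange(T, dtype=float),
        tuple(f"rep{r + 1}" for r in range(R)),
        values,
    )
    true_edges = frozenset(
        (tensor.gene_ids[c], tensor.gene_ids[g])
        for c in range(p)
        for g in range(p)
        if c != g and np.any(tensor.beta[:, c, g] != 0.0)
    )
    gold = GoldStandard(tensor.gene_ids, true_edges)
    return ts, gold, tensor


def add_perturbation_phase(
    ts: ExpressionTimeSeries, affected_fraction: float, magnitude: float, seed: int
) -> ExpressionTimeSeries:
    """Shift a random subset of genes by a constant for the first half of the series.

    Exactly ``round(affected_fraction * p)`` genes are shifted for time
    indices in the first half (t index < T // 2 + T % 2 excluded; the shift
    covers indices 0 .. floor(T/2) - 1) and unshifted afterward.
    """
    rng = np.random.default_rng(seed)
    p, T, _ = ts.values.shape
    n_affected = int(round(affected_fraction * p))
    affected = rng.choice(p, size=n_affected, replace=False)
    values = ts.values.copy()
    half = T // 2
    values[affected[:, None], np.arange(half)[None, :], :] += magnitude
    return replace(ts, values=values)
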