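import numpy as np
import pytest

from bets.timeseries import ExpressionTimeSeries


@pytest.fixture
def tiny_ts() -> ExpressionTimeSeries:
    """2 genes x 3 times x 1 replicate with simple integer profiles."""
    values = np.array([[[1.0], [2.0], [3.0]], [[4.0], [5.0], [6.0]]])
    return ExpressionTimeSeries(("g1", "g2"), np.array([0.0, 1.0, 2.0]), ("r1",), values)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260930)


@pytest.fixture(scope="session")
def planted_study():
    """20 seeded pipeline replicates on planted sparse-VAR data (B=100).

    Session-scoped because each replicate runs the full inference pipeline;
    several end-to-end checks share the same run.
    """
    from bets.experiments import planted_recovery_study

    return planted_recovery_study(n_seeds=20, base_seed=0, B=100)
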