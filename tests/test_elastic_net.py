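"""Penalised VAR solver, LOOCV selection and permutation edge FDR.

The solver is checked against three independent oracles: the closed-form
ridge solution, soft-thresholding on an orthonormal design, and a naive
coordinate-descent minimiser of the penalised objective written here.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bets.design import LaggedDesign, build_design
from bets.elastic_net import (
    PenaltyConfig,
    edge_fdr_threshold,
    elastic_net_fit,
    fdr_threshold,
    fit_null_coefficients,
    loocv_select,
    objective,
    permute_profiles,
)
from bets.simulate import PlantedNetworkSpec, simulate_var
from bets.pipeline import preprocess
from bets.timeseries import ExpressionTimeSeries


def _design(X, y):
    return LaggedDesign(
        effect_gene="g",
        response=np.asarray(y, dtype=float),
        predictors=np.asarray(X, dtype=float),
        column_index=tuple(("x", i + 1) for i in range(X.shape[1])),
        N=X.shape[0],
        L=1,
    )


def _naive_coordinate_descent(X, y, lam, a, iters=20000):
    """Exhaustive coordinate-descent minimiser of
    ||y - Xb||^2 + lam*(a*||b||_1 + (1-a)*||b||_2^2)."""
    n, k = X.shape
    b = np.zeros(k)
    col_sq = (X ** 2).sum(axis=0)
    for _ in range(iters):
        b_old = b.copy()
        for j in range(k):
            r = y - X @ b + X[:, j] * b[j]
            rho = X[:, j] @ r
            denom = col_sq[j] + lam * (1 - a)
            z = np.sign(rho) * max(abs(rho) - lam * a / 2.0, 0.0)
            b[j] = z / denom
        if np.max(np.abs(b - b_old)) < 1e-12:
            break
    return b


class TestElasticNetFit:
    def test_zero_response_gives_zero_vector(self, rng):
        X = rng.normal(size=(8, 5))
        coef = elastic_net_fit(_design(X, np.zeros(8)), lam=0.1, a=0.5)
        np.testing.assert_allclose(coef, 0.0, atol=1e-12)

    def test_ridge_matches_closed_form(self, rng):
        X = rng.normal(size=(8, 6))
        y = rng.normal(size=8)
        lam = 0.7
        coef = elastic_net_fit(_design(X, y), lam=lam, a=0.0)
        oracle = np.linalg.solve(X.T @ X + lam * np.eye(6), X.T @ y)
        np.testing.assert_allclose(coef, oracle, atol=1e-6)

    def test_lasso_orthonormal_soft_threshold(self, rng):
        # orthonormal columns: minimiser is soft-threshold of OLS at lam/2
        Q, _ = np.linalg.qr(rng.normal(size=(12, 6)))
        y = rng.normal(size=12)
        lam = 0.4
        coef = elastic_net_fit(_design(Q, y), lam=lam, a=1.0)
        ols = Q.T @ y
        oracle = np.sign(ols) * np.maximum(np.abs(ols) - lam / 2.0, 0.0)
        np.testing.assert_allclose(coef, oracle, atol=1e-6)

    @pytest.mark.parametrize("a", [0.1, 0.5, 0.9, 1.0])
    def test_matches_naive_coordinate_descent(self, rng, a):
        X = rng.normal(size=(6, 4))
        y = rng.normal(size=6)
        lam = 0.3
        coef = elastic_net_fit(_design(X, y), lam=lam, a=a)
        oracle = _naive_coordinate_descent(X, y, lam, a)
        np.testing.assert_allclose(coef, oracle, atol=1e-6)

    def test_objective_no_worse_than_zero_vector(self, rng):
        X = rng.normal(size=(10, 7))
        y = rng.normal(size=10)
        d = _design(X, y)
        for a in (0.0, 0.3, 1.0):
            coef = elastic_net_fit(d, lam=0.5, a=a)
            assert objective(d, coef, 0.5, a) <= objective(d, np.zeros(7), 0.5, a) + 1e-12

    def test_non_finite_design_rejected(self, rng):
        X = rng.normal(size=(5, 3))
        X[2, 1] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            elastic_net_fit(_design(X, np.zeros(5)), lam=0.1, a=0.5)


class TestLoocvSelect:
    def _designs(self, seed=11, p=4, T=12, R=2, noise=0.1):
        ts, _, _ = simulate_var(
            PlantedNetworkSpec(p=p, density=0.2, T=T, R=R, noise_sd=noise, seed=seed)
        )
        ts = preprocess(ts)
        return [build_design(ts, g, 2) for g in ts.gene_ids]

    def test_single_grid_point_returned_unchanged(self):
        designs = self._designs()
        config = PenaltyConfig((0.01,), (0.5,))
        lam, a, mse = loocv_select(designs, config)
        assert (lam, a) == (0.01, 0.5)
        assert np.isfinite(mse).all()

    def test_clean_signal_prefers_light_penalty(self):
        # near-noiseless data from a sparse VAR: heavy shrinkage hurts
        designs = self._designs(noise=0.01)
        config = PenaltyConfig()
        lam, _, mse = loocv_select(designs, config)
        assert lam <= np.median(config.lambda_grid)
        # selected point is the grid argmin of the summed CV error
        i = config.lambda_grid.index(lam)
        assert mse[i].min() == pytest.approx(mse.min())

    def test_tie_breaks_toward_sparser_model(self):
        # all-zero response: every grid point has identical (zero-coef) error
        X = np.arange(12.0).reshape(6, 2)
        d = _design(X, np.zeros(6))
        d = LaggedDesign(d.effect_gene, d.response, d.predictors, d.column_index, 6, 1)
        config = PenaltyConfig((0.01, 1.0), (0.1, 0.9))
        lam, a, _ = loocv_select([d], config)
        assert (lam, a) == (1.0, 0.9)


class TestPermuteProfiles:
    def _ts(self, rng, p=3, T=6, R=2):
        return ExpressionTimeSeries(
            tuple(f"g{i}" for i in range(p)),
            np.arange(T, dtype=float),
            tuple(f"r{i}" for i in range(R)),
            rng.normal(size=(p, T, R)),
        )

    def test_preserves_multiset_per_profile(self, rng):
        ts = self._ts(rng)
        out = permute_profiles(ts, seed=5)
        for g in range(3):
            for r in range(2):
                np.testing.assert_allclose(
                    np.sort(out.values[g, :, r]), np.sort(ts.values[g, :, r])
                )

    def test_single_time_point_identity(self, rng):
        ts = self._ts(rng, T=1)
        out = permute_profiles(ts, seed=9)
        np.testing.assert_array_equal(out.values, ts.values)

    def test_seed_contract(self, rng):
        ts = self._ts(rng, p=5, T=8)
        a = permute_profiles(ts, seed=1)
        b = permute_profiles(ts, seed=1)
        c = permute_profiles(ts, seed=2)
        np.testing.assert_array_equal(a.values, b.values)
        assert not np.array_equal(a.values, c.values)

    def test_profiles_permuted_independently(self, rng):
        # with 5 genes x 8 times, all profiles sharing one permutation is
        # astronomically unlikely under independent shuffles
        ts = self._ts(rng, p=5, T=8, R=1)
        out = permute_profiles(ts, seed=3)
        perms = []
        for g in range(5):
            order = np.argsort(ts.values[g, :, 0])
            pos = np.searchsorted(ts.values[g, order, 0], out.values[g, :, 0])
            perms.append(tuple(order[pos]))  # out[g, i] == ts[g, perm[i]]
        assert len(set(perms)) > 1


class TestFitNullCoefficients:
    def test_identity_permutation_reproduces_real_fit(self, rng):
        ts, _, _ = simulate_var(PlantedNetworkSpec(p=4, T=10, R=2, seed=2))
        ts = preprocess(ts)
        null_coef = fit_null_coefficients(ts, ts, "G2", lam=0.1, a=0.5, L=2)
        real_coef = elastic_net_fit(build_design(ts, "G2", 2), lam=0.1, a=0.5)
        np.testing.assert_allclose(null_coef, real_coef, atol=1e-10)

    def test_white_noise_null_and_real_indistinguishable(self, rng):
        # independent white noise: real and null cross-coefficient magnitude
        # distributions should agree (rank-sum test over repeated draws)
        from scipy.stats import mannwhitneyu

        real_mags, null_mags = [], []
        for rep in range(50):
            local = np.random.default_rng(100 + rep)
            p, T, R = 10, 12, 1
            ts = ExpressionTimeSeries(
                tuple(f"g{i}" for i in range(p)),
                np.arange(T, dtype=float),
                ("r1",),
                local.normal(size=(p, T, R)),
            )
            ts = preprocess(ts)
            permuted = permute_profiles(ts, seed=200 + rep)
            real = elastic_net_fit(build_design(ts, "g0", 2), lam=0.01, a=0.5)
            null = fit_null_coefficients(ts, permuted, "g0", lam=0.01, a=0.5, L=2)
            own = {0, p}  # lag-major self columns of gene 0
            cross = [i for i in range(2 * p) if i not in own]
            real_mags.extend(np.abs(real[cross]))
            null_mags.extend(np.abs(null[cross]))
        _, pval = mannwhitneyu(real_mags, null_mags)
        assert pval > 0.01


class TestEdgeFDR:
    def test_coefficient_export_roundtrip(self, tmp_path):
        import pandas as pd

        from bets.elastic_net import export_coefficients

        real = {("g", 1): {"a": 0.9, "b": 0.5, "c": 0.1}}
        null = {("g", 1): {"a": 0.4, "b": 0.05, "c": 0.02}}
        res = edge_fdr_threshold(real, null, target_fdr=0.05)
        path = tmp_path / "coef.tsv"
        export_coefficients(real, res, path)
        df = pd.read_csv(path, sep="\t")
        assert list(df.columns) == [
            "cause", "effect", "lag", "coefficient", "null_threshold", "survives",
        ]
        assert df.set_index("cause")["survives"].to_dict() == {"a": 1, "b": 1, "c": 0}

    def test_worked_example(self):
        real = {("g", 1): {"a": 0.9, "b": 0.5, "c": 0.1}}
        null = {("g", 1): {"a": 0.4, "b": 0.05, "c": 0.02}}
        res = edge_fdr_threshold(real, null, target_fdr=0.05)
        assert res.thresholds[("g", 1)] == pytest.approx(0.4)
        assert res.surviving == {("a", "g", 1), ("b", "g", 1)}

    def test_null_all_zero_everything_survives(self):
        real = {("g", 1): {"a": 0.2, "b": 0.7}}
        null = {("g", 1): {"a": 0.0, "b": 0.0}}
        res = edge_fdr_threshold(real, null)
        assert res.surviving_pairs() == {("a", "g"), ("b", "g")}

    def test_null_equals_real_kills_everything(self):
        vals = {"a": 0.3, "b": 0.6, "c": 0.9}
        res = edge_fdr_threshold({("g", 1): vals}, {("g", 1): dict(vals)}, 0.05)
        assert not res.surviving

    def test_survival_at_any_lag(self):
        real = {("g", 1): {"a": 0.9, "b": 0.0}, ("g", 2): {"a": 0.0, "b": 0.8}}
        null = {("g", 1): {"a": 0.0, "b": 0.0}, ("g", 2): {"a": 0.0, "b": 0.0}}
        res = edge_fdr_threshold(real, null)
        assert res.surviving_pairs() == {("a", "g"), ("b", "g")}

    def test_invalid_target(self):
        with pytest.raises(ValueError):
            edge_fdr_threshold({}, {}, target_fdr=1.5)

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(
        real=st.lists(st.floats(-2, 2, allow_nan=False), min_size=1, max_size=20),
        null=st.lists(st.floats(-2, 2, allow_nan=False), min_size=1, max_size=20),
        target=st.floats(0.01, 0.5),
    )
    def test_inequality_holds_at_returned_threshold(self, real, null, target):
        real, null = np.array(real), np.array(null)
        T = fdr_threshold(real, null, target)
        n_null = int((np.abs(null) > T).sum())
        n_real = int((np.abs(real) > T).sum())
        ratio = 0.0 if n_null + n_real == 0 else n_null / (n_null + n_real)
        assert ratio <= target

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(
        real=st.lists(st.floats(-2, 2, allow_nan=False), min_size=2, max_size=15),
        null=st.lists(st.floats(-2, 2, allow_nan=False), min_size=2, max_size=15),
    )
    def test_raising_target_never_shrinks_survivors(self, real, null):
        real, null = np.array(real), np.array(null)
        lo = fdr_threshold(real, null, 0.05)
        hi = fdr_threshold(real, null, 0.3)
        survivors_lo = set(np.flatnonzero(np.abs(real) > lo))
        survivors_hi = set(np.flatnonzero(np.abs(real) > hi))
        assert survivors_lo <= survivors_hi
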