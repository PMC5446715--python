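import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from smartsva import (
    DesignMatrices,
    ProbeProbabilities,
    compute_weights,
    empirical_bayes_lfdr,
    estimate_num_components_rmt,
    probe_f_pvalues,
    qr_residualize,
    smartsva_fit,
)
from smartsva.core import (
    estimate_pi0,
    get_op_counter,
    orthonormal_basis,
    reset_op_counter,
)

from conftest import small_config
from smartsva.simulate import assemble_dataset


class TestQRResidualize:
    def test_intercept_only_is_row_centering(self, rng):
        Y = rng.normal(size=(20, 8))
        resid, _ = qr_residualize(Y, np.ones((8, 1)))
        np.testing.assert_allclose(resid, Y - Y.mean(axis=1, keepdims=True), atol=1e-12)

    def test_probe_in_column_space_has_zero_residual(self, rng):
        X = np.column_stack([np.ones(10), rng.normal(size=10)])
        Y = np.vstack([X[:, 1], rng.normal(size=10)])
        resid, _ = qr_residualize(Y, X)
        np.testing.assert_allclose(resid[0], 0.0, atol=1e-10)

    def test_matches_per_probe_least_squares(self, rng):
        # oracle: one ordinary least-squares fit per probe
        Y = rng.normal(size=(50, 10))
        X = np.column_stack([np.ones(10), rng.normal(size=(10, 2))])
        resid, _ = qr_residualize(Y, X)
        for j in range(Y.shape[0]):
            beta, *_ = np.linalg.lstsq(X, Y[j], rcond=None)
            np.testing.assert_allclose(resid[j], Y[j] - X @ beta, atol=1e-10)

    def test_rank_deficient_names_columns(self, rng):
        x = rng.normal(size=10)
        X = np.column_stack([np.ones(10), x, 2 * x])
        with pytest.raises(ValueError, match="collinear"):
            qr_residualize(rng.normal(size=(5, 10)), X, column_names=["int", "x", "2x"])


class TestProbeFPValues:
    def _bases(self, rng, n=20, k_small=2, k_extra=3):
        X_small = np.column_stack([np.ones(n), rng.normal(size=(n, k_small - 1))])
        X_big = np.column_stack([X_small, rng.normal(size=(n, k_extra))])
        return orthonormal_basis(X_big), orthonormal_basis(X_small), X_small, X_big

    def test_orthogonal_probe_gives_p_one(self, rng):
        q_big, q_small, _, X_big = self._bases(rng)
        # residual of a random vector on the big design is orthogonal to it
        y = rng.normal(size=20)
        y_orth = y - q_big @ (q_big.T @ y)
        out = probe_f_pvalues(np.vstack([y_orth, y]), q_big, q_small)
        assert out.fstat[0] == pytest.approx(0.0, abs=1e-10)
        assert out.pvalues[0] == pytest.approx(1.0)

    def test_probe_in_extra_span_gives_capped_p(self, rng):
        # near-perfect fit by the extra columns drives p to the floor;
        # an exactly perfect fit is flagged degenerate instead (below)
        q_big, q_small, X_small, X_big = self._bases(rng)
        extra = X_big[:, X_small.shape[1]]
        extra_resid = extra - q_small @ (q_small.T @ extra)
        probe = extra_resid + 1e-5 * rng.normal(size=20)
        out = probe_f_pvalues(np.vstack([probe, rng.normal(size=20)]), q_big, q_small)
        assert not out.degenerate[0]
        assert 0 < out.pvalues[0] <= 1e-12

    def test_matches_naive_nested_anova(self, rng):
        # oracle: per-probe two-model F-test via explicit least squares
        n, p, k_small, k_big = 20, 100, 2, 5
        X_small = np.column_stack([np.ones(n), rng.normal(size=(n, k_small - 1))])
        X_big = np.column_stack([X_small, rng.normal(size=(n, k_big - k_small))])
        Y = rng.normal(size=(p, n))
        out = probe_f_pvalues(Y, orthonormal_basis(X_big), orthonormal_basis(X_small))
        for j in range(p):
            rss = []
            for X in (X_small, X_big):
                beta, *_ = np.linalg.lstsq(X, Y[j], rcond=None)
                rss.append(np.sum((Y[j] - X @ beta) ** 2))
            f = ((rss[0] - rss[1]) / (k_big - k_small)) / (rss[1] / (n - k_big))
            p_naive = stats.f.sf(f, k_big - k_small, n - k_big)
            assert out.pvalues[j] == pytest.approx(p_naive, abs=1e-8)

    def test_degenerate_probe_flagged(self, rng):
        q_big, q_small, _, X_big = self._bases(rng)
        fitted = X_big @ rng.normal(size=X_big.shape[1])  # zero residual variance
        out = probe_f_pvalues(np.vstack([fitted, rng.normal(size=20)]), q_big, q_small)
        assert out.degenerate[0] and not out.degenerate[1]
        assert out.pvalues[0] == 1.0


class TestEmpiricalBayesLfdr:
    def test_uniform_null_is_flat(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(size=10_000)
        lfdr = empirical_bayes_lfdr(p)
        assert lfdr.mean() >= 0.9
        assert estimate_pi0(p) >= 0.9

    def test_signal_mixture_flags_small_pvalues(self):
        rng = np.random.default_rng(8)
        p = np.concatenate([rng.uniform(size=8000), rng.beta(0.05, 1.0, size=2000)])
        p = np.clip(p, np.finfo(float).tiny, 1.0)
        lfdr = empirical_bayes_lfdr(p)
        smallest = np.argsort(p)[: p.size // 100]
        assert lfdr[smallest].mean() < 0.2

    def test_identical_inputs_identical_outputs(self):
        lfdr = empirical_bayes_lfdr(np.full(50, 0.31))
        assert np.all(lfdr == lfdr[0])

    def test_monotone_in_p(self):
        rng = np.random.default_rng(9)
        p = np.clip(np.concatenate([rng.uniform(size=500), rng.beta(0.2, 1, 500)]), 1e-300, 1)
        lfdr = empirical_bayes_lfdr(p)
        order = np.argsort(p)
        assert np.all(np.diff(lfdr[order]) >= -1e-12)

    def test_too_few_pvalues_rejected(self):
        with pytest.raises(ValueError, match="20"):
            empirical_bayes_lfdr(np.linspace(0.1, 0.9, 10))


class TestComputeWeights:
    def test_printed_formula_points(self):
        probs = ProbeProbabilities(p_gamma=np.array([1.0, 0.5, 0.5]), p_b=np.array([0.0, 0.5, 0.0625]))
        np.testing.assert_allclose(compute_weights(probs, 1.0)[:2], [1.0, 0.25])
        assert compute_weights(probs, 0.25)[2] == pytest.approx(0.25)

    def test_endpoints(self):
        for alpha in (0.1, 0.25, 1.0):
            probs = ProbeProbabilities(
                p_gamma=np.array([0.0, 0.7, 0.7]), p_b=np.array([0.5, 1.0, 0.0])
            )
            w = compute_weights(probs, alpha)
            assert w[0] == 0.0  # p_gamma = 0
            assert w[1] == pytest.approx(0.0)  # p_b = 1
            assert w[2] == pytest.approx(0.7)  # p_b = 0 -> w = p_gamma

    @settings(deadline=None, max_examples=100)
    @given(
        pg=st.floats(0, 1), pb=st.floats(0, 1), dpg=st.floats(0, 1), dpb=st.floats(0, 1),
        alpha=st.floats(0.05, 1.0),
    )
    def test_monotonicity(self, pg, pb, dpg, dpb, alpha):
        """Nondecreasing in p_gamma, nonincreasing in p_b, elementwise."""
        base = compute_weights(ProbeProbabilities([pg], [pb]), alpha)[0]
        up_g = compute_weights(ProbeProbabilities([min(1, pg + dpg)], [pb]), alpha)[0]
        up_b = compute_weights(ProbeProbabilities([pg], [min(1, pb + dpb)]), alpha)[0]
        assert up_g >= base - 1e-12
        assert up_b <= base + 1e-12

    def test_alpha_validation(self):
        probs = ProbeProbabilities([0.5], [0.5])
        for bad in (0.0, -0.5, 1.5):
            with pytest.raises(ValueError):
                compute_weights(probs, bad)


def _planted_factor_data(seed=5, p=2000, n=80):
    rng = np.random.default_rng(seed)
    g = rng.normal(size=n)
    loadings = np.zeros(p)
    affected = rng.choice(p, size=int(0.3 * p), replace=False)
    loadings[affected] = rng.normal(scale=1.0, size=affected.size)
    Y = np.outer(loadings, g) + 0.5 * rng.normal(size=(p, n))
    phenotype = (rng.uniform(size=n) < 0.5).astype(float)
    return Y, g, phenotype


class TestSmartsvaFit:
    def _wrap(self, Y):
        from smartsva import MethylationMatrix

        p, n = Y.shape
        return MethylationMatrix(Y, [f"cg{j}" for j in range(p)], [f"s{i}" for i in range(n)])

    def test_recovers_planted_factor(self):
        Y, g, phenotype = _planted_factor_data()
        design = DesignMatrices.from_phenotype(phenotype)
        fit = smartsva_fit(self._wrap(Y), design, K=1)
        corr = np.corrcoef(fit.sv[:, 0], g)[0, 1]
        assert abs(corr) > 0.95

    def test_result_invariants(self):
        Y, _, phenotype = _planted_factor_data(seed=6)
        design = DesignMatrices.from_phenotype(phenotype)
        fit = smartsva_fit(self._wrap(Y), design, K=3)
        gram = fit.sv.T @ fit.sv
        np.testing.assert_allclose(gram, np.eye(3), atol=1e-8)
        assert np.all((fit.weights >= 0) & (fit.weights <= 1))
        if fit.converged:
            assert fit.weight_history_corr[-1] > fit.corr_threshold

    def test_smart_degenerates_to_classic(self):
        """With the power transform off and the convergence test unreachable,
        the smart iteration reproduces the fixed-B classic trajectory
        step for step."""
        ds = assemble_dataset(small_config(seed=21))
        design = DesignMatrices.from_phenotype(ds.truth.phenotype)
        smart = smartsva_fit(
            ds.Y, design, K=3, alpha=1.0, corr_threshold=1.5, max_iter=3,
            keep_trace=True,
        )
        classic = smartsva_fit(ds.Y, design, K=3, mode="classic_fixed_B", B=3, keep_trace=True)
        assert not smart.converged and classic.n_iter == 3
        for (w_s, sv_s), (w_c, sv_c) in zip(smart.trace, classic.trace):
            assert np.array_equal(w_s, w_c)
            assert np.array_equal(sv_s, sv_c)

    def test_k_out_of_range(self):
        Y, _, phenotype = _planted_factor_data(seed=7, p=500, n=20)
        design = DesignMatrices.from_phenotype(phenotype)
        with pytest.raises(ValueError, match="K"):
            smartsva_fit(self._wrap(Y), design, K=20)
        with pytest.raises(ValueError, match="K"):
            smartsva_fit(self._wrap(Y), design, K=0)

    def test_iteration_cost_linear_in_p(self):
        """Operation-count proxy for one iteration doubles when p doubles."""
        counts = []
        for p in (1000, 2000):
            Y, _, phenotype = _planted_factor_data(seed=8, p=p, n=40)
            design = DesignMatrices.from_phenotype(phenotype)
            reset_op_counter()
            smartsva_fit(self._wrap(Y), design, K=2, mode="classic_fixed_B", B=1)
            counts.append(get_op_counter())
        assert counts[1] / counts[0] == pytest.approx(2.0, rel=0.05)


class TestDesignMatrices:
    def test_nesting_enforced(self, rng):
        full = np.column_stack([np.ones(12), rng.normal(size=12)])
        null = rng.normal(size=(12, 1))  # not in full's span
        with pytest.raises(ValueError, match="nested"):
            DesignMatrices(full=full, null=null, primary_cols=[1])

    def test_from_phenotype(self, rng):
        pheno = rng.normal(size=15)
        covars = rng.normal(size=(15, 2))
        d = DesignMatrices.from_phenotype(pheno, covars)
        assert d.full.shape == (15, 4) and d.null.shape == (15, 3)
        assert list(d.primary_cols) == [3]


class TestRMT:
    def test_deterministic(self, rng):
        Y = rng.normal(size=(500, 30))
        assert estimate_num_components_rmt(Y) == estimate_num_components_rmt(Y)

    def test_recovers_planted_rank_small(self):
        rng = np.random.default_rng(10)
        p, n = 3000, 60
        Y = rng.normal(size=(p, n))
        for k in range(3):
            Y += 0.35 * np.outer(rng.normal(size=p), rng.normal(size=n))
        assert estimate_num_components_rmt(Y) == 3

    def test_zero_variance_probes_dropped(self, rng):
        Y = rng.normal(size=(400, 20))
        Y[::7] = 3.14  # constant probes
        K_with = estimate_num_components_rmt(Y)
        K_without = estimate_num_components_rmt(Y[np.arange(400) % 7 != 0])
        assert K_with == K_without

    def test_all_zero_variance_errors(self):
        with pytest.raises(ValueError, match="zero variance"):
            estimate_num_components_rmt(np.ones((50, 12)))

    def test_requires_more_probes_than_samples(self, rng):
        with pytest.raises(ValueError):
            estimate_num_components_rmt(rng.normal(size=(10, 30)))
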