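import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scrnmf.core import (
    FactorModel,
    Hyperparams,
    closs,
    fit,
    hq_weights,
    impute,
    init_factors,
    load_model,
    objective,
    save_model,
    update_factors,
)
from scrnmf.similarity import SimilarityGraphs


def oracle_nmf_step(x, W, H):
    """Independent classical multiplicative (Frobenius) NMF step."""
    W = W * (x @ H.T) / (W @ H @ H.T)
    H = H * (W.T @ x) / (W.T @ (W @ H))
    return W, H


def oracle_objective_scalar(x, W, H, graphs, hyper):
    """Scalar-loop re-implementation of the objective, term by term."""
    G, C = x.shape
    k = W.shape[1]
    total = 0.0
    for g in range(G):
        for c in range(C):
            wh = sum(W[g, i] * H[i, c] for i in range(k))
            r = x[g, c] - wh
            if x[g, c] != 0:
                total += 0.5 * r * r
            else:
                total += 0.5 * (1 - math.exp(-r * r / (2 * hyper.sigma**2)))
                total += 0.5 * hyper.lam * wh * wh
    if graphs is not None:
        WWt = W @ W.T
        HtH = H.T @ H
        total += 0.5 * hyper.alpha * float(np.sum((graphs.K_G - WWt) ** 2))
        total += 0.5 * hyper.beta * float(np.sum((graphs.K_C - HtH) ** 2))
    return total


class TestCloss:
    def test_zero_residual(self):
        assert closs(0.0, 1.0) == 0.0

    @pytest.mark.parametrize("sigma", [0.1, 1.0, 10.0])
    def test_residual_equal_sigma(self, sigma):
        assert closs(sigma, sigma) == pytest.approx(1 - math.exp(-0.5), abs=1e-12)

    def test_bounded_below_one(self):
        assert closs(5.0, 1.0) < 1.0
        # saturates to the supremum at float precision, never exceeds it
        assert closs(1e6, 1.0) <= 1.0

    def test_even(self):
        assert closs(1.7, 0.5) == closs(-1.7, 0.5)

    def test_invalid_sigma(self):
        with pytest.raises(ValueError):
            closs(1.0, 0.0)

    def test_l2_bound_and_small_residual_limit(self):
        sigma = 0.8
        for r in [1e-4, 1e-2, 0.5, 2.0, 10.0]:
            assert closs(r, sigma) <= r**2 / (2 * sigma**2) + 1e-15
        r = 1e-6
        ratio = closs(r, sigma) / (r**2 / (2 * sigma**2))
        assert ratio == pytest.approx(1.0, abs=1e-9)


class TestObjective:
    def test_all_zero_trivial(self):
        x = np.zeros((2, 3))
        W = np.zeros((2, 1))
        H = np.zeros((1, 3))
        hyper = Hyperparams(k=1, sigma=1.0, alpha=0.0, beta=0.0, lam=0.0)
        assert objective(x, W, H, None, hyper) == 0.0

    def test_perfect_fit_no_zeros(self):
        rng = np.random.default_rng(0)
        W = rng.uniform(0.5, 1.0, (4, 2))
        H = rng.uniform(0.5, 1.0, (2, 5))
        x = W @ H
        hyper = Hyperparams(k=2, sigma=1.0, alpha=0.0, beta=0.0, lam=0.0)
        assert objective(x, W, H, None, hyper) == pytest.approx(0.0, abs=1e-20)

    def test_hand_computed_2x2(self):
        x = np.array([[1.0, 0.0], [0.0, 2.0]])
        W = np.array([[1.0], [1.0]])
        H = np.array([[1.0, 1.0]])
        hyper = Hyperparams(k=1, sigma=1.0, alpha=0.0, beta=0.0, lam=1.0)
        expected = 0.5 + (1 - math.exp(-0.5)) + 1.0
        assert objective(x, W, H, None, hyper) == pytest.approx(expected, abs=1e-12)

    def test_matches_scalar_loop_oracle(self, small_graphs):
        rng = np.random.default_rng(1)
        G, C = small_graphs.K_G.shape[0], small_graphs.K_C.shape[0]
        x = rng.uniform(0, 3, (G, C)) * (rng.random((G, C)) < 0.5)
        W = rng.uniform(0.1, 1.0, (G, 4))
        H = rng.uniform(0.1, 1.0, (4, C))
        hyper = Hyperparams(k=4, sigma=0.7, alpha=0.3, beta=0.2, lam=0.5)
        fast = objective(x, W, H, small_graphs, hyper)
        slow = oracle_objective_scalar(x, W, H, small_graphs, hyper)
        assert fast == pytest.approx(slow, rel=1e-12)

    def test_shape_mismatch(self):
        hyper = Hyperparams(k=1, alpha=0.0, beta=0.0)
        with pytest.raises(ValueError, match="shape"):
            objective(np.ones((2, 2)), np.ones((3, 1)), np.ones((1, 2)), None, hyper)


class TestHQWeights:
    def test_zero_entry_zero_residual(self):
        x = np.array([[0.0, 1.0]])
        W = np.zeros((1, 1))
        H = np.zeros((1, 2))
        hq = hq_weights(x, W, H, sigma=1.0)
        assert hq.M[0, 0] == 1.0

    def test_zero_entry_residual_sigma(self):
        x = np.array([[0.0]])
        W = np.array([[2.0]])
        H = np.array([[1.0]])  # WH = 2 = sigma
        hq = hq_weights(x, W, H, sigma=2.0)
        assert hq.M[0, 0] == pytest.approx(math.exp(-0.5), abs=1e-12)

    def test_nonzero_entry_weight_one(self):
        x = np.array([[5.0]])
        hq = hq_weights(x, np.array([[100.0]]), np.array([[1.0]]), sigma=1.0)
        assert hq.M[0, 0] == 1.0

    def test_p_is_zero_indicator(self):
        x = np.array([[0.0, 3.0], [2.0, 0.0]])
        hq = hq_weights(x, np.ones((2, 1)), np.ones((1, 2)), sigma=1.0)
        np.testing.assert_array_equal(hq.P, np.array([[1.0, 0.0], [0.0, 1.0]]))


class TestUpdateFactors:
    def test_fixed_point_on_perfect_fit(self):
        rng = np.random.default_rng(2)
        W = rng.uniform(0.5, 1.0, (5, 2))
        H = rng.uniform(0.5, 1.0, (2, 6))
        x = W @ H
        hyper = Hyperparams(k=2, sigma=1.0, alpha=0.0, beta=0.0, lam=0.0)
        hq = hq_weights(x, W, H, 1.0)
        W2, H2 = update_factors(x, W, H, hq, None, hyper)
        np.testing.assert_allclose(W2, W, rtol=1e-12)
        np.testing.assert_allclose(H2, H, rtol=1e-12)

    def test_matches_independent_nmf_oracle(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(0.5, 2.0, (6, 5))  # strictly positive: no zeros
        hyper = Hyperparams(k=2, sigma=1.0, alpha=0.0, beta=0.0, lam=0.0)
        W, H = init_factors(x, 2, seed=4)
        Wo, Ho = W.copy(), H.copy()
        for _ in range(20):
            hq = hq_weights(x, W, H, 1.0)
            W, H = update_factors(x, W, H, hq, None, hyper)
            Wo, Ho = oracle_nmf_step(x, Wo, Ho)
        np.testing.assert_allclose(W, Wo, rtol=1e-10)
        np.testing.assert_allclose(H, Ho, rtol=1e-10)

    def test_outputs_non_negative(self, small_processed, small_graphs):
        rng = np.random.default_rng(5)
        x = small_processed.values
        hyper = Hyperparams(k=3, sigma=0.5, alpha=1.0, beta=1.0, lam=1.0)
        W = rng.uniform(0.01, 1.0, (x.shape[0], 3))
        H = rng.uniform(0.01, 1.0, (3, x.shape[1]))
        hq = hq_weights(x, W, H, 0.5)
        W2, H2 = update_factors(x, W, H, hq, small_graphs, hyper)
        assert W2.min() >= 0 and H2.min() >= 0


class TestFit:
    def test_exact_rank2_recovery(self):
        rng = np.random.default_rng(42)
        Ws = rng.uniform(0.5, 1.5, (30, 2))
        Hs = rng.uniform(0.5, 1.5, (2, 20))
        x = Ws @ Hs
        hyper = Hyperparams(k=2, sigma=1.0, alpha=0.0, beta=0.0, lam=0.0)
        model = fit(x, None, hyper, init_seed=0, max_iter=2000, tol=1e-12)
        rel = np.linalg.norm(x - model.W @ model.H) / np.linalg.norm(x)
        assert rel < 1e-3

    def test_trace_non_increasing(self, small_processed, small_graphs, default_hyper):
        model = fit(small_processed, small_graphs, default_hyper, init_seed=0, max_iter=60)
        trace = np.asarray(model.objective_trace)
        assert np.all(np.diff(trace) <= 1e-8)

    def test_determinism(self, small_processed, small_graphs, default_hyper):
        m1 = fit(small_processed, small_graphs, default_hyper, init_seed=9, max_iter=20)
        m2 = fit(small_processed, small_graphs, default_hyper, init_seed=9, max_iter=20)
        np.testing.assert_array_equal(m1.W, m2.W)
        np.testing.assert_array_equal(m1.H, m2.H)
        assert m1.objective_trace == m2.objective_trace

    def test_different_seed_different_solution(self, small_processed, small_graphs, default_hyper):
        m1 = fit(small_processed, small_graphs, default_hyper, init_seed=0, max_iter=5)
        m2 = fit(small_processed, small_graphs, default_hyper, init_seed=1, max_iter=5)
        assert not np.array_equal(m1.W, m2.W)

    def test_factors_stay_positive(self, small_processed, small_graphs, default_hyper):
        model = fit(small_processed, small_graphs, default_hyper, init_seed=0, max_iter=30)
        assert model.W.min() > 0 and model.H.min() > 0

    def test_permuting_genes_leaves_objective_unchanged(self, small_processed, small_graphs):
        hyper = Hyperparams(k=4, sigma=1.0, alpha=0.2, beta=0.1, lam=0.3)
        x = small_processed.values
        rng = np.random.default_rng(6)
        W = rng.uniform(0.1, 1.0, (x.shape[0], 4))
        H = rng.uniform(0.1, 1.0, (4, x.shape[1]))
        perm = rng.permutation(x.shape[0])
        permuted_graphs = SimilarityGraphs(
            K_G=small_graphs.K_G[np.ix_(perm, perm)], K_C=small_graphs.K_C
        )
        j1 = objective(x, W, H, small_graphs, hyper)
        j2 = objective(x[perm], W[perm], H, permuted_graphs, hyper)
        assert j1 == pytest.approx(j2, rel=1e-12)

    def test_invalid_max_iter(self, small_processed, small_graphs, default_hyper):
        with pytest.raises(ValueError):
            fit(small_processed, small_graphs, default_hyper, max_iter=0)

    def test_l2_ablation_runs_and_is_monotone(self, small_processed, small_graphs, default_hyper):
        model = fit(small_processed, small_graphs, default_hyper, init_seed=0,
                    max_iter=40, zero_loss="l2")
        trace = np.asarray(model.objective_trace)
        assert np.all(np.diff(trace) <= 1e-8)


class TestImpute:
    def test_zeros_only_preserves_observed(self, small_processed, small_graphs, default_hyper):
        model = fit(small_processed, small_graphs, default_hyper, init_seed=0, max_iter=15)
        out = impute(small_processed, model, mode="zeros_only")
        x = small_processed.values
        nz = x != 0
        np.testing.assert_array_equal(out[nz], x[nz])

    def test_full_is_plain_product(self):
        W = np.array([[1.0, 0.0], [0.0, 1.0]])
        H = np.array([[2.0, 0.0], [0.0, 3.0]])
        model = FactorModel(W=W, H=H, hyper=Hyperparams(k=2))
        out = impute(np.zeros((2, 2)), model, mode="full")
        np.testing.assert_array_equal(out, np.array([[2.0, 0.0], [0.0, 3.0]]))

    def test_non_negative(self, small_processed, small_graphs, default_hyper):
        model = fit(small_processed, small_graphs, default_hyper, init_seed=0, max_iter=15)
        assert impute(small_processed, model, mode="full").min() >= 0

    def test_shape_mismatch(self):
        model = FactorModel(W=np.ones((3, 1)), H=np.ones((1, 2)), hyper=Hyperparams(k=1))
        with pytest.raises(ValueError, match="shape"):
            impute(np.ones((2, 2)), model)

    def test_unknown_mode(self):
        model = FactorModel(W=np.ones((2, 1)), H=np.ones((1, 2)), hyper=Hyperparams(k=1))
        with pytest.raises(ValueError, match="mode"):
            impute(np.ones((2, 2)), model, mode="bogus")


class TestCheckpoint:
    def test_round_trip(self, tmp_path, small_processed, small_graphs, default_hyper):
        model = fit(small_processed, small_graphs, default_hyper, init_seed=0, max_iter=10)
        save_model(model, tmp_path / "ckpt")
        back = load_model(tmp_path / "ckpt")
        np.testing.assert_allclose(back.W, model.W, rtol=1e-12)
        np.testing.assert_allclose(back.H, model.H, rtol=1e-12)
        assert back.hyper == model.hyper
        assert back.n_iter == model.n_iter


class TestHyperparams:
    @pytest.mark.parametrize(
        "kwargs",
        [dict(k=0), dict(k=2, sigma=0.0), dict(k=2, sigma=-1.0), dict(k=2, alpha=-0.1)],
    )
    def test_invalid(self, kwargs):
        with pytest.raises(ValueError):
            Hyperparams(**kwargs)


@settings(max_examples=40, deadline=None)
@given(
    st.floats(-50, 50, allow_nan=False),
    st.floats(1e-3, 1e3, allow_nan=False),
)
def test_closs_properties(r, sigma):
    value = closs(r, sigma)
    assert 0.0 <= value <= 1.0  # float saturation can reach the supremum
    assert value == closs(-r, sigma)
    assert value <= r**2 / (2 * sigma**2) + 1e-12
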