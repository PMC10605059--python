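"""Opinions, Dempster-Shafer fusion, the Dirichlet density and loss terms."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, special, stats

from evidentomics import (Opinion, compute_opinion, dirichlet_kl_uniform,
                          dirichlet_pdf, ds_fuse, ds_fuse_all, loss_integrate,
                          loss_overall, loss_single, vacuous_opinion)
from evidentomics._autodiff import Tensor


def _random_opinion(rng, K=3, scale=5.0):
    return compute_opinion(rng.uniform(0, scale, size=K))


class TestOpinion:
    def test_zero_evidence_is_vacuous(self):
        op = compute_opinion(np.zeros(2))
        assert np.allclose(op.beliefs, 0.0)
        assert op.uncertainty == 1.0

    def test_worked_example(self):
        op = compute_opinion(np.array([8.0, 2.0]))
        assert np.isclose(op.dirichlet_strength, 12.0)
        assert np.allclose(op.beliefs, [8 / 12, 2 / 12], atol=1e-12)
        assert np.isclose(op.uncertainty, 2 / 12, atol=1e-12)

    @settings(max_examples=200, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.integers(2, 8))
    def test_identity_u_plus_sum_b(self, seed, K):
        rng = np.random.default_rng(seed)
        op = compute_opinion(rng.uniform(0, 50, size=K))
        assert abs(op.uncertainty + op.beliefs.sum() - 1.0) <= 1e-12

    def test_negative_evidence_rejected(self):
        with pytest.raises(ValueError):
            compute_opinion(np.array([-0.1, 1.0]))


class TestFusion:
    def test_vacuous_is_two_sided_identity(self):
        rng = np.random.default_rng(0)
        op = _random_opinion(rng)
        vac = vacuous_opinion(3)
        for fused in (ds_fuse(op, vac), ds_fuse(vac, op)):
            assert np.allclose(fused.beliefs, op.beliefs, atol=1e-12)
            assert np.isclose(fused.uncertainty, op.uncertainty, atol=1e-12)

    def test_hand_worked_fusion(self):
        op1 = Opinion([0.6, 0.2], 0.2, np.array([0.6, 0.2]) * 2 / 0.2)
        op2 = Opinion([0.3, 0.3], 0.4, np.array([0.3, 0.3]) * 2 / 0.4)
        fused = ds_fuse(op1, op2)
        # C = 0.6*0.3 + 0.2*0.3 = 0.24
        assert np.allclose(fused.beliefs, [0.48 / 0.76, 0.20 / 0.76], atol=1e-9)
        assert np.isclose(fused.uncertainty, 0.08 / 0.76, atol=1e-9)
        assert np.isclose(fused.beliefs.sum() + fused.uncertainty, 1.0, atol=1e-12)

    def test_total_conflict_raises(self):
        op1 = Opinion([1.0, 0.0], 1e-15, np.array([1.0, 0.0]) * 2 / 1e-15)
        op2 = Opinion([0.0, 1.0], 1e-15, np.array([0.0, 1.0]) * 2 / 1e-15)
        with pytest.raises(ValueError, match="conflict"):
            ds_fuse(op1, op2)

    def test_commutative_exact(self):
        rng = np.random.default_rng(1)
        a, b = _random_opinion(rng), _random_opinion(rng)
        ab, ba = ds_fuse(a, b), ds_fuse(b, a)
        assert np.array_equal(ab.beliefs, ba.beliefs)
        assert ab.uncertainty == ba.uncertainty

    def test_associative_over_all_orderings(self):
        rng = np.random.default_rng(2)
        ops = [_random_opinion(rng) for _ in range(3)]
        results = [ds_fuse_all([ops[i] for i in perm])
                   for perm in itertools.permutations(range(3))]
        ref = results[0]
        for r in results[1:]:
            assert np.allclose(r.beliefs, ref.beliefs, atol=1e-9)
            assert np.isclose(r.uncertainty, ref.uncertainty, atol=1e-9)

    @settings(max_examples=100, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_identity_preserved_and_uncertainty_floor(self, seed):
        rng = np.random.default_rng(seed)
        a, b = _random_opinion(rng), _random_opinion(rng)
        fused = ds_fuse(a, b)
        assert abs(fused.uncertainty + fused.beliefs.sum() - 1.0) <= 1e-12
        # u = u1 u2 / (1 - C) >= u1 u2
        assert fused.uncertainty >= a.uncertainty * b.uncertainty - 1e-15

    def test_agreeing_confident_opinion_does_not_raise_uncertainty(self):
        rng = np.random.default_rng(3)
        a = _random_opinion(rng)
        k = int(np.argmax(a.beliefs))
        e = np.zeros(3)
        e[k] = 100.0
        confident = compute_opinion(e)
        assert ds_fuse(a, confident).uncertainty <= a.uncertainty + 1e-12

    def test_fuse_all_base_cases(self):
        rng = np.random.default_rng(4)
        op = _random_opinion(rng)
        alone = ds_fuse_all([op])
        assert np.array_equal(alone.beliefs, op.beliefs)
        vac = ds_fuse_all([vacuous_opinion(3)] * 4)
        assert vac.uncertainty == 1.0


class TestDirichletPdf:
    def test_uniform_density_is_one(self):
        assert dirichlet_pdf([0.3, 0.7], [1.0, 1.0]) == 1.0

    def test_symmetric_2_2_at_center(self):
        # 1/B(2,2) * 0.25 = 6 * 0.25
        assert np.isclose(dirichlet_pdf([0.5, 0.5], [2.0, 2.0]), 1.5, atol=1e-12)

    def test_matches_beta_density_on_grid(self):
        alpha = np.array([3.2, 1.7])
        grid = np.linspace(0.002, 0.998, 200)
        ours = np.array([dirichlet_pdf([m, 1 - m], alpha) for m in grid])
        beta = stats.beta.pdf(grid, alpha[0], alpha[1])
        assert np.allclose(ours, beta, atol=1e-9)

    @pytest.mark.parametrize("alpha", [[1.5, 2.5], [2.0, 3.0, 1.2]])
    def test_integrates_to_one(self, alpha):
        alpha = np.array(alpha)
        if len(alpha) == 2:
            val, _ = integrate.quad(
                lambda m: dirichlet_pdf([m, 1 - m], alpha), 0, 1)
        else:
            val, _ = integrate.dblquad(
                lambda b, a: dirichlet_pdf([a, b, 1 - a - b], alpha),
                0, 1, 0, lambda a: 1 - a)
        assert np.isclose(val, 1.0, atol=1e-3)

    def test_off_simplex_zero_and_alpha_below_one_errors(self):
        assert dirichlet_pdf([0.4, 0.4], [2.0, 2.0]) == 0.0
        with pytest.raises(ValueError):
            dirichlet_pdf([0.5, 0.5], [0.5, 2.0])


class TestLosses:
    def test_single_perfect_beliefs_vanish(self):
        y = np.array([[1.0, 0.0]])
        b = np.array([[1.0 - 1e-15, 1e-15]])
        assert np.isclose(loss_single([b, b, b], y)[0], 0.0, atol=1e-9)

    def test_single_half_belief_gives_log2(self):
        y = np.array([[1.0, 0.0]])
        perfect = np.array([[1.0, 0.0]])
        half = np.array([[0.5, 0.3]])
        val = loss_single([perfect, half, perfect], y)[0]
        assert np.isclose(val, math.log(2), atol=1e-9)

    def test_single_matches_scalar_loop(self):
        rng = np.random.default_rng(5)
        B, K, M = 4, 3, 3
        beliefs = [rng.uniform(0.05, 1.0, size=(B, K)) for _ in range(M)]
        y_idx = rng.integers(0, K, size=B)
        Y = np.eye(K)[y_idx]
        ours = loss_single(beliefs, Y)
        oracle = np.zeros(B)
        for i in range(B):
            for m in range(M):
                oracle[i] -= math.log(beliefs[m][i, y_idx[i]])
        assert np.allclose(ours, oracle, atol=1e-12)

    def test_integrate_at_uniform_alpha(self):
        # digamma term psi(2) - psi(1) = 1; alpha_tilde = 1 so KL = 0
        alpha = np.array([[1.0, 1.0]])
        y = np.array([[1.0, 0.0]])
        assert np.isclose(loss_integrate(alpha, y, kl_weight=1.0)[0], 1.0,
                          atol=1e-12)

    def test_kl_closed_form_alpha_2_1(self):
        # KL[Dir(2,1) || Dir(1,1)] = ln 2 - 1/2
        val = dirichlet_kl_uniform(np.array([[2.0, 1.0]]))[0]
        assert np.isclose(val, math.log(2) - 0.5, atol=1e-12)

    def test_kl_matches_numerical_integration(self):
        alpha = np.array([2.6, 1.4])

        def integrand(m):
            p = stats.beta.pdf(m, alpha[0], alpha[1])
            if p <= 0:
                return 0.0
            return p * np.log(p)  # uniform reference has density 1

        num, _ = integrate.quad(integrand, 1e-9, 1 - 1e-9)
        closed = dirichlet_kl_uniform(alpha[None])[0]
        assert np.isclose(closed, num, atol=1e-3)

    def test_digamma_term_minimized_by_true_class_evidence(self):
        y = np.array([[1.0, 0.0, 0.0]])
        total = 9.0
        vals = []
        for frac in np.linspace(0.34, 0.9, 8):
            a_true = total * frac
            rest = (total - a_true) / 2
            alpha = np.array([[a_true, rest, rest]])
            vals.append(loss_integrate(alpha, y, kl_weight=0.0)[0])
        assert np.all(np.diff(vals) < 0)

    def test_overall_zero_components(self):
        assert loss_overall(0.0, 0.0, 0.0, 0.0, 0.0) == 0.0

    def test_overall_l1_scaling(self):
        assert np.isclose(loss_overall(0.0, 0.0, 0.0, 0.0, 1e4,
                                       l1_weight=1e-4), 1.0)

    def test_overall_rejects_nonfinite_and_names_component(self):
        with pytest.raises(FloatingPointError, match="integrate"):
            loss_overall(0.0, 0.0, float("nan"), 0.0, 0.0)

    def test_gradient_reaches_every_component(self):
        comps = {name: Tensor(0.5, requires_grad=True)
                 for name in ("tcl", "single", "integrate", "u", "l1")}
        total = loss_overall(comps["tcl"], comps["single"],
                             comps["integrate"], comps["u"], comps["l1"])
        total.backward()
        for name, t in comps.items():
            assert t.grad is not None and abs(t.grad) > 0, name
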