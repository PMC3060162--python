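"""Community construction: efficiency solves and the dominance hierarchy."""

import numpy as np
import pytest

from patchcomm import (
    Community,
    FixpointResult,
    dominance_fixpoint,
    solve_abundance_fixpoint,
    solve_efficiencies,
    stability_check,
)
from patchcomm.fixpoint import FixpointError


class TestSolveEfficiencies:
    def test_single_species_inversion(self):
        n0, alpha = 100.0, 0.001
        fp = solve_efficiencies(n0, [0.2], alpha)
        expected = n0 * (1 - alpha) / (1 - np.exp(-alpha * n0))
        assert fp.Y[0] == pytest.approx(expected, rel=1e-10)
        assert fp.residual < 1e-9 * n0

    def test_fifteen_species_tradeoff(self, fp15):
        # solved efficiencies fall monotonically with growth rate —
        # the trade-off that permits equal-abundance coexistence
        assert fp15.converged
        assert fp15.residual < 1e-9 * fp15.n_star[0] * 10
        assert np.all(np.diff(fp15.Y) < 0)
        assert np.all(fp15.Y > 0)

    def test_label_permutation_permutes_solution(self, fp3):
        perm = np.array([2, 0, 1])
        fp_perm = solve_efficiencies(
            fp3.n_star[perm], fp3.community.mu[perm], fp3.alpha0
        )
        np.testing.assert_allclose(fp_perm.Y, fp3.Y[perm], rtol=1e-8)

    def test_invalid_targets_rejected(self):
        with pytest.raises(ValueError):
            solve_efficiencies(-1.0, [0.1, 0.2], 0.001)
        with pytest.raises(ValueError):
            solve_efficiencies(10.0, [0.2, 0.2], 0.001)  # duplicate rates


class TestDominance:
    def test_single_species_root_threshold(self):
        # n = sY(1 - e^{-alpha n}) has a positive root iff alpha*s*Y > 1
        alpha = 1e-3
        c_low = Community(mu=[0.2], Y=[900.0])
        n, excluded = dominance_fixpoint(c_low, alpha, s=1.0)  # alpha*Y = 0.9
        assert excluded[0] and n[0] == 0.0
        c_high = Community(mu=[0.2], Y=[2000.0])
        n, excluded = dominance_fixpoint(c_high, alpha, s=1.0)
        assert not excluded[0]
        # bisection oracle for the scalar root
        from scipy.optimize import brentq

        root = brentq(lambda x: 2000.0 * (1 - np.exp(-alpha * x)) - x, 1e-6, 2000.0)
        assert n[0] == pytest.approx(root, rel=1e-10)

    def test_top_species_ignores_weaker_ones(self):
        alpha = 1e-3
        a = Community(mu=np.array([0.1, 0.3]), Y=np.array([3000.0, 2000.0]))
        b = Community(mu=np.array([0.2, 0.3]), Y=np.array([99.0, 2000.0]))
        na, _ = dominance_fixpoint(a, alpha)
        nb, _ = dominance_fixpoint(b, alpha)
        assert na[1] == pytest.approx(nb[1], rel=1e-12)

    def test_two_species_dominance_matches_full_model_at_large_s(self):
        # focal phenotype (mu, Y) = (0.5, 125) plus a faster partner, at a
        # large resource rescaling and a dilution small enough that patches
        # stay sparsely seeded
        s = 1e6
        c = Community(mu=np.array([0.5, 1.0]), Y=np.array([125.0, 12.5]))
        alpha = 2.5 / (s * 12.5)
        nd, excluded = dominance_fixpoint(c, alpha, s=s)
        assert not excluded.any()
        full = solve_abundance_fixpoint(c.rescaled(s), alpha, nd)
        rel = np.abs(nd - full.n_star) / full.n_star
        assert np.max(rel) < 0.05

    def test_dominance_error_shrinks_with_s(self):
        # three-species hierarchy with alpha*s held fixed (the regime in
        # which every level keeps a positive root while the non-dominant
        # growth corrections decay like a power of s)
        mu = np.array([0.1, 0.173, 0.3])
        Y_base = np.array([30.0, 6.25, 1.25])
        errs = []
        for s in (1e2, 1e4, 1e6):
            c = Community(mu=mu, Y=Y_base)
            alpha = 2.0 / (s * Y_base[-1])
            nd, excluded = dominance_fixpoint(c, alpha, s=s)
            assert not excluded.any()
            from patchcomm.dynamics import StepKernel, TruncationPolicy

            kern = StepKernel(
                c.rescaled(s),
                TruncationPolicy(tail_epsilon=1e-10, config_ceiling=2_000_000),
            )
            full = solve_abundance_fixpoint(c.rescaled(s), alpha, nd, kernel=kern)
            errs.append(float(np.max(np.abs(nd - full.n_star) / full.n_star)))
        assert errs[0] > errs[1] > errs[2]

    def test_unsorted_community_rejected(self):
        c = Community(mu=np.array([0.3, 0.1]), Y=np.array([1.0, 1.0]))
        with pytest.raises(ValueError):
            dominance_fixpoint(c, 0.001)


class TestStability:
    def test_canonical_community_is_stable(self, fp15):
        rho, stable = stability_check(fp15)
        assert stable and 0 < rho < 1

    def test_super_species_community_has_no_equal_coexistence(self):
        # constant efficiency with increasing growth rate: the fastest
        # species dominates outright and equal abundances are infeasible
        mu = np.array([0.1, 0.2, 0.3])
        c = Community(mu=mu, Y=np.full(3, 1500.0))
        try:
            fp = solve_abundance_fixpoint(c, 0.001, np.full(3, 30.0), max_iter=60)
        except FixpointError:
            return  # no convergence is an acceptable outcome
        # if the solve converges it must be to a collapsed state, not to
        # three-species coexistence
        assert np.min(fp.n_star) < 1e-6

    def test_raising_one_efficiency_breaks_the_balance(self, fp3):
        # bump one species' Y above its solved value and iterate: the
        # favoured species pulls ahead while its competitors fall below
        # the old equal-abundance state — the balance is gone
        Y = fp3.Y.copy()
        Y[1] *= 1.2
        from patchcomm.dynamics import StepKernel, TruncationPolicy

        kern = StepKernel(
            Community(mu=fp3.community.mu, Y=Y), TruncationPolicy(tail_epsilon=1e-9)
        )
        n = fp3.n_star.copy()
        for _ in range(150):
            n, _ = kern.step(n, fp3.alpha0)
        delta = n - fp3.n_star
        assert delta[1] > 0
        assert np.all(np.delete(delta, 1) < 0)

    def test_verdict_invariant_under_relabeling(self, fp3):
        perm = np.array([1, 2, 0])
        fp_perm = solve_efficiencies(
            fp3.n_star[perm], fp3.community.mu[perm], fp3.alpha0
        )
        rho_a, stable_a = stability_check(fp3)
        rho_b, stable_b = stability_check(fp_perm)
        assert stable_a == stable_b
        assert rho_a == pytest.approx(rho_b, rel=1e-6)
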