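"""Expectation update: Poisson seeding weights, certified truncation."""

import math

import numpy as np
import pytest
from scipy import stats
from scipy.special import gammaln

from patchcomm import Community, derive_truncation, seeding_probability, step_map
from patchcomm.dynamics import (
    StaleTruncationError,
    StepKernel,
    TruncationPolicy,
    compositions,
    n_configurations,
    required_total,
)


@pytest.fixture(scope="module")
def small_kernel():
    c = Community(mu=np.array([0.1, 0.2, 0.3]), Y=np.array([1500.0, 1000.0, 700.0]))
    return StepKernel(c, TruncationPolicy(tail_epsilon=1e-9))


class TestSeedingProbability:
    def test_empty_seeding_probability(self):
        n = np.array([5.0, 5.0])
        assert seeding_probability([0, 0], n, 0.01) == pytest.approx(
            np.exp(-0.1), rel=1e-12
        )

    def test_canonical_community_empty_patch(self):
        # 15 species at 100/15 per patch, alpha 0.001: lambda_total = 0.1
        n = np.full(15, 100.0 / 15)
        p0 = seeding_probability(np.zeros(15, dtype=int), n, 0.001)
        assert p0 == pytest.approx(np.exp(-0.1), rel=1e-12)

    def test_normalization_over_enumeration_plus_tail(self, small_kernel):
        n = np.array([40.0, 30.0, 30.0])
        alpha = 0.002
        lam_tot = alpha * n.sum()
        M = required_total(lam_tot, 1e-9)
        mass = 0.0
        for total in range(M + 1):
            for m in compositions(3, total):
                mass += seeding_probability(m, n, alpha)
        assert mass + stats.poisson.sf(M, lam_tot) == pytest.approx(1.0, abs=1e-9)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            seeding_probability([0], np.array([-1.0]), 0.01)
        with pytest.raises(ValueError):
            seeding_probability([0], np.array([1.0]), 0.0)


class TestTruncation:
    @pytest.mark.parametrize("lam,eps", [(0.1, 1e-7), (0.5, 1e-7), (3.0, 1e-5)])
    def test_required_total_matches_direct_tail_sum(self, lam, eps):
        M = required_total(lam, eps)

        def tail(M_):
            # direct summation oracle, enough terms to exhaust the tail
            js = np.arange(M_ + 1, M_ + 200)
            return np.sum(np.exp(-lam + js * np.log(lam) - gammaln(js + 1)))

        assert tail(M) < eps
        if M > 0:
            assert tail(M - 1) >= eps

    def test_zero_rate_needs_no_seeds(self):
        assert required_total(0.0, 1e-7) == 0

    def test_configuration_count_is_stars_and_bars(self):
        N, M = 4, 5
        count = sum(compositions(N, t).shape[0] for t in range(M + 1))
        assert count == n_configurations(N, M) == math.comb(N + M, M)

    def test_compositions_are_lexicographic_and_complete(self):
        rows = compositions(3, 4)
        assert np.all(rows.sum(axis=1) == 4)
        as_tuples = [tuple(r) for r in rows]
        assert as_tuples == sorted(as_tuples)
        assert len(set(as_tuples)) == len(as_tuples) == math.comb(3 + 4 - 1, 4)

    def test_derive_truncation_certificate(self):
        n = np.full(15, 100.0 / 15)
        pol = derive_truncation(n, 0.001, 1e-7)
        assert stats.poisson.sf(pol.max_total, 0.1) < 1e-7

    def test_static_policy_goes_stale(self):
        c = Community(mu=np.array([0.2]), Y=np.array([1000.0]))
        pol = derive_truncation(np.array([10.0]), 1e-3, 1e-7)
        kern = StepKernel(c, pol)
        kern.step(np.array([10.0]), 1e-3)  # fine at the anchoring state
        with pytest.raises(StaleTruncationError):
            kern.step(np.array([5000.0]), 1e-3)


class TestStepMap:
    def test_extinct_community_stays_extinct(self, small_kernel):
        out, info = small_kernel.step(np.zeros(3), 0.001)
        assert np.all(out == 0.0)
        assert info.mass == 1.0

    @pytest.mark.parametrize("n", [0.1, 1.0, 10.0, 100.0])
    @pytest.mark.parametrize("alpha", [1e-4, 1e-3, 1e-2])
    def test_single_species_closed_form(self, n, alpha):
        # sum over m of P(m) (m + Y) collapses analytically
        Y = 1000.0
        kern = StepKernel(
            Community(mu=np.array([0.2]), Y=np.array([Y])),
            TruncationPolicy(tail_epsilon=1e-13),
        )
        out, info = kern.step(np.array([n]), alpha)
        expected = alpha * n + Y * (1.0 - np.exp(-alpha * n))
        assert out[0] == pytest.approx(expected, rel=1e-9)
        assert info.mass >= 1.0 - 1e-13

    def test_refinement_converges_with_tail(self, fp3):
        n = fp3.n_star * 1.7
        outs = []
        for eps in (1e-5, 1e-7, 1e-9):
            kern = StepKernel(fp3.community, TruncationPolicy(tail_epsilon=eps))
            outs.append(kern.step(n, fp3.alpha0)[0])
        d1 = np.max(np.abs(outs[0] - outs[1]))
        d2 = np.max(np.abs(outs[1] - outs[2]))
        assert d2 < d1 < 1e-2

    def test_solved_fixpoint_is_fixed(self, fp15):
        out, _ = fp15.kernel.step(fp15.n_star, fp15.alpha0)
        assert np.max(np.abs(out - fp15.n_star)) < 1e-8

    def test_monte_carlo_fallback_tracks_enumeration(self, fp3, rng):
        n = fp3.n_star
        exact = fp3.kernel.step(n, fp3.alpha0)[0]
        tiny = StepKernel(
            fp3.community,
            TruncationPolicy(tail_epsilon=1e-7, config_ceiling=2, mc_samples=40000),
        )
        approx, info = tiny.step(n, fp3.alpha0, rng=rng)
        assert info.monte_carlo
        np.testing.assert_allclose(approx, exact, rtol=0.05)

    def test_mc_fallback_without_rng_raises(self, fp3):
        tiny = StepKernel(fp3.community, TruncationPolicy(config_ceiling=2))
        with pytest.raises(RuntimeError, match="Monte-Carlo"):
            tiny.step(fp3.n_star, fp3.alpha0)

    def test_functional_wrapper_matches_kernel(self, fp3):
        out = step_map(fp3.n_star, fp3.alpha0, fp3.community, fp3.kernel.policy)
        np.testing.assert_allclose(
            out, fp3.kernel.step(fp3.n_star, fp3.alpha0)[0], rtol=1e-12
        )

    def test_table_export_mass(self, small_kernel):
        n = np.array([30.0, 40.0, 30.0])
        frame = small_kernel.table_frame(n, 0.001)
        assert frame["prob"].sum() == pytest.approx(1.0, abs=1e-7)
        assert {"m1", "f1", "prob"} <= set(frame.columns)
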