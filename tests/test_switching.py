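"""Life-span law, jump-time sampling, and the two process simulators."""

import math

import numpy as np
import pytest

from ifsgene import (
    IntensityPair,
    JumpCapExceededError,
    ProbabilityPair,
    fixed_point_w,
    flow,
    jump_cdf,
    life_span,
    sample_jump_time,
    simulate_ifs_process,
    simulate_jump_process,
    step,
    survival_product,
    switch_rule_from_intensities,
)
from ifsgene.functions import constant, inverse_quadratic


class TestLifeSpan:
    def test_no_time_no_switch(self, example1):
        q = constant(0.3)
        assert life_span(q, example1, 0, (1, 1, 1), 0.0) == 1.0
        assert life_span(q, example1, 0, (1, 1, 1), 0.999) == 1.0
        assert jump_cdf(q, example1, 0, (1, 1, 1), 0.0) == 0.0

    def test_constant_hazard_closed_form(self, example1):
        q = constant(0.2)
        for t in (1, 3, 7.5):
            assert life_span(q, example1, 1, (0, 0, 0), t) == pytest.approx(
                math.exp(-0.2 * math.floor(t)), rel=1e-12
            )

    def test_place_dependent_hazard_matches_brute_force(self, example1):
        """Accumulate the hazard along the explicit orbit and exponentiate."""
        q = lambda x: 0.1 * (1.0 + x[0])  # noqa: E731
        x0 = (1.0, 1.0, 1.0)
        total = sum(q(flow(example1, s, x0, 1)) for s in range(3))
        assert life_span(q, example1, 1, x0, 3) == pytest.approx(math.exp(-total), rel=1e-12)

    def test_nonincreasing_and_positive(self, example1):
        q = inverse_quadratic(0.4)
        vals = [life_span(q, example1, 1, (0.5, 0.5, 0.5), t) for t in range(0, 30)]
        assert all(v > 0 for v in vals)
        assert all(v1 > v2 for v1, v2 in zip(vals, vals[1:]))  # q > 0 everywhere


class TestSurvivalProduct:
    def test_empty_product(self, example1):
        assert survival_product(constant(0.5), example1, 0, (1, 1, 1), 0.5) == 1.0

    def test_constant_hazard(self, example1):
        assert survival_product(constant(0.25), example1, 0, (1, 1, 1), 4) == pytest.approx(
            0.75**4, rel=1e-12
        )

    def test_telescoping_identity(self, example1):
        """Phi(t+1)/Phi(t) = 1 - q at the orbit point, exactly."""
        q = inverse_quadratic(0.4)
        x0 = (0.5, 0.5, 0.5)
        for t in range(8):
            ratio = survival_product(q, example1, 1, x0, t + 1) / survival_product(
                q, example1, 1, x0, t
            )
            assert ratio == pytest.approx(1.0 - q(flow(example1, t, x0, 1)), rel=1e-12)

    def test_hazard_of_one_rejected(self, example1):
        with pytest.raises(ValueError):
            survival_product(constant(1.0), example1, 0, (1, 1, 1), 3)

    def test_close_to_exponential_form_for_small_hazard(self, example1):
        q = lambda x: 0.02 * (1.0 + x[0] / 2.0)  # noqa: E731  (q_max <= 0.05 in the box)
        x0 = (0.5, 0.5, 0.5)
        for t in (5, 20, 50):
            gap = abs(
                survival_product(q, example1, 1, x0, t) - life_span(q, example1, 1, x0, t)
            )
            assert gap <= t * 0.05**2


class TestJumpCdf:
    def test_complement_of_survival(self, example1):
        q = inverse_quadratic(0.4)
        for t in (0, 1, 2.5, 10):
            assert jump_cdf(q, example1, 0, (1, 1, 1), t) + life_span(
                q, example1, 0, (1, 1, 1), t
            ) == pytest.approx(1.0, rel=1e-12)

    def test_bounded_by_max_hazard_law(self, example1):
        """F(t) <= 1 - exp(-q_max t) on orbits confined to the invariant box."""
        q = inverse_quadratic(0.5)
        q_max = 0.5  # supremum of 0.5/(1+|x|^2) over the box, attained at the origin
        for t in range(1, 40):
            f = jump_cdf(q, example1, 1, (0.0, 0.0, 0.0), t)
            assert f <= 1.0 - math.exp(-q_max * t) + 1e-12

    def test_approaches_one(self, example1):
        q = inverse_quadratic(0.5)
        assert jump_cdf(q, example1, 1, (0.0, 0.0, 0.0), 2000) > 0.999


class TestSampleJumpTime:
    def test_geometric_law_for_constant_hazard(self, example1):
        """t1 - 1 is geometric with success probability 1 - exp(-q)."""
        qbar = 0.3
        rng = np.random.default_rng(0)
        draws = np.array(
            [sample_jump_time(constant(qbar), example1, 0, (1, 1, 1), rng) for _ in range(20000)]
        )
        success = 1.0 - math.exp(-qbar)
        mean_expected = 1.0 / success
        sd = math.sqrt((1 - success) / success**2)
        assert draws.min() >= 1
        assert abs(draws.mean() - mean_expected) <= 3 * sd / math.sqrt(len(draws))

    def test_reproducible(self, example1):
        q = inverse_quadratic(0.4)
        a = [sample_jump_time(q, example1, 0, (1, 1, 1), np.random.default_rng(5)) for _ in range(3)]
        b = [sample_jump_time(q, example1, 0, (1, 1, 1), np.random.default_rng(5)) for _ in range(3)]
        assert a == b

    def test_cap_exceeded_raises_with_survival(self, example1):
        with pytest.raises(JumpCapExceededError) as err:
            sample_jump_time(
                constant(1e-12), example1, 0, (1, 1, 1), np.random.default_rng(123), t_cap=10
            )
        assert err.value.phi_at_cap == pytest.approx(math.exp(-1e-11), rel=1e-9)

    def test_cap_exceedance_vanishes_with_growing_cap(self, example1):
        """P(no jump by t_cap) = Phi(t_cap) -> 0, so each jump time is a.s. finite."""
        q = constant(0.05)
        failures = []
        for cap in (10, 100, 1000):
            n_fail = 0
            rng = np.random.default_rng(7)
            for _ in range(500):
                try:
                    sample_jump_time(q, example1, 0, (1, 1, 1), rng, t_cap=cap)
                except JumpCapExceededError:
                    n_fail += 1
            failures.append(n_fail / 500)
        assert failures[0] > failures[1] >= failures[2] == 0.0


class TestJumpProcessSimulator:
    def test_vanishing_intensity_gives_pure_flow(self, example1):
        qpair = IntensityPair(q0=constant(1e-9), q1=constant(1e-9))
        traj = simulate_jump_process(
            example1, qpair, (1.0, 1.0, 1.0), 0, 100, np.random.default_rng(0), t_cap=10**7
        )
        assert len(traj.jump_steps) == 0
        x = np.array([1.0, 1.0, 1.0])
        for n in range(1, 101):
            x = step(example1, x, 0)
            np.testing.assert_allclose(traj.states[n], x, rtol=1e-12)

    def test_box_invariance(self, example1):
        qpair = IntensityPair(q0=constant(0.2), q1=constant(0.1))
        traj = simulate_jump_process(
            example1, qpair, (0.5, 0.5, 0.5), 0, 2000, np.random.default_rng(1)
        )
        assert np.all(traj.states >= -1e-12) and np.all(traj.states <= 2 + 1e-12)

    def test_trajectory_structure(self, example1):
        """Gene flips exactly at jump steps; states follow the flow in between."""
        qpair = IntensityPair(q0=constant(0.3), q1=constant(0.3))
        traj = simulate_jump_process(
            example1, qpair, (0.5, 0.5, 0.5), 0, 500, np.random.default_rng(2)
        )
        flips = np.nonzero(np.diff(traj.gene) != 0)[0] + 1
        np.testing.assert_array_equal(flips, traj.jump_steps)
        assert np.all(np.diff(traj.jump_steps) > 0)
        for n in range(500):
            np.testing.assert_allclose(
                traj.states[n + 1], step(example1, traj.states[n], traj.gene[n]), rtol=1e-12
            )

    def test_mean_jump_count_within_exponential_bound(self, example1):
        qpair = IntensityPair(q0=constant(0.1), q1=constant(0.1), q_max=0.1)
        rng = np.random.default_rng(3)
        counts = [
            simulate_jump_process(example1, qpair, (0.5, 0.5, 0.5), 0, 20, rng).n_jumps_by(20.0)
            for _ in range(2000)
        ]
        assert np.mean(counts) <= math.exp(0.1 * 20)


class TestIfsProcessSimulator:
    def test_always_gene_off_contracts_to_origin(self, example1):
        ppair = ProbabilityPair(p0=constant(1.0))
        traj = simulate_ifs_process(
            example1, ppair, (1.5, 1.5, 1.5), 1, 200, np.random.default_rng(0)
        )
        assert len(traj.jump_steps) == 1  # the single forced 1 -> 0 switch
        np.testing.assert_allclose(traj.states[-1], np.zeros(3), atol=1e-15)

    def test_canonical_place_dependent_run_stays_in_box(self, example1):
        ppair = ProbabilityPair(p0=inverse_quadratic(0.5), box_upper=fixed_point_w(example1))
        traj = simulate_ifs_process(
            example1, ppair, (0.5, 0.5, 0.5), 0, 5000, np.random.default_rng(1)
        )
        assert np.all(traj.states >= -1e-12) and np.all(traj.states <= 2 + 1e-12)
        assert len(traj.jump_steps) > 0

    def test_reproducible(self, example1):
        ppair = ProbabilityPair(p0=inverse_quadratic(0.5))
        runs = [
            simulate_ifs_process(
                example1, ppair, (0.5, 0.5, 0.5), 0, 300, np.random.default_rng(9)
            )
            for _ in range(2)
        ]
        np.testing.assert_array_equal(runs[0].states, runs[1].states)
        np.testing.assert_array_equal(runs[0].gene, runs[1].gene)

    def test_choice_uses_current_point(self, example1):
        """A threshold rule must evaluate p at x_t, producing a relaxation cycle."""
        ppair = ProbabilityPair(p0=lambda x: 0.0 if x[0] < 1.0 else 1.0)
        traj = simulate_ifs_process(
            example1, ppair, (0.0, 0.0, 0.0), 0, 50, np.random.default_rng(0)
        )
        for n in range(50):
            expected_gene = 1 if traj.states[n][0] < 1.0 else 0
            assert traj.gene[n + 1] == expected_gene
        assert len(traj.jump_steps) > 2  # the orbit really crosses the threshold


class TestIntensityBridge:
    def test_first_jump_law_matches_product_survival(self, example1):
        """Under the bridged rule, P(t1 > n) equals the exact product form."""
        q = inverse_quadratic(0.45)
        qpair = IntensityPair(q0=q, q1=q)
        rule = switch_rule_from_intensities(qpair)
        x0 = (0.5, 0.5, 0.5)
        # law of the first switch implied by the per-step rule, computed exactly
        surv_rule = 1.0
        x = np.array(x0)
        for n in range(1, 21):
            p_stay = rule.probs(x, 0)[0]
            surv_rule *= p_stay
            x = step(example1, x, 0)
            assert surv_rule == pytest.approx(
                survival_product(q, example1, 0, x0, n), rel=1e-12
            )

    def test_small_hazard_limit_approaches_exponential_sampler(self, example1):
        """For q -> 0 the bridged and exponential-law jump distributions merge."""
        qbar = 0.005
        prod = survival_product(constant(qbar), example1, 0, (1, 1, 1), 100)
        expo = life_span(constant(qbar), example1, 0, (1, 1, 1), 100)
        assert prod == pytest.approx(expo, rel=100 * qbar**2 / (1 - qbar) + 1e-12)

    def test_gene_state_dependence_flagged(self):
        symmetric = switch_rule_from_intensities(IntensityPair(q0=constant(0.1), q1=constant(0.1)))
        assert not symmetric.gene_state_dependent
        asymmetric = switch_rule_from_intensities(IntensityPair(q0=constant(0.1), q1=constant(0.2)))
        assert asymmetric.gene_state_dependent
        # the asymmetric rule's transition matrix differs across gene states
        x = np.array([0.3, 0.3, 0.3])
        assert asymmetric.probs(x, 0) != asymmetric.probs(x, 1)

    def test_bridge_rejects_hazard_of_one(self):
        rule = switch_rule_from_intensities(IntensityPair(q0=constant(1.0), q1=constant(0.5)))
        with pytest.raises(ValueError):
            rule.probs(np.zeros(3), 0)
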